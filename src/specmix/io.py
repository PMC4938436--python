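"""File formats and reports: TIFF stacks, label-type maps, quantification CSVs.

Conventions used throughout: pixel coordinates are 0-based, row-major
``(row, col)``; bounding boxes and ROIs are half-open.  On disk, one
multipage TIFF per excitation wavelength holds that excitation's emission
channels as pages; stacks are typically written in acquisition order
(descending excitation wavelength) and reordered to the ascending
concatenated convention on ingestion.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .spectra import AcquisitionLayout
from .segmentation import SegmentationMask

__all__ = [
    "read_spectral_stacks",
    "write_spectral_stacks",
    "write_label_mask",
    "label_type_palette",
    "write_label_type_map",
    "write_quantification",
]


def read_spectral_stacks(
    paths: Mapping[float, str | Path],
    layout: AcquisitionLayout,
) -> dict[float, np.ndarray]:
    """Load one multipage TIFF per excitation, checking page counts and dtypes.

    Integer pixel data is preserved bit-exact.  Every excitation in the
    layout must have a path; page count must equal that excitation's channel
    count, and pages within a file must share one dtype.
    """
    stacks: dict[float, np.ndarray] = {}
    for exc, count in zip(layout.excitations, layout.channels_per_excitation):
        if exc not in paths:
            raise ValueError(f"no stack path given for excitation {exc} nm")
        path = Path(paths[exc])
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a multipage (channel) TIFF")
        if data.shape[0] != count:
            raise ValueError(
                f"{path}: {data.shape[0]} pages but layout expects {count} "
                f"channels for excitation {exc} nm"
            )
        stacks[exc] = data
    return stacks


def write_spectral_stacks(
    stacks: Mapping[float, np.ndarray],
    out_dir: str | Path,
    layout: AcquisitionLayout,
    dtype=np.uint16,
) -> dict[float, Path]:
    """Write one multipage TIFF per excitation, in acquisition order.

    Returns the mapping excitation -> written path.  File names encode the
    excitation wavelength so stacks can be re-associated unambiguously.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[float, Path] = {}
    for k in layout.acquisition_order:
        exc = layout.excitations[k]
        data = np.asarray(stacks[exc])
        if np.issubdtype(dtype, np.integer):
            info = np.iinfo(dtype)
            data = np.clip(np.rint(data), info.min, info.max).astype(dtype)
        path = out_dir / f"stack_ex{exc:g}nm.tif"
        tifffile.imwrite(path, data, photometric="minisblack")
        paths[exc] = path
    return paths


def write_label_mask(mask: SegmentationMask, path: str | Path) -> None:
    """Export a label image as 16-bit single-channel TIFF."""
    if mask.labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("too many particles for a 16-bit label image")
    tifffile.imwrite(Path(path), mask.labels.astype(np.uint16))


def label_type_palette(n_types: int) -> np.ndarray:
    """Deterministic palette of visually distinct RGB colors, one per label type.

    Evenly spaced hues at alternating value/saturation so neighbors in index
    differ in hue and nearby hues differ in brightness; supports well over
    the 120 types of the full combinatorial experiment.
    """
    import matplotlib.colors as mcolors

    h = (np.arange(n_types) * 0.61803398875) % 1.0  # golden-ratio hue walk
    s = np.where(np.arange(n_types) % 3 == 1, 0.6, 1.0)
    v = np.where(np.arange(n_types) % 2 == 1, 0.7, 1.0)
    rgb = mcolors.hsv_to_rgb(np.stack([h, s, v], axis=1))
    palette = (rgb * 255).astype(np.uint8)
    if len({tuple(c) for c in palette}) < n_types:
        raise ValueError(f"palette cannot provide {n_types} distinct colors")
    return palette


def write_label_type_map(
    assignments: pd.DataFrame,
    mask: SegmentationMask,
    path: str | Path,
    allowed_types: Sequence[tuple[int, int]] | None = None,
    palette: np.ndarray | None = None,
    n_fluorophores: int | None = None,
) -> np.ndarray:
    """Pseudo-colored label-type map: background black, one color per pair.

    Colors are deterministic in the lexicographic pair index so the same
    label type is the same color across images.  In restricted-mixture mode
    (``allowed_types`` given) any particle assigned a pair outside the
    allowed set is rendered gray, visually flagging impossible label types.
    """
    from .unmixing import enumerate_pairs

    labels = mask.labels
    if n_fluorophores is None:
        mx = int(assignments["pair_j"].max()) if len(assignments) else 1
        n_fluorophores = mx + 1
    pairs = enumerate_pairs(max(n_fluorophores, 2))
    pair_index = {p: k for k, p in enumerate(pairs)}
    if palette is None:
        palette = label_type_palette(len(pairs))
    elif len(palette) < len(pairs):
        raise ValueError("palette smaller than the number of label types")
    allowed = (
        {tuple(sorted(p)) for p in allowed_types} if allowed_types is not None else None
    )
    gray = np.array([128, 128, 128], dtype=np.uint8)
    rgb = np.zeros((*labels.shape, 3), dtype=np.uint8)
    for row in assignments.itertuples():
        if row.pair_i < 0:
            continue
        pair = (int(row.pair_i), int(row.pair_j))
        color = palette[pair_index[pair]]
        if allowed is not None and pair not in allowed:
            color = gray
        rgb[labels == row.particle_id] = color
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, rgb)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, rgb)
    return rgb


def write_quantification(
    assignments: pd.DataFrame,
    path: str | Path,
    ground_truth: pd.DataFrame | None = None,
    allowed_types: Sequence[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Per-label-type counts and percentages, optionally with accuracy columns.

    With ground truth, adds per-type true counts; with a restricted allowed
    set, adds a summary row with the possible/impossible percentage split.
    """
    ok = assignments[assignments["pair_i"] >= 0]
    total = len(ok)
    counts = (
        ok.groupby(["pair_i", "pair_j", "fluor_i", "fluor_j"])
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["pair_i", "pair_j"], ignore_index=True)
    )
    counts["percent"] = 100.0 * counts["count"] / total if total else 0.0
    if allowed_types is not None:
        allowed = {tuple(sorted(p)) for p in allowed_types}
        counts["possible"] = [
            (int(i), int(j)) in allowed
            for i, j in zip(counts["pair_i"], counts["pair_j"])
        ]
    if ground_truth is not None:
        true_counts = (
            ground_truth.groupby(["true_i", "true_j"])
            .size()
            .rename("true_count")
            .reset_index()
            .rename(columns={"true_i": "pair_i", "true_j": "pair_j"})
        )
        counts = counts.merge(true_counts, on=["pair_i", "pair_j"], how="outer")
        counts["count"] = counts["count"].fillna(0).astype(int)
        counts["percent"] = counts["percent"].fillna(0.0)
    counts.to_csv(path, index=False)
    return counts
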