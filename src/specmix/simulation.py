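"""Synthetic spectra, particles, and images for validating the unmixer.

The generator emulates the data the pipeline consumes without any real
microscope images: parametric fluorophores with Gaussian excitation and
emission curves, binary-labeled elliptical cells placed in an image, a
constant stray-light background, and Poisson shot noise.

SNR convention (shot-noise regime): with a Poisson photon count of mean N in
the peak channel, SNR = N / sqrt(N) = sqrt(N), so a target ``snr`` maps to a
peak expected count of ``snr**2`` photons.

The default 16-fluorophore palette carries the names of widely used
commercial dyes with textbook-plausible excitation/emission peak positions;
the numbers are synthetic stand-ins (real measured spectra are instrument-
specific), adequate for exercising the algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .spectra import (
    AcquisitionLayout,
    FluorophoreSpectrum,
    ReferenceMatrix,
    build_reference_matrix,
    normalize_reference,
)
from .unmixing import binary_constrained_unmix, enumerate_pairs, unmix_unconstrained

__all__ = [
    "FluorophoreModel",
    "SimulationSpec",
    "GroundTruthRecord",
    "DEFAULT_FLUOROPHORES",
    "default_layout",
    "single_excitation_layout",
    "fig5_style_models",
    "synth_fluorophore_spectrum",
    "reference_matrix_from_models",
    "simulate_particle_spectrum",
    "run_snr_experiment",
    "generate_synthetic_image",
    "score_assignments",
]


@dataclass(frozen=True)
class FluorophoreModel:
    """Gaussian excitation/emission model of one fluorophore.

    Peaks and widths in nm; ``excitation_width`` / ``emission_width`` are
    Gaussian standard deviations.  ``brightness`` is a relative scale applied
    before peak normalization of mixtures.
    """

    name: str
    excitation_peak: float
    emission_peak: float
    excitation_width: float = 25.0
    emission_width: float = 25.0
    brightness: float = 1.0

    def __post_init__(self) -> None:
        if not (350.0 <= self.excitation_peak <= 800.0):
            raise ValueError(f"{self.name}: excitation peak outside 350-800 nm")
        if not (350.0 <= self.emission_peak <= 800.0):
            raise ValueError(f"{self.name}: emission peak outside 350-800 nm")
        if self.emission_peak <= self.excitation_peak:
            raise ValueError(f"{self.name}: Stokes shift must be positive")
        if self.brightness <= 0:
            raise ValueError(f"{self.name}: brightness must be positive")


# Synthetic stand-in palette: dye names as commonly marketed, peak positions
# close to vendor catalog values, Gaussian shapes.
DEFAULT_FLUOROPHORES: tuple[FluorophoreModel, ...] = (
    FluorophoreModel("7HC", 370.0, 450.0),
    FluorophoreModel("PacBl", 404.0, 455.0),
    FluorophoreModel("AF405", 402.0, 424.0),
    FluorophoreModel("PacOr", 400.0, 551.0),
    FluorophoreModel("BOFl", 503.0, 512.0),
    FluorophoreModel("AF488", 495.0, 519.0),
    FluorophoreModel("OG514", 511.0, 530.0),
    FluorophoreModel("AF546", 556.0, 573.0),
    FluorophoreModel("AF555", 555.0, 565.0),
    FluorophoreModel("TET", 555.0, 580.0),
    FluorophoreModel("RRX", 570.0, 590.0),
    FluorophoreModel("AF594", 590.0, 617.0),
    FluorophoreModel("AF633", 632.0, 647.0),
    FluorophoreModel("AF647", 650.0, 668.0),
    FluorophoreModel("AF680", 679.0, 702.0),
    FluorophoreModel("AF700", 702.0, 723.0),
)


def default_layout() -> AcquisitionLayout:
    """Six-laser layout (405-633 nm), 10 nm emission bands up to 750 nm.

    Per-excitation channel counts follow from the spectral range each laser
    leaves available (up to a 32-anode detector), so the concatenated axis
    has 120 channels; the split among excitations is configuration, not a
    fixed constant.
    """
    excitations = (405.0, 488.0, 514.0, 561.0, 594.0, 633.0)
    counts = []
    for exc in excitations:
        counts.append(min(32, int((750.0 - (exc + 10.0)) // 10.0)))
    return AcquisitionLayout.regular(excitations, counts, channel_width=10.0)


def single_excitation_layout(
    excitation: float = 488.0, n_channels: int = 16, width: float = 10.0
) -> AcquisitionLayout:
    """One-laser layout, e.g. 488 nm with 16 emission channels of 10 nm."""
    return AcquisitionLayout.regular([excitation], [n_channels], width)


def fig5_style_models() -> tuple[FluorophoreModel, ...]:
    """Four green-excitable dyes with heavily overlapping emission.

    The canonical hard case: a particle carrying AF488 + BODIPY-FL unmixed
    against these four candidates under a single 488 nm excitation.
    """
    return tuple(
        m for m in DEFAULT_FLUOROPHORES if m.name in ("BOFl", "AF488", "OG514", "AF555")
    )


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one synthetic experiment."""

    fluorophore_models: tuple[FluorophoreModel, ...]
    layout: AcquisitionLayout
    snr: float
    seed: int = 0
    background_level: float = 2.0  # expected stray-light photons per channel

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.background_level < 0:
            raise ValueError("background level must be non-negative")


@dataclass(frozen=True)
class GroundTruthRecord:
    """True label of one synthetic particle, for scoring."""

    particle_id: int
    true_pair: tuple[int, int]
    abundances: tuple[float, float]
    position: tuple[float, float]
    pixel_count: int


def synth_fluorophore_spectrum(
    model: FluorophoreModel, layout: AcquisitionLayout
) -> FluorophoreSpectrum:
    """Concatenated spectrum of one model fluorophore under a layout.

    Within each excitation block the emission channels sample a Gaussian
    emission curve at the channel centers, scaled by the Gaussian excitation
    curve evaluated at that block's laser wavelength — emission shape is the
    same at every excitation, amplitude is not.  Channels at or below the
    excitation wavelength are zeroed (no anti-Stokes emission).
    """
    centers = layout.channel_centers()
    excs = layout.channel_excitations()
    exc_amp = np.exp(
        -((excs - model.excitation_peak) ** 2) / (2 * model.excitation_width**2)
    )
    em = np.exp(
        -((centers - model.emission_peak) ** 2) / (2 * model.emission_width**2)
    )
    values = model.brightness * exc_amp * em
    values[centers <= excs] = 0.0
    if values.max() <= 0 or values.max() < 1e-12 * model.brightness:
        raise ValueError(
            f"{model.name}: spectrum is zero over this layout (no overlap "
            "between emission range and recorded channels)"
        )
    return normalize_reference(FluorophoreSpectrum(model.name, values))


@lru_cache(maxsize=64)
def _cached_reference_matrix(
    models: tuple[FluorophoreModel, ...], layout: AcquisitionLayout
) -> ReferenceMatrix:
    return build_reference_matrix(
        [synth_fluorophore_spectrum(m, layout) for m in models], layout
    )


def reference_matrix_from_models(
    models: Sequence[FluorophoreModel], layout: AcquisitionLayout
) -> ReferenceMatrix:
    # models and layout are frozen/hashable, so repeated simulation calls
    # under one spec reuse the assembled matrix
    return _cached_reference_matrix(tuple(models), layout)


def _expected_spectrum(
    F: np.ndarray,
    pair: tuple[int, int],
    abundances: tuple[float, float],
    snr: float,
    background_level: float,
) -> np.ndarray:
    """Expected photon counts: mixture scaled to snr**2 at its peak, plus background."""
    i, j = pair
    mix = abundances[0] * F[:, i] + abundances[1] * F[:, j]
    peak = mix.max()
    if peak <= 0:
        raise ValueError("mixture spectrum is identically zero")
    return mix * (snr**2 / peak) + background_level


def simulate_particle_spectrum(
    spec: SimulationSpec,
    pair: tuple[int, int],
    abundances: tuple[float, float] = (1.0, 1.0),
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> tuple[np.ndarray, GroundTruthRecord]:
    """One noisy particle spectrum plus its ground-truth record.

    The expected spectrum is x_i f_i + x_j f_j scaled so its peak channel
    expects ``snr**2`` photons, plus the constant background; each channel is
    an independent Poisson draw.  With ``noise=False`` the expectation itself
    is returned (the infinite-SNR limit).
    """
    if abundances[0] <= 0 or abundances[1] <= 0:
        raise ValueError("true abundances must be positive")
    F = reference_matrix_from_models(spec.fluorophore_models, spec.layout).matrix
    mu = _expected_spectrum(F, pair, abundances, spec.snr, spec.background_level)
    if spec.snr**2 < 1:
        import warnings

        warnings.warn("sub-photon peak signal (snr**2 < 1)", stacklevel=2)
    if noise:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        y = rng.poisson(mu).astype(float)
    else:
        y = mu
    record = GroundTruthRecord(
        particle_id=0,
        true_pair=(min(pair), max(pair)),
        abundances=tuple(abundances),
        position=(float("nan"), float("nan")),
        pixel_count=1,
    )
    return y, record


def _top2_rule(abundances: np.ndarray) -> tuple[int, int]:
    """Label type implied by unconstrained unmixing: the two largest abundances."""
    order = np.argsort(abundances, kind="stable")[::-1]
    i, j = int(order[0]), int(order[1])
    return (i, j) if i < j else (j, i)


def run_snr_experiment(
    snr_levels: Sequence[float] = (3.0, 10.0, 30.0, 100.0, 300.0),
    n_particles: int = 1000,
    models: Sequence[FluorophoreModel] | None = None,
    layout: AcquisitionLayout | None = None,
    true_pair_names: tuple[str, str] = ("AF488", "BOFl"),
    abundances: tuple[float, float] = (1.0, 1.0),
    background_level: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Percent of particles correctly identified vs SNR, constrained vs not.

    Replicates the in-silico benchmark design: particles carrying a 1:1
    mixture of two heavily overlapping green dyes, modeled under a single
    488 nm excitation with 16 emission channels of 10 nm, Poisson shot noise,
    unmixed against four candidate fluorophores.  Each noisy spectrum is
    classified twice — by the binary-constrained unmixer and by standard
    unconstrained unmixing followed by a top-two-abundance rule — so the two
    algorithms see identical noise realizations.
    """
    models = tuple(models) if models is not None else fig5_style_models()
    layout = layout or single_excitation_layout()
    ref = reference_matrix_from_models(models, layout)
    F = ref.matrix
    names = ref.names
    ia, ib = names.index(true_pair_names[0]), names.index(true_pair_names[1])
    true_pair = (min(ia, ib), max(ia, ib))
    rng = np.random.default_rng(seed)
    rows = []
    for snr in snr_levels:
        mu = _expected_spectrum(F, true_pair, abundances, snr, background_level)
        b = np.full(layout.m, background_level)
        n_constrained = 0
        n_unconstrained = 0
        for _ in range(n_particles):
            y = rng.poisson(mu).astype(float)
            if binary_constrained_unmix(y, F, b).pair == true_pair:
                n_constrained += 1
            res = unmix_unconstrained(y - b, F)
            if _top2_rule(res.abundances) == true_pair:
                n_unconstrained += 1
        rows.append(
            {
                "snr": float(snr),
                "n_particles": n_particles,
                "pct_correct_constrained": 100.0 * n_constrained / n_particles,
                "pct_correct_unconstrained": 100.0 * n_unconstrained / n_particles,
            }
        )
    return pd.DataFrame(rows)


def generate_synthetic_image(
    spec: SimulationSpec,
    label_types: Sequence[tuple[int, int]],
    proportions: Sequence[float] | None = None,
    shape: tuple[int, int] = (512, 512),
    n_cells: int = 500,
    cell_axes: tuple[float, float] = (3.5, 1.6),
    abundance_ratio_spread: float = 0.25,
    rng: np.random.Generator | None = None,
) -> tuple[dict[float, np.ndarray], list[GroundTruthRecord]]:
    """Synthetic field of binary-labeled elliptical cells, one stack per excitation.

    Cells are ellipses (rod-like, random orientation) with uniform expected
    interior intensity, placed on a jittered grid so they never touch.  Each
    cell's label type is drawn from ``label_types`` with the given
    proportions; its expected in-cell spectrum peaks at ``snr**2`` photons,
    the constant stray-light background is added everywhere, and every pixel
    of every channel is an independent Poisson draw.

    Returns the per-excitation stacks keyed by excitation wavelength (build
    order follows the layout's acquisition order, typically descending
    wavelength) and one ground-truth record per cell.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    label_types = [tuple(sorted(p)) for p in label_types]
    if proportions is None:
        probs = np.full(len(label_types), 1.0 / len(label_types))
    else:
        probs = np.asarray(proportions, dtype=float)
        if probs.shape != (len(label_types),):
            raise ValueError("one proportion per label type required")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
    H, W = shape
    a_max = max(cell_axes)
    slot = int(np.ceil(2 * a_max + 3))  # cells in distinct slots cannot touch
    rows_n, cols_n = H // slot, W // slot
    if rows_n * cols_n < n_cells:
        raise ValueError(
            f"cannot place {n_cells} non-overlapping cells in a {H}x{W} "
            f"image; at most {rows_n * cols_n} fit"
        )
    slots = [(r, c) for r in range(rows_n) for c in range(cols_n)]
    chosen = rng.choice(len(slots), size=n_cells, replace=False)

    ref = reference_matrix_from_models(spec.fluorophore_models, spec.layout)
    F = ref.matrix
    m = spec.layout.m
    expected = np.full((m, H, W), spec.background_level, dtype=float)
    records: list[GroundTruthRecord] = []
    type_idx = rng.choice(len(label_types), size=n_cells, p=probs)
    for cell_id, (slot_i, t_i) in enumerate(zip(chosen, type_idx), start=1):
        r0, c0 = slots[slot_i]
        margin = slot - 2 * a_max - 1
        cy = r0 * slot + a_max + 0.5 + rng.uniform(0, max(margin, 0))
        cx = c0 * slot + a_max + 0.5 + rng.uniform(0, max(margin, 0))
        theta = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(
            cy, cx, cell_axes[0], cell_axes[1], shape=(H, W), rotation=theta
        )
        pair = label_types[t_i]
        # per-cell abundance ratio jitter around 1:1 (log-normal)
        ab = (
            float(np.exp(rng.normal(0.0, abundance_ratio_spread))),
            float(np.exp(rng.normal(0.0, abundance_ratio_spread))),
        )
        mix = ab[0] * F[:, pair[0]] + ab[1] * F[:, pair[1]]
        mix = mix * (spec.snr**2 / mix.max())
        expected[:, rr, cc] += mix[:, None]
        records.append(
            GroundTruthRecord(
                particle_id=cell_id,
                true_pair=pair,
                abundances=ab,
                position=(float(cy), float(cx)),
                pixel_count=int(rr.size),
            )
        )
    noisy = rng.poisson(expected).astype(float)
    stacks: dict[float, np.ndarray] = {}
    for k in spec.layout.acquisition_order:
        exc = spec.layout.excitations[k]
        stacks[exc] = noisy[spec.layout.block_slices[k]]
    return stacks, records


def ground_truth_frame(records: Sequence[GroundTruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "particle_id": [r.particle_id for r in records],
            "true_i": [r.true_pair[0] for r in records],
            "true_j": [r.true_pair[1] for r in records],
            "x_i": [r.abundances[0] for r in records],
            "x_j": [r.abundances[1] for r in records],
            "row": [r.position[0] for r in records],
            "col": [r.position[1] for r in records],
            "pixel_count": [r.pixel_count for r in records],
        }
    )


def score_assignments(
    assignments: pd.DataFrame,
    ground_truth: pd.DataFrame | Sequence[GroundTruthRecord],
    allowed_types: Sequence[tuple[int, int]] | None = None,
    match_radius: float = 5.0,
) -> dict:
    """Score assignments against ground truth.

    Particles are matched to true cells by nearest centroid (within
    ``match_radius`` pixels).  Reports exact-pair accuracy, a per-pair
    confusion table, the fraction of assignments outside ``allowed_types``
    (the impossible-label-type rate, when a restricted mixture is given),
    and the Pearson correlation between true and detected label-type
    proportions.
    """
    from scipy.spatial import cKDTree
    from scipy.stats import pearsonr

    if not isinstance(ground_truth, pd.DataFrame):
        ground_truth = ground_truth_frame(ground_truth)
    ok = assignments[assignments["pair_i"] >= 0].copy()
    tree = cKDTree(ground_truth[["row", "col"]].to_numpy())
    dist, idx = tree.query(ok[["centroid_row", "centroid_col"]].to_numpy())
    matched = dist <= match_radius
    ok = ok.loc[matched].copy()
    gt = ground_truth.iloc[idx[matched]]
    true_pairs = list(zip(gt["true_i"].to_numpy(), gt["true_j"].to_numpy()))
    found_pairs = list(zip(ok["pair_i"].to_numpy(), ok["pair_j"].to_numpy()))
    n = len(ok)
    correct = sum(t == f for t, f in zip(true_pairs, found_pairs))
    confusion = (
        pd.DataFrame({"true": true_pairs, "assigned": found_pairs})
        .value_counts()
        .rename("count")
        .reset_index()
    )
    out = {
        "n_matched": n,
        "n_unmatched": int(len(assignments) - n),
        "percent_correct": 100.0 * correct / n if n else float("nan"),
        "confusion": confusion,
    }
    if allowed_types is not None:
        allowed = {tuple(sorted(p)) for p in allowed_types}
        impossible = sum(f not in allowed for f in found_pairs)
        out["percent_impossible"] = 100.0 * impossible / n if n else float("nan")
        out["percent_possible"] = 100.0 - out["percent_impossible"] if n else float("nan")
    # input/output proportion correlation over the label types present in truth
    types = sorted(set(true_pairs))
    true_counts = np.array([sum(t == ty for t in true_pairs) for ty in types], float)
    found_counts = np.array([sum(f == ty for f in found_pairs) for ty in types], float)
    if len(types) >= 2 and n:
        tp, fp = true_counts / n, found_counts / n
        if tp.std() == 0 or fp.std() == 0:
            # degenerate (e.g. perfectly uniform mixture): correlation is
            # undefined; call it 1 when detected proportions reproduce the
            # input exactly
            out["proportion_correlation"] = (
                1.0 if np.allclose(tp, fp) else float("nan")
            )
        else:
            r, _ = pearsonr(tp, fp)
            out["proportion_correlation"] = float(r)
    else:
        out["proportion_correlation"] = float("nan")
    return out
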