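"""Excitation-concatenated reference spectra and the reference matrix F.

A spectral image acquired at ``p`` excitation wavelengths, each with its own
set of emission channels, is treated as a single linear system by joining the
per-excitation emission spectra end-to-end ("concatenation").  The resulting
channel axis orders excitations ascending by wavelength, and within each
excitation block orders emission channels ascending by emission wavelength.
Reference spectra of pure singly-labeled populations, measured on that
concatenated axis and peak-normalized, form the columns of the m x n
reference matrix F used for linear unmixing (y = F @ x).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AcquisitionLayout",
    "FluorophoreSpectrum",
    "ReferenceMatrix",
    "concatenate_stacks",
    "normalize_reference",
    "derive_reference_spectrum",
    "build_reference_matrix",
]


@dataclass(frozen=True)
class AcquisitionLayout:
    """Excitation wavelengths and the per-excitation emission channel grid.

    Parameters
    ----------
    excitations
        Excitation wavelengths in nm, strictly ascending.  This is the order
        of blocks on the concatenated channel axis.
    channels_per_excitation
        Number of emission channels recorded for each excitation.
    channel_edges
        For each excitation, the emission band edges in nm: a strictly
        increasing sequence of length ``channels_per_excitation[k] + 1``
        defining contiguous, non-overlapping bands.
    acquisition_order
        Permutation of excitation indices recording the order stacks were
        acquired in.  Defaults to descending excitation wavelength, the
        bleaching-minimizing protocol (longest wavelength first).
    """

    excitations: tuple[float, ...]
    channels_per_excitation: tuple[int, ...]
    channel_edges: tuple[tuple[float, ...], ...]
    acquisition_order: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        excitations = tuple(float(e) for e in self.excitations)
        counts = tuple(int(c) for c in self.channels_per_excitation)
        edges = tuple(tuple(float(v) for v in e) for e in self.channel_edges)
        object.__setattr__(self, "excitations", excitations)
        object.__setattr__(self, "channels_per_excitation", counts)
        object.__setattr__(self, "channel_edges", edges)
        if len(excitations) == 0:
            raise ValueError("layout needs at least one excitation")
        if not all(a < b for a, b in zip(excitations, excitations[1:])):
            raise ValueError("excitations must be strictly ascending")
        if len(counts) != len(excitations) or len(edges) != len(excitations):
            raise ValueError(
                "channels_per_excitation and channel_edges must have one "
                "entry per excitation"
            )
        for exc, count, edge in zip(excitations, counts, edges):
            if count < 1:
                raise ValueError(f"excitation {exc} nm has no channels")
            if len(edge) != count + 1:
                raise ValueError(
                    f"excitation {exc} nm: expected {count + 1} channel "
                    f"edges, got {len(edge)}"
                )
            if not all(a < b for a, b in zip(edge, edge[1:])):
                raise ValueError(
                    f"excitation {exc} nm: channel edges must be strictly "
                    "increasing"
                )
        if not self.acquisition_order:
            # default: acquire in descending excitation wavelength
            object.__setattr__(
                self, "acquisition_order", tuple(range(len(excitations)))[::-1]
            )
        else:
            order = tuple(int(i) for i in self.acquisition_order)
            object.__setattr__(self, "acquisition_order", order)
            if sorted(order) != list(range(len(excitations))):
                raise ValueError("acquisition_order must be a permutation")
        if self.m < 1:
            raise ValueError("total channel count must be >= 1")

    @property
    def p(self) -> int:
        """Number of excitations."""
        return len(self.excitations)

    @property
    def m(self) -> int:
        """Total number of concatenated channels."""
        return int(sum(self.channels_per_excitation))

    @property
    def block_slices(self) -> tuple[slice, ...]:
        """Slice of the concatenated axis covered by each excitation block."""
        out, start = [], 0
        for c in self.channels_per_excitation:
            out.append(slice(start, start + c))
            start += c
        return tuple(out)

    def channel_centers(self) -> np.ndarray:
        """Emission band centers (nm) along the concatenated axis."""
        centers = [
            (np.asarray(e[:-1]) + np.asarray(e[1:])) / 2.0
            for e in self.channel_edges
        ]
        return np.concatenate(centers)

    def channel_excitations(self) -> np.ndarray:
        """Excitation wavelength (nm) of every concatenated channel."""
        return np.repeat(self.excitations, self.channels_per_excitation)

    @classmethod
    def regular(
        cls,
        excitations: Sequence[float],
        channels_per_excitation: Sequence[int],
        channel_width: float,
        start_offset: float = 10.0,
        acquisition_order: Sequence[int] | None = None,
    ) -> "AcquisitionLayout":
        """Layout with contiguous equal-width bands starting just above each laser line."""
        excs = sorted(float(e) for e in excitations)
        edges = []
        for exc, count in zip(excs, channels_per_excitation):
            start = exc + start_offset
            edges.append(
                tuple(start + channel_width * i for i in range(int(count) + 1))
            )
        return cls(
            excitations=tuple(excs),
            channels_per_excitation=tuple(int(c) for c in channels_per_excitation),
            channel_edges=tuple(edges),
            acquisition_order=tuple(acquisition_order or ()),
        )

    def to_dict(self) -> dict:
        return {
            "excitations": list(self.excitations),
            "channels_per_excitation": list(self.channels_per_excitation),
            "channel_edges": [list(e) for e in self.channel_edges],
            "acquisition_order": list(self.acquisition_order),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AcquisitionLayout":
        return cls(
            excitations=tuple(d["excitations"]),
            channels_per_excitation=tuple(d["channels_per_excitation"]),
            channel_edges=tuple(tuple(e) for e in d["channel_edges"]),
            acquisition_order=tuple(d.get("acquisition_order") or ()),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AcquisitionLayout":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class FluorophoreSpectrum:
    """A fluorophore's intensity on the concatenated channel axis."""

    name: str
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("spectrum values must be a 1-D vector")
        if np.any(values < 0):
            raise ValueError(f"spectrum {self.name!r} has negative values")
        if self.normalized and values.max(initial=0.0) != 1.0:
            raise ValueError(
                f"spectrum {self.name!r} flagged normalized but max != 1"
            )

    def __len__(self) -> int:
        return self.values.size


def normalize_reference(spectrum: FluorophoreSpectrum) -> FluorophoreSpectrum:
    """Peak-normalize a reference spectrum.

    The overall highest-intensity excitation/emission channel becomes unit
    intensity; all other channels are fractions of it.  Normalization is
    global across the whole concatenated axis, not per excitation block.
    """
    peak = spectrum.values.max(initial=0.0)
    if peak <= 0:
        raise ValueError(f"cannot normalize all-zero spectrum {spectrum.name!r}")
    values = spectrum.values / peak
    # guard against rounding: the peak element must be exactly 1
    values[np.argmax(spectrum.values)] = 1.0
    return FluorophoreSpectrum(spectrum.name, values, normalized=True)


def concatenate_stacks(
    stacks: Mapping[float, np.ndarray],
    layout: AcquisitionLayout,
) -> np.ndarray:
    """Join per-excitation image stacks into one concatenated spectral image.

    Parameters
    ----------
    stacks
        Mapping from excitation wavelength (nm) to a ``(channels, H, W)``
        image stack, emission channels ascending.  Stacks may be supplied in
        any order (e.g. acquisition order, which is typically descending
        excitation wavelength).
    layout
        Acquisition layout; every excitation must have a stack.

    Returns
    -------
    ndarray of shape ``(layout.m, H, W)`` with excitation blocks ordered
    ascending by excitation wavelength.  Pixel values are unchanged, only
    reindexed.
    """
    ordered = []
    shape = None
    for exc, count in zip(layout.excitations, layout.channels_per_excitation):
        if exc not in stacks:
            raise ValueError(f"missing stack for excitation {exc} nm")
        stack = np.asarray(stacks[exc])
        if stack.ndim != 3:
            raise ValueError(
                f"excitation {exc} nm: stack must be (channels, H, W), "
                f"got shape {stack.shape}"
            )
        if stack.shape[0] != count:
            raise ValueError(
                f"excitation {exc} nm: expected {count} channels, "
                f"got {stack.shape[0]}"
            )
        if shape is None:
            shape = stack.shape[1:]
        elif stack.shape[1:] != shape:
            raise ValueError(
                f"excitation {exc} nm: image shape {stack.shape[1:]} does "
                f"not match {shape}"
            )
        ordered.append(stack)
    return np.concatenate(ordered, axis=0)


def derive_reference_spectrum(
    pure_image: np.ndarray,
    background: np.ndarray | None = None,
    *,
    name: str = "reference",
    min_size: int = 4,
    threshold_channels: Sequence[int] | None = None,
) -> FluorophoreSpectrum:
    """Derive a reference spectrum from an image of a pure singly-labeled population.

    Segments the image (Otsu threshold on the channel-sum image, connected
    components), averages the spectrum over all in-particle pixels, subtracts
    the background vector, clips negatives to zero and peak-normalizes.
    """
    from .segmentation import compute_threshold, segment_particles

    pure_image = np.asarray(pure_image, dtype=float)
    thresh = compute_threshold(pure_image, channels=threshold_channels)
    mask = segment_particles(
        pure_image, thresh, min_size=min_size, channels=threshold_channels
    )
    inside = mask.labels > 0
    if not inside.any():
        raise ValueError("no particles found in pure-population image")
    mean = pure_image[:, inside].mean(axis=1)
    if background is not None:
        background = np.asarray(background, dtype=float)
        if background.shape != mean.shape:
            raise ValueError("background vector length must match channel count")
        mean = mean - background
    mean = np.clip(mean, 0.0, None)
    return normalize_reference(FluorophoreSpectrum(name, mean))


@dataclass(frozen=True)
class ReferenceMatrix:
    """The m x n matrix F of peak-normalized concatenated fluorophore spectra."""

    layout: AcquisitionLayout
    fluorophores: tuple[FluorophoreSpectrum, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fluorophores", tuple(self.fluorophores))
        names = [f.name for f in self.fluorophores]
        if len(set(names)) != len(names):
            raise ValueError("duplicate fluorophore names in reference matrix")
        for f in self.fluorophores:
            if len(f) != self.layout.m:
                raise ValueError(
                    f"spectrum {f.name!r} has {len(f)} channels, layout "
                    f"expects {self.layout.m}"
                )
            if not f.normalized:
                raise ValueError(f"spectrum {f.name!r} is not peak-normalized")

    @property
    def n(self) -> int:
        return len(self.fluorophores)

    @property
    def m(self) -> int:
        return self.layout.m

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.fluorophores)

    @property
    def matrix(self) -> np.ndarray:
        return np.column_stack([f.values for f in self.fluorophores])

    def to_csv(self, path) -> None:
        """Write as a plain-text table: one column per fluorophore, one row per channel."""
        pd.DataFrame(self.matrix, columns=list(self.names)).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, layout: AcquisitionLayout) -> "ReferenceMatrix":
        df = pd.read_csv(path)
        spectra = [
            FluorophoreSpectrum(str(col), df[col].to_numpy(dtype=float))
            for col in df.columns
        ]
        return build_reference_matrix(spectra, layout)


def build_reference_matrix(
    spectra: Sequence[FluorophoreSpectrum],
    layout: AcquisitionLayout,
) -> ReferenceMatrix:
    """Assemble F from reference spectra, normalizing any unnormalized column."""
    if len(spectra) < 2:
        raise ValueError("binary unmixing requires at least 2 fluorophores")
    normalized = [
        s if s.normalized else normalize_reference(s) for s in spectra
    ]
    return ReferenceMatrix(layout=layout, fluorophores=tuple(normalized))
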