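"""Spectral channels, image stacks, NFE correction and reference spectra.

A multispectral acquisition is a stack of 2-D radiance images, one per
excitation:emission filter pair.  Radiance images are scaled per channel by an
excitation-light correction factor, yielding normalized fluorescence
efficiency (NFE) images whose pixel vectors are comparable across channels.
Endmember reference spectra (tissue autofluorescence, DsRed reporter) are
built from region-of-interest means of NFE stacks and normalized to unit
Euclidean norm so that unmixed abundances are comparable across sessions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "SpectralChannel",
    "ChannelSet",
    "SpectralStack",
    "Roi",
    "Spectrum",
    "default_channelset",
    "apply_nfe_correction",
    "extract_mean_spectrum",
    "build_autofluorescence_reference",
    "build_dsred_reference",
]

RADIANCE = "radiance"  # photons / s / cm^2 / sr
NFE = "NFE"

#: excitation:emission center wavelengths (nm) of the 4-channel IVIS protocol
DEFAULT_CHANNELS = ((465, 540), (465, 580), (535, 600), (570, 620))


@dataclass(frozen=True)
class SpectralChannel:
    """One excitation:emission filter pair.

    Parameters
    ----------
    ex_center, em_center : float
        Filter center wavelengths in nm.  ``ex_center < em_center`` is
        enforced (Stokes shift).
    ex_passband, em_passband : float
        Filter widths in nm (defaults 30 and 20, the instrument's passbands).
    correction_factor : float
        Positive per-channel excitation-light correction divisor; dividing a
        radiance image by it yields the NFE image.
    """

    ex_center: float
    em_center: float
    ex_passband: float = 30.0
    em_passband: float = 20.0
    correction_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.ex_center < self.em_center:
            raise ValueError(
                f"excitation center {self.ex_center} nm must lie below the "
                f"emission center {self.em_center} nm"
            )
        if not (np.isfinite(self.correction_factor) and self.correction_factor > 0):
            raise ValueError(f"correction_factor must be > 0, got {self.correction_factor}")

    @property
    def name(self) -> str:
        return f"{self.ex_center:g}:{self.em_center:g}"


@dataclass(frozen=True)
class ChannelSet:
    """Ordered, fixed set of spectral channels for a study."""

    channels: tuple[SpectralChannel, ...]

    def __post_init__(self) -> None:
        if len(self.channels) < 2:
            raise ValueError("a ChannelSet needs at least 2 channels")
        pairs = [(c.ex_center, c.em_center) for c in self.channels]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (ex_center, em_center) pairs in ChannelSet")

    def __len__(self) -> int:
        return len(self.channels)

    def __iter__(self):
        return iter(self.channels)

    @property
    def correction_factors(self) -> np.ndarray:
        return np.array([c.correction_factor for c in self.channels], dtype=float)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]


def default_channelset(
    correction_factors: Sequence[float] | None = None,
) -> ChannelSet:
    """The 4-channel 465:540 / 465:580 / 535:600 / 570:620 protocol.

    ``correction_factors`` defaults to 1.0 for every channel (calibration data
    are instrument-specific and supplied by the user).
    """
    if correction_factors is None:
        correction_factors = [1.0] * len(DEFAULT_CHANNELS)
    if len(correction_factors) != len(DEFAULT_CHANNELS):
        raise ValueError("need one correction factor per channel")
    return ChannelSet(
        tuple(
            SpectralChannel(ex, em, correction_factor=float(f))
            for (ex, em), f in zip(DEFAULT_CHANNELS, correction_factors)
        )
    )


@dataclass
class SpectralStack:
    """L-channel image stack with unit tag and acquisition metadata.

    ``data`` has shape (L, H, W); pixel (r, c) carries the length-L channel
    vector ``data[:, r, c]``.  Units are either raw radiance or NFE.  NaN or
    infinite pixels are rejected outright rather than masked, so ROI means
    can never change silently.
    """

    data: np.ndarray
    channelset: ChannelSet
    units: str = RADIANCE
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be (L, H, W), got shape {self.data.shape}")
        if self.data.shape[0] != len(self.channelset):
            raise ValueError(
                f"stack has {self.data.shape[0]} pages but the channel set "
                f"defines {len(self.channelset)} channels"
            )
        if self.units not in (RADIANCE, NFE):
            raise ValueError(f"unknown units tag {self.units!r}")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                f"non-finite pixel in channel {bad[0]} at (row={bad[1]}, col={bad[2]})"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


class Roi:
    """Explicit pixel set: (row, col) coordinates, 0-based, origin top-left."""

    def __init__(self, pixels: Iterable[tuple[int, int]]):
        px = sorted({(int(r), int(c)) for r, c in pixels})
        if not px:
            raise ValueError("ROI must contain at least one pixel")
        if any(r < 0 or c < 0 for r, c in px):
            raise ValueError("ROI coordinates must be non-negative")
        self._pixels = px
        self._rows = np.array([p[0] for p in px])
        self._cols = np.array([p[1] for p in px])

    def __len__(self) -> int:
        return len(self._pixels)

    def __iter__(self):
        return iter(self._pixels)

    def __eq__(self, other) -> bool:
        return isinstance(other, Roi) and self._pixels == other._pixels

    @property
    def rows(self) -> np.ndarray:
        return self._rows

    @property
    def cols(self) -> np.ndarray:
        return self._cols

    def check_bounds(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self._rows.max() >= h or self._cols.max() >= w:
            raise ValueError(f"ROI exceeds image bounds {shape}")

    @classmethod
    def rectangle(cls, top: int, left: int, height: int, width: int) -> "Roi":
        return cls(
            (r, c)
            for r in range(top, top + height)
            for c in range(left, left + width)
        )

    @classmethod
    def disk(cls, center: tuple[float, float], radius: float) -> "Roi":
        r0, c0 = center
        rr = int(np.ceil(radius))
        pixels = [
            (r, c)
            for r in range(int(np.floor(r0)) - rr, int(np.ceil(r0)) + rr + 1)
            for c in range(int(np.floor(c0)) - rr, int(np.ceil(c0)) + rr + 1)
            if (r - r0) ** 2 + (c - c0) ** 2 <= radius**2 and r >= 0 and c >= 0
        ]
        return cls(pixels)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["row", "col"])
            writer.writerows(self._pixels)

    @classmethod
    def from_csv(cls, path) -> "Roi":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            return cls((int(row["row"]), int(row["col"])) for row in reader)


@dataclass
class Spectrum:
    """Length-L endmember spectrum (NFE per unit abundance)."""

    values: np.ndarray
    label: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size < 2:
            raise ValueError("a spectrum needs at least 2 channels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum contains non-finite values")
        norm = float(np.linalg.norm(self.values))
        if norm == 0.0:
            raise ValueError("spectrum is the zero vector")
        if self.normalized and abs(norm - 1.0) > 1e-12:
            raise ValueError(f"spectrum flagged normalized but ‖s‖ = {norm}")

    def __len__(self) -> int:
        return self.values.size

    def unit(self, label: str | None = None) -> "Spectrum":
        """Return this spectrum scaled to unit Euclidean norm."""
        v = self.values / np.linalg.norm(self.values)
        # re-normalize once more to push ‖v‖ within 1e-12 of 1 exactly
        v = v / np.linalg.norm(v)
        return Spectrum(v, label=label if label is not None else self.label, normalized=True)


# ---------------------------------------------------------------------------
# operations


def apply_nfe_correction(
    stack: SpectralStack, channelset: ChannelSet | None = None
) -> SpectralStack:
    """Divide each radiance channel by its excitation correction factor.

    Returns a new stack tagged NFE; the input must be in radiance units.
    """
    if stack.units != RADIANCE:
        raise ValueError(f"expected radiance units, got {stack.units!r}")
    cs = channelset if channelset is not None else stack.channelset
    if len(cs) != stack.n_channels:
        raise ValueError(
            f"channel set has {len(cs)} channels, stack has {stack.n_channels}"
        )
    factors = cs.correction_factors
    data = stack.data / factors[:, None, None]
    return SpectralStack(data, cs, units=NFE, metadata=dict(stack.metadata))


def extract_mean_spectrum(stack: SpectralStack, roi: Roi, label: str = "") -> Spectrum:
    """Arithmetic mean of the channel vectors over the ROI pixels."""
    roi.check_bounds(stack.shape)
    values = stack.data[:, roi.rows, roi.cols].mean(axis=1)
    return Spectrum(values, label=label, normalized=False)


def build_autofluorescence_reference(
    day0_stack: SpectralStack, roi: Roi, label: str = "autofluorescence"
) -> Spectrum:
    """Unit-norm background spectrum from a pre-injection (day 0) ROI."""
    mean = extract_mean_spectrum(day0_stack, roi)
    return mean.unit(label=label)


def build_dsred_reference(
    tumor_stack: SpectralStack,
    roi: Roi,
    autofluor: Spectrum,
    *,
    subtract_mode: Literal["direct", "projection"] = "direct",
    background: Spectrum | None = None,
    residual_tol: float = 1e-10,
    label: str = "DsRed",
) -> Spectrum:
    """Unit-norm reporter spectrum from a tumor ROI, background removed.

    Two removal modes:

    ``direct`` (default)
        Subtract the *unscaled* day-0 background spectrum recorded from the
        same region (``background``; ``autofluor`` is used as a fallback when
        no unscaled background is given).  When the autofluorescence field is
        stable between the background and tumor acquisitions this cancels the
        background contribution exactly and recovers the true reporter
        spectrum, including its direction.

    ``projection``
        Remove the component parallel to the unit autofluorescence vector â:
        ``d_raw = m − (m·â)â``.  The result is orthogonal to â by
        construction, which tilts it away from the true reporter spectrum
        whenever reporter and background overlap spectrally; provided for
        completeness and for data without a matched background ROI.
    """
    if not autofluor.normalized:
        raise ValueError("autofluorescence reference must be unit-norm")
    m = extract_mean_spectrum(tumor_stack, roi).values
    if len(autofluor) != m.size:
        raise ValueError("autofluorescence spectrum length does not match stack")
    if subtract_mode == "projection":
        a_hat = autofluor.values
        d_raw = m - (m @ a_hat) * a_hat
    elif subtract_mode == "direct":
        bg = background if background is not None else autofluor
        if len(bg) != m.size:
            raise ValueError("background spectrum length does not match stack")
        d_raw = m - bg.values
    else:
        raise ValueError(f"unknown subtract_mode {subtract_mode!r}")
    norm = float(np.linalg.norm(d_raw))
    if norm <= residual_tol * max(1.0, float(np.linalg.norm(m))):
        raise ValueError(
            "tumor ROI is indistinguishable from autofluorescence "
            f"(residual norm {norm:.3g}); unusable DsRed reference"
        )
    return Spectrum(d_raw, label=label).unit(label=label)
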