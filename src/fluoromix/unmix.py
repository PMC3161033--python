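"""Per-pixel linear (pseudo-inverse) spectral unmixing and thresholding.

Each NFE pixel vector y (length L) is decomposed as y ≈ S·c where the columns
of S are the unit-norm endmember spectra (autofluorescence, DsRed).  The
coefficients c are the unconstrained least-squares solution c = S⁺y with S⁺
the Moore–Penrose pseudo-inverse; negative coefficients are retained at this
stage and handled downstream by thresholding.  The DsRed abundance map is
thresholded at a control-derived level τ (mean + k·sd of a tumor-free day-0
map by default) before quantification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectra import NFE, SpectralStack, Spectrum

__all__ = [
    "SpectrumLibrary",
    "AbundanceMaps",
    "ThresholdedMap",
    "make_unmixer",
    "unmix_stack",
    "compute_threshold",
    "threshold_map",
]


@dataclass
class SpectrumLibrary:
    """Endmember matrix S (L×K) with unit-norm columns and labels."""

    spectra: list[Spectrum]

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("library needs at least one spectrum")
        lengths = {len(s) for s in self.spectra}
        if len(lengths) != 1:
            raise ValueError("all library spectra must have the same length")
        if not all(s.normalized for s in self.spectra):
            raise ValueError("library columns must be unit-norm spectra")
        if self.n_endmembers > self.n_channels:
            raise ValueError("more endmembers than channels (K > L)")
        if np.linalg.matrix_rank(self.matrix) < self.n_endmembers:
            raise ValueError("library is rank-deficient (collinear spectra)")

    @property
    def matrix(self) -> np.ndarray:
        return np.column_stack([s.values for s in self.spectra])

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.spectra]

    @property
    def n_channels(self) -> int:
        return len(self.spectra[0])

    @property
    def n_endmembers(self) -> int:
        return len(self.spectra)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


def make_unmixer(library: SpectrumLibrary, cond_limit: float = 1e4) -> np.ndarray:
    """Moore–Penrose pseudo-inverse S⁺ (K×L) of the library matrix.

    Computed by SVD (rank-revealing) rather than the normal equations, which
    serve as the independent test oracle.  A condition number above
    ``cond_limit`` triggers a warning, not an error.
    """
    cond = library.condition_number
    if cond > cond_limit:
        warnings.warn(
            f"spectrum library is ill-conditioned (cond = {cond:.3g} > {cond_limit:g}); "
            "abundances will be noise-amplified",
            stacklevel=2,
        )
    return np.linalg.pinv(library.matrix)


@dataclass
class AbundanceMaps:
    """K per-pixel coefficient maps plus the per-pixel residual norm."""

    maps: np.ndarray  # (K, H, W)
    residual: np.ndarray  # (H, W), ‖y − S·c‖ per pixel
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        self.residual = np.asarray(self.residual, dtype=np.float64)
        if self.maps.ndim != 3 or self.residual.shape != self.maps.shape[1:]:
            raise ValueError("maps must be (K, H, W) with matching residual")
        if np.any(self.residual < 0):
            raise ValueError("residual map must be non-negative")

    def get(self, label: str) -> np.ndarray:
        return self.maps[self.labels.index(label)]


def unmix_stack(
    stack: SpectralStack,
    library: SpectrumLibrary,
    *,
    nonneg: bool = False,
) -> AbundanceMaps:
    """Unmix an NFE stack into per-endmember abundance maps.

    The default is the unconstrained pseudo-inverse solution.  With
    ``nonneg=True`` each pixel is solved by non-negative least squares
    instead (comparison mode; much slower).
    """
    if stack.units != NFE:
        raise ValueError(f"unmixing requires NFE units, got {stack.units!r}")
    if stack.n_channels != library.n_channels:
        raise ValueError(
            f"stack has {stack.n_channels} channels, library expects {library.n_channels}"
        )
    L, h, w = stack.data.shape
    Y = stack.data.reshape(L, -1)
    S = library.matrix
    if nonneg:
        from scipy.optimize import nnls

        C = np.empty((library.n_endmembers, Y.shape[1]))
        for j in range(Y.shape[1]):
            C[:, j] = nnls(S, Y[:, j])[0]
    else:
        C = make_unmixer(library) @ Y
    R = np.linalg.norm(Y - S @ C, axis=0)
    return AbundanceMaps(
        C.reshape(library.n_endmembers, h, w),
        R.reshape(h, w),
        labels=list(library.labels),
    )


def compute_threshold(control_map: np.ndarray, k: float = 3.0) -> float:
    """Control-derived threshold τ = mean + k·sd of a tumor-free DsRed map.

    ``sd`` uses denominator n−1.  The control map should come from a day-0
    (pre-injection) stack run through the same unmixing.
    """
    control = np.asarray(control_map, dtype=np.float64).ravel()
    if control.size < 2:
        raise ValueError("control map needs at least 2 pixels")
    if k < 0:
        raise ValueError("k must be non-negative")
    return float(control.mean() + k * control.std(ddof=1))


@dataclass
class ThresholdedMap:
    """DsRed abundance map thresholded at τ (strict inequality)."""

    threshold: float
    mask: np.ndarray  # bool, abundance > τ
    masked: np.ndarray  # abundance on mask, 0 elsewhere

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.masked = np.asarray(self.masked, dtype=np.float64)
        if self.mask.shape != self.masked.shape:
            raise ValueError("mask and masked map shapes differ")


def threshold_map(maps: AbundanceMaps, tau: float, label: str = "DsRed") -> ThresholdedMap:
    """Keep abundance strictly above τ; zero elsewhere.

    Strict inequality means τ = 0 excludes exact-zero background.
    """
    if not np.isfinite(tau):
        raise ValueError("threshold must be finite")
    abundance = maps.get(label)
    mask = abundance > tau
    return ThresholdedMap(float(tau), mask, np.where(mask, abundance, 0.0))


def render_overlay(
    tmap: ThresholdedMap,
    photo: np.ndarray,
    *,
    cmap: str = "hot",
    alpha: float = 0.7,
) -> np.ndarray:
    """Color-coded DsRed overlay on a grayscale photograph; RGB float array.

    Mirrors the instrument's display convention: intensity color-coded
    fluorescence on a white-light image.
    """
    import matplotlib

    photo = np.asarray(photo, dtype=float)
    span = photo.max() - photo.min()
    gray = (photo - photo.min()) / span if span > 0 else np.zeros_like(photo)
    rgb = np.repeat(gray[..., None], 3, axis=2)
    vmax = tmap.masked.max()
    if vmax > 0:
        intensity = tmap.masked / vmax
        colors = matplotlib.colormaps[cmap](intensity)[..., :3]
        w = alpha * tmap.mask[..., None]
        rgb = (1 - w) * rgb + w * colors
    return np.clip(rgb, 0.0, 1.0)
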