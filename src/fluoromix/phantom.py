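"""Synthetic multispectral phantoms and longitudinal mouse cohorts.

Every pipeline stage is validated against images with known ground truth.
A phantom image is built exactly on the linear mixing model the unmixing
assumes: per pixel, NFE signal = A(x)·a + D(x)·d, where A is a smooth
autofluorescence field (constant base plus random Gaussian bumps), D is a
localized Gaussian tumor inclusion, and a, d are unit-norm endmember
spectra.  Radiance is the NFE signal multiplied by the per-channel
excitation correction factors, so NFE correction inverts the synthesis
exactly in the noiseless case.  Noise models: none, additive Gaussian, or
Poisson photon counting (counts = radiance × gain, Poisson-drawn, rescaled).

Cohorts emulate a two-group subcutaneous tumor study: ~5×10⁵ reporter-labeled
cells injected on day 0, daily imaging, treatment on day 2 (or days 2/4/6),
5 animals per group.  Per-animal initial burden B₀ and growth rate g are
lognormal; treatment multiplies the growth rate by ρ ∈ [0, 1] from the first
dose onward (piecewise exponential, multiple doses do not compound ρ).

The default "true" spectra are plausible 4-channel shapes (autofluorescence
decaying across emission wavelength, the reporter peaked in the 570:620
channel).  They are simulator choices shipped as editable configuration, not
measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .quantify import AnimalRecord, CohortTable
from .spectra import RADIANCE, ChannelSet, Roi, SpectralStack, Spectrum, default_channelset

__all__ = [
    "PhantomConfig",
    "CohortConfig",
    "GroundTruthMaps",
    "SimulatedCohort",
    "generate_stack",
    "autofluorescence_field",
    "growth_model",
    "simulate_cohort",
]

# plausible 4-channel endmember shapes (unit-norm after normalization)
_DEFAULT_AUTOFLUOR = (0.62, 0.54, 0.45, 0.34)
_DEFAULT_DSRED = (0.05, 0.15, 0.35, 0.92)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass
class PhantomConfig:
    """Full parameterization of one synthetic spectral image."""

    height: int = 128
    width: int = 128
    channelset: ChannelSet = field(default_factory=default_channelset)
    autofluor_spectrum: tuple[float, ...] = _DEFAULT_AUTOFLUOR
    dsred_spectrum: tuple[float, ...] = _DEFAULT_DSRED
    min_angle_deg: float = 15.0
    # autofluorescence field: constant base plus smooth Gaussian bumps
    autofluor_base: float = 1.0
    n_bumps: int = 6
    bump_amplitude: tuple[float, float] = (0.25, 0.75)
    bump_width: tuple[float, float] = (10.0, 40.0)
    # localized tumor inclusion
    tumor_center: tuple[float, float] | None = None  # default: (0.45 H, 0.5 W)
    tumor_sigma: float = 8.0
    tumor_peak: float = 5.0
    # noise model: "none", "gaussian" (additive, noise_sigma) or
    # "poisson" (counts = radiance × poisson_gain, rescaled)
    noise_model: str = "poisson"
    noise_sigma: float = 0.01
    poisson_gain: float = 1e5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("phantom dimensions must be positive")
        L = len(self.channelset)
        a = _unit(self.autofluor_spectrum)
        d = _unit(self.dsred_spectrum)
        if a.size != L or d.size != L:
            raise ValueError("true spectra must match the channel count")
        angle = np.degrees(np.arccos(np.clip(a @ d, -1.0, 1.0)))
        if angle < self.min_angle_deg:
            raise ValueError(
                f"true spectra are nearly collinear ({angle:.2f}° < "
                f"{self.min_angle_deg}° minimum)"
            )
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.tumor_sigma <= 0 or self.tumor_peak < 0:
            raise ValueError("tumor sigma must be positive, peak non-negative")

    @property
    def true_autofluor(self) -> Spectrum:
        return Spectrum(_unit(self.autofluor_spectrum), "autofluorescence").unit()

    @property
    def true_dsred(self) -> Spectrum:
        return Spectrum(_unit(self.dsred_spectrum), "DsRed").unit()

    @property
    def center(self) -> tuple[float, float]:
        if self.tumor_center is not None:
            return self.tumor_center
        return (0.45 * self.height, 0.5 * self.width)


@dataclass
class GroundTruthMaps:
    """True abundance fields behind one generated stack."""

    autofluor_field: np.ndarray
    dsred_field: np.ndarray

    @property
    def integrated_dsred(self) -> float:
        return float(self.dsred_field.sum())


def autofluorescence_field(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth positive background field: base level + random Gaussian bumps."""
    h, w = config.height, config.width
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    A = np.full((h, w), config.autofluor_base)
    for _ in range(config.n_bumps):
        r0, c0 = rng.uniform(0, h), rng.uniform(0, w)
        amp = rng.uniform(*config.bump_amplitude)
        width = rng.uniform(*config.bump_width)
        A += amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * width**2))
    return A


def _tumor_field(config: PhantomConfig, scale: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : config.height, 0 : config.width].astype(float)
    r0, c0 = config.center
    return (
        config.tumor_peak
        * scale
        * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * config.tumor_sigma**2))
    )


def generate_stack(
    config: PhantomConfig,
    day_abundance_scale: float = 1.0,
    rng: np.random.Generator | None = None,
    autofluor: np.ndarray | None = None,
    metadata: dict | None = None,
) -> tuple[SpectralStack, GroundTruthMaps]:
    """Synthesize one radiance stack plus its ground-truth abundance maps.

    ``autofluor`` lets a caller reuse one background field across the days of
    an animal (the field is anatomical, not temporal); when omitted it is
    drawn from ``rng``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    a = config.true_autofluor.values
    d = config.true_dsred.values
    A = autofluor if autofluor is not None else autofluorescence_field(config, rng)
    if A.shape != (config.height, config.width):
        raise ValueError("autofluorescence field shape mismatch")
    D = _tumor_field(config, day_abundance_scale)
    nfe = A[None] * a[:, None, None] + D[None] * d[:, None, None]
    factors = config.channelset.correction_factors
    radiance = nfe * factors[:, None, None]
    if config.noise_model == "gaussian":
        radiance = radiance + rng.normal(0.0, config.noise_sigma, radiance.shape)
    elif config.noise_model == "poisson":
        g = config.poisson_gain
        radiance = rng.poisson(np.clip(radiance, 0.0, None) * g).astype(float) / g
    md = {"seed": config.seed, "noise_model": config.noise_model}
    if metadata:
        md.update(metadata)
    stack = SpectralStack(radiance, config.channelset, units=RADIANCE, metadata=md)
    return stack, GroundTruthMaps(A, D)


def growth_model(
    day: float,
    b0: float,
    g: float,
    rho: float = 1.0,
    dosing_days: tuple[int, ...] = (),
) -> float:
    """Piecewise-exponential burden: rate g before the first dose, ρ·g after.

    burden(t) = B₀ · exp(g·min(t, t₁) + ρ·g·max(0, t − t₁)) with t₁ the first
    dosing day; repeat doses maintain but do not compound the effect.
    """
    if day < 0:
        raise ValueError("day must be non-negative")
    if b0 < 0 or g < 0:
        raise ValueError("burden and growth rate must be non-negative")
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"treatment effect rho must lie in [0, 1], got {rho}")
    t1 = min(dosing_days) if dosing_days else np.inf
    pre = min(day, t1)
    post = max(0.0, day - t1)
    return float(b0 * np.exp(g * pre + rho * g * post))


@dataclass
class CohortConfig:
    """Two-group longitudinal study design with lognormal animal parameters."""

    n_per_group: int = 5
    days: tuple[int, ...] = tuple(range(8))  # daily imaging, day 0..7
    b0_median: float = 1.0  # initial burden scale (inoculum fluorescence)
    b0_sigma: float = 0.3  # lognormal sigma of B0
    growth_median: float = float(np.log(2))  # one doubling per day
    growth_sigma: float = 0.15
    treatment_effect: float = 0.3  # rho: growth-rate multiplier after dosing
    dosing_days: tuple[int, ...] = (2,)
    sacrifice_threshold: float | None = None  # burden cap; off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("need at least one animal per group")
        if not 0.0 <= self.treatment_effect <= 1.0:
            raise ValueError("treatment_effect must lie in [0, 1]")
        if self.dosing_days and not set(self.dosing_days) <= set(
            range(min(self.days), max(self.days) + 1)
        ):
            raise ValueError("dosing days must fall within the imaging window")


@dataclass
class SimulatedCohort:
    """Ground truth (and optionally rendered stacks) for one simulated study."""

    config: CohortConfig
    phantom_config: PhantomConfig
    params: pd.DataFrame  # animal_id, group, b0, growth_rate
    ground_truth: CohortTable  # true integrated DsRed abundance per animal-day
    #: animal_id -> {"pre": pre-injection stack, day: stack, ...}; None if not rendered
    stacks: dict[str, dict] | None = None
    truth_maps: dict[str, dict] | None = None

    @property
    def tumor_roi(self) -> Roi:
        cfg = self.phantom_config
        return Roi.disk(cfg.center, 0.75 * cfg.tumor_sigma)

    @property
    def background_roi(self) -> Roi:
        cfg = self.phantom_config
        return Roi.disk((0.12 * cfg.height, 0.2 * cfg.width), 6.0)


def simulate_cohort(
    cconfig: CohortConfig,
    pconfig: PhantomConfig | None = None,
    render: bool = False,
    keep_truth_maps: bool = False,
) -> SimulatedCohort:
    """Draw a full two-group cohort; optionally render every animal-day stack.

    Per-animal B₀ and g are lognormal around the configured medians; the
    treated group's growth rate is multiplied by ρ from the first dosing day
    onward.  The ground-truth table records the true integrated DsRed
    abundance (burden × integral of the unit tumor field).  With ``render``
    each animal also gets a pre-injection (tumor-free) stack used for
    background references and control thresholds.  Regeneration from the same
    configs and seed is deterministic.
    """
    if pconfig is None:
        pconfig = PhantomConfig()
    rng = np.random.default_rng(cconfig.seed)
    unit_integral = _tumor_field(pconfig, 1.0).sum()

    rows, animals = [], []
    stacks: dict[str, dict] = {}
    truth_maps: dict[str, dict] = {}
    for group in ("vehicle", "treated"):
        rho = cconfig.treatment_effect if group == "treated" else 1.0
        for i in range(cconfig.n_per_group):
            animal_id = f"{group[0]}{i + 1}"
            b0 = cconfig.b0_median * np.exp(rng.normal(0.0, cconfig.b0_sigma))
            g = cconfig.growth_median * np.exp(rng.normal(0.0, cconfig.growth_sigma))
            rows.append(
                {"animal_id": animal_id, "group": group, "b0": b0, "growth_rate": g}
            )
            measurements: dict[int, float] = {}
            sacrificed = False
            burdens: dict[int, float] = {}
            for day in cconfig.days:
                if sacrificed:
                    break
                burden = growth_model(day, b0, g, rho, cconfig.dosing_days)
                burdens[day] = burden
                measurements[day] = burden * unit_integral
                if (
                    cconfig.sacrifice_threshold is not None
                    and burden > cconfig.sacrifice_threshold
                ):
                    sacrificed = True  # last image on the crossing day
            animals.append(AnimalRecord(animal_id, group, measurements))
            if render:
                field_rng = np.random.default_rng(rng.integers(0, 2**31))
                A = autofluorescence_field(pconfig, field_rng)
                noise_rng = np.random.default_rng(rng.integers(0, 2**31))
                per_animal: dict = {}
                per_truth: dict = {}
                pre_stack, pre_truth = generate_stack(
                    pconfig,
                    0.0,
                    rng=noise_rng,
                    autofluor=A,
                    metadata={"animal": animal_id, "day": "pre"},
                )
                per_animal["pre"] = pre_stack
                per_truth["pre"] = pre_truth
                for day, burden in burdens.items():
                    per_animal[day], per_truth[day] = generate_stack(
                        pconfig,
                        burden,
                        rng=noise_rng,
                        autofluor=A,
                        metadata={"animal": animal_id, "day": day},
                    )
                    # table totals equal the rendered true-map sums exactly
                    measurements[day] = per_truth[day].integrated_dsred
                animals[-1] = AnimalRecord(animal_id, group, measurements)
                stacks[animal_id] = per_animal
                if keep_truth_maps:
                    truth_maps[animal_id] = per_truth

    params = pd.DataFrame(rows, columns=["animal_id", "group", "b0", "growth_rate"])
    truth_table = CohortTable(
        animals,
        metadata={
            "dosing_days": list(cconfig.dosing_days),
            "treatment_effect": cconfig.treatment_effect,
            "seed": cconfig.seed,
            "unit_tumor_integral": float(unit_integral),
        },
    )
    return SimulatedCohort(
        config=cconfig,
        phantom_config=pconfig,
        params=params,
        ground_truth=truth_table,
        stacks=stacks if render else None,
        truth_maps=truth_maps if keep_truth_maps else None,
    )


def null_cohort_config(seed: int, **overrides) -> CohortConfig:
    """A no-effect (ρ = 1) design: both groups share one growth law."""
    return replace(CohortConfig(seed=seed, treatment_effect=1.0), **overrides)
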