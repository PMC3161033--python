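"""File formats, pipeline configuration, manifests and the end-to-end run.

Stacks travel as multi-page 32-bit float TIFF plus a human-readable YAML
sidecar carrying the channel definitions, units and acquisition metadata
(sidecars rather than TIFF tags: provenance stays readable and independent
of tag dialects).  Spectra and ROIs are plain CSV; result tables CSV; the
manifest JSON with a SHA-256 checksum per artifact so reruns can be verified
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import quantify, stats, unmix
from .phantom import CohortConfig, PhantomConfig, SimulatedCohort, simulate_cohort
from .spectra import (
    NFE,
    RADIANCE,
    ChannelSet,
    Roi,
    SpectralChannel,
    SpectralStack,
    Spectrum,
    apply_nfe_correction,
    build_autofluorescence_reference,
    build_dsred_reference,
    extract_mean_spectrum,
)
from .unmix import SpectrumLibrary, compute_threshold, threshold_map, unmix_stack

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "read_stack",
    "write_stack",
    "spectrum_to_csv",
    "spectrum_from_csv",
    "write_outputs",
    "write_simulated_cohort",
    "read_simulated_cohort",
    "run_pipeline",
    "analyze_cohort",
]

logger = logging.getLogger("fluoromix")


# ---------------------------------------------------------------------------
# stack I/O


def write_stack(stack: SpectralStack, path, sidecar=None) -> None:
    """Multi-page float32 TIFF (one page per channel) + YAML sidecar."""
    path = Path(path)
    if sidecar is None:
        sidecar = path.with_suffix(".yaml")
    tifffile.imwrite(path, stack.data.astype(np.float32), photometric="minisblack")
    meta = {
        "units": stack.units,
        "channels": [
            {
                "ex_center": c.ex_center,
                "em_center": c.em_center,
                "ex_passband": c.ex_passband,
                "em_passband": c.em_passband,
                "correction_factor": c.correction_factor,
            }
            for c in stack.channelset
        ],
        "metadata": {k: _yaml_safe(v) for k, v in stack.metadata.items()},
    }
    Path(sidecar).write_text(yaml.safe_dump(meta, sort_keys=True))


def _yaml_safe(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def read_stack(path, sidecar=None) -> SpectralStack:
    """Read a stack; page count must match the sidecar's channel list.

    Pixel data are widened to float (at least 32-bit); NaN or infinite
    pixels make the load fail with the offending channel and pixel named.
    """
    path = Path(path)
    if sidecar is None:
        sidecar = path.with_suffix(".yaml")
    meta = yaml.safe_load(Path(sidecar).read_text())
    channels = ChannelSet(
        tuple(SpectralChannel(**entry) for entry in meta["channels"])
    )
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != len(channels):
        raise ValueError(
            f"{path.name}: {data.shape[0]} pages but sidecar defines "
            f"{len(channels)} channels"
        )
    return SpectralStack(
        data.astype(np.float64),
        channels,
        units=meta.get("units", RADIANCE),
        metadata=meta.get("metadata", {}) or {},
    )


def spectrum_to_csv(spectrum: Spectrum, channelset: ChannelSet, path) -> None:
    pd.DataFrame(
        {
            "channel_index": np.arange(len(spectrum)),
            "ex_center": [c.ex_center for c in channelset],
            "em_center": [c.em_center for c in channelset],
            "value": spectrum.values,
        }
    ).to_csv(path, index=False)


def spectrum_from_csv(path, label: str = "", normalized: bool = False) -> Spectrum:
    df = pd.read_csv(path).sort_values("channel_index")
    return Spectrum(df["value"].to_numpy(), label=label, normalized=normalized)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Resolved analysis parameters; unknown keys are rejected at load."""

    correction_factors: list[float] | None = None  # per channel; default all 1.0
    subtract_mode: str = "direct"  # DsRed reference background removal
    reference_day: int = 5  # day of the tumor-reference image
    threshold_k: float | None = 3.0  # control-derived tau = mean + k sd
    fixed_tau: float | None = None  # overrides threshold_k when set
    nonneg: bool = False  # NNLS instead of pseudo-inverse
    baseline_mode: str = "ratio"  # "ratio" | "difference" vs day 0
    baseline_day: int = 0
    eps: float = 1e-9  # zero-baseline guard for ratio mode
    stats_method: str = "ranksum"  # "ranksum" | "signedrank" | "auc"
    stats_mode: str = "auto"  # "auto" | "exact" | "normal"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subtract_mode not in ("direct", "projection"):
            raise ValueError(f"subtract_mode must be direct|projection, got {self.subtract_mode!r}")
        if self.baseline_mode not in ("ratio", "difference"):
            raise ValueError(f"baseline_mode must be ratio|difference, got {self.baseline_mode!r}")
        if self.fixed_tau is None and self.threshold_k is None:
            raise ValueError("set either threshold_k or fixed_tau")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


# ---------------------------------------------------------------------------
# manifest / outputs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(results: dict, outdir) -> dict:
    """Write artifacts into a deterministic layout and return the manifest.

    Dispatch by value type: DataFrame → tables/<name>.csv, float 2-D array →
    maps/<name>.tiff, bool 2-D array → maps/<name>.tiff (8-bit), RGB float
    array → figures/<name>.png, dict → <name>.json.  manifest.json lists
    every artifact with its SHA-256 checksum.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name in sorted(results):
        value = results[name]
        if isinstance(value, pd.DataFrame):
            rel = Path("tables") / f"{name}.csv"
            (outdir / rel).parent.mkdir(exist_ok=True)
            value.to_csv(outdir / rel, index=False, float_format="%.12g")
        elif isinstance(value, np.ndarray) and value.dtype == bool:
            rel = Path("maps") / f"{name}.tiff"
            (outdir / rel).parent.mkdir(exist_ok=True)
            tifffile.imwrite(outdir / rel, value.astype(np.uint8) * 255)
        elif isinstance(value, np.ndarray) and value.ndim == 3:
            rel = Path("figures") / f"{name}.png"
            (outdir / rel).parent.mkdir(exist_ok=True)
            import imageio.v3 as iio

            iio.imwrite(outdir / rel, (np.clip(value, 0, 1) * 255).astype(np.uint8))
        elif isinstance(value, np.ndarray):
            rel = Path("maps") / f"{name}.tiff"
            (outdir / rel).parent.mkdir(exist_ok=True)
            tifffile.imwrite(outdir / rel, value.astype(np.float32))
        elif isinstance(value, dict):
            rel = Path(f"{name}.json")
            (outdir / rel).write_text(json.dumps(value, indent=2, sort_keys=True, default=str))
        else:
            raise TypeError(f"no writer for artifact {name!r} of type {type(value)}")
        entries.append({"path": str(rel), "sha256": _sha256(outdir / rel)})
    manifest = {"artifacts": entries}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# simulated-cohort trees on disk


def write_simulated_cohort(sim: SimulatedCohort, outdir) -> None:
    """animal_<id>/{pre,day_<d>}.tiff trees + ground truth, ROIs and config."""
    if sim.stacks is None:
        raise ValueError("cohort was simulated without render=True; no stacks to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for animal_id, per_day in sim.stacks.items():
        adir = outdir / f"animal_{animal_id}"
        adir.mkdir(exist_ok=True)
        for key, stack in per_day.items():
            name = "pre" if key == "pre" else f"day_{key}"
            write_stack(stack, adir / f"{name}.tiff")
    sim.ground_truth.to_frame().to_csv(outdir / "ground_truth.csv", index=False)
    sim.params.to_csv(outdir / "params.csv", index=False)
    (outdir / "rois").mkdir(exist_ok=True)
    sim.background_roi.to_csv(outdir / "rois" / "background.csv")
    sim.tumor_roi.to_csv(outdir / "rois" / "tumor.csv")
    cfg = {"cohort": asdict(sim.config), "phantom": _phantom_dict(sim.phantom_config)}
    (outdir / "config.yaml").write_text(yaml.safe_dump(_yaml_clean(cfg), sort_keys=True))


def _phantom_dict(p: PhantomConfig) -> dict:
    d = asdict(p)
    d["channelset"] = [
        {
            "ex_center": c.ex_center,
            "em_center": c.em_center,
            "ex_passband": c.ex_passband,
            "em_passband": c.em_passband,
            "correction_factor": c.correction_factor,
        }
        for c in p.channelset
    ]
    return d


def _yaml_clean(obj):
    if isinstance(obj, dict):
        return {k: _yaml_clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_clean(v) for v in obj]
    return _yaml_safe(obj)


def read_simulated_cohort(indir) -> tuple[dict[str, dict], Roi, Roi]:
    """Load every stack of a simulated tree plus the stored reference ROIs."""
    indir = Path(indir)
    stacks: dict[str, dict] = {}
    for adir in sorted(indir.glob("animal_*")):
        animal_id = adir.name.removeprefix("animal_")
        per_day: dict = {}
        for tiff in sorted(adir.glob("*.tiff")):
            key = tiff.stem
            per_day["pre" if key == "pre" else int(key.removeprefix("day_"))] = read_stack(tiff)
        stacks[animal_id] = per_day
    background_roi = Roi.from_csv(indir / "rois" / "background.csv")
    tumor_roi = Roi.from_csv(indir / "rois" / "tumor.csv")
    return stacks, background_roi, tumor_roi


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineResult:
    cohort: quantify.CohortTable
    relative: quantify.CohortTable
    growth_curves: pd.DataFrame
    comparisons: pd.DataFrame
    libraries: dict[str, SpectrumLibrary] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    dsred_maps: dict = field(default_factory=dict)


def _group_of(animal_id: str) -> str:
    return "treated" if animal_id.startswith("t") else "vehicle"


def analyze_cohort(
    stacks: dict[str, dict],
    background_roi: Roi,
    tumor_roi: Roi,
    config: PipelineConfig | None = None,
    groups: dict[str, str] | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory stacks.

    ``stacks`` maps animal_id → {"pre": pre-injection radiance stack,
    day (int): radiance stack}.  Stage order: NFE correction → per-animal
    reference spectra (background from the pre-injection stack; reporter
    from the reference-day tumor ROI with the pre-injection contribution
    removed) → pseudo-inverse unmixing → control-derived thresholding on the
    pre-injection DsRed map → per-animal totals → day-0-normalized series →
    group growth curves → per-day two-group tests.
    """
    cfg = config or PipelineConfig()
    animals = []
    libraries: dict[str, SpectrumLibrary] = {}
    thresholds: dict[str, float] = {}
    dsred_maps: dict = {}
    for animal_id in sorted(stacks):
        per_day = stacks[animal_id]
        if "pre" not in per_day:
            raise ValueError(f"animal {animal_id}: missing pre-injection control stack")
        days = sorted(k for k in per_day if k != "pre")
        logger.info("animal %s: NFE correction and reference building", animal_id)
        nfe = {k: apply_nfe_correction(per_day[k]) for k in per_day}

        autofluor = build_autofluorescence_reference(nfe["pre"], background_roi)
        ref_day = cfg.reference_day if cfg.reference_day in days else days[-1]
        background = extract_mean_spectrum(nfe["pre"], tumor_roi)
        dsred = build_dsred_reference(
            nfe[ref_day],
            tumor_roi,
            autofluor,
            subtract_mode=cfg.subtract_mode,
            background=background,
        )
        library = SpectrumLibrary([autofluor, dsred])
        libraries[animal_id] = library

        control_maps = unmix_stack(nfe["pre"], library, nonneg=cfg.nonneg)
        if cfg.fixed_tau is not None:
            tau = cfg.fixed_tau
        else:
            tau = compute_threshold(control_maps.get("DsRed"), k=cfg.threshold_k)
        thresholds[animal_id] = tau
        logger.info("animal %s: tau = %.4g (reference day %s)", animal_id, tau, ref_day)

        measurements: dict[int, float] = {}
        for day in days:
            maps = unmix_stack(nfe[day], library, nonneg=cfg.nonneg)
            tmap = threshold_map(maps, tau)
            measurements[day] = quantify.total_dsred(tmap)
            dsred_maps[(animal_id, day)] = tmap
        group = (groups or {}).get(animal_id, _group_of(animal_id))
        animals.append(quantify.AnimalRecord(animal_id, group, measurements))

    cohort = quantify.CohortTable(animals, metadata={"seed": cfg.seed})
    relative = cohort.relative(
        baseline_day=cfg.baseline_day, eps=cfg.eps, mode=cfg.baseline_mode
    )
    growth = quantify.growth_curve_table(relative)
    comparisons = stats.compare_groups_by_day(
        relative, method=cfg.stats_method, mode=cfg.stats_mode, alpha=cfg.alpha
    )
    return PipelineResult(cohort, relative, growth, comparisons, libraries, thresholds, dsred_maps)


def run_pipeline(config: PipelineConfig, cohort_dir, outdir=None) -> PipelineResult:
    """Disk-to-disk run: read a simulated (or equivalently laid out) cohort
    tree, analyze it, and optionally write tables + manifest to ``outdir``."""
    logger.info("pipeline start: %s", asdict(config))
    stacks, background_roi, tumor_roi = read_simulated_cohort(cohort_dir)
    result = analyze_cohort(stacks, background_roi, tumor_roi, config)
    if outdir is not None:
        write_outputs(
            {
                "cohort": result.cohort.to_frame(),
                "relative_burden": result.relative.to_frame().rename(
                    columns={"total_dsred": "relative_burden"}
                ),
                "growth_curves": result.growth_curves,
                "comparisons": result.comparisons,
                "config": asdict(config),
            },
            outdir,
        )
    return result
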