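"""End-to-end orchestration: simulate -> render -> quantify -> fit -> compare.

A run is described by a YAML config (see :class:`RunConfig`); every
stage persists its outputs (populations CSV, TIFF frames, per-fibril
CSV, distribution CSV, fit JSON) under the output directory and is
skipped on rerun if its artifacts already exist, so runs are idempotent
and resumable. Per-stage, per-sample seeds are derived deterministically
from the master seed.

Two quantification routes exist: ``imaging: true`` renders AFM frames
and traces them (the full emulation), while ``imaging: false`` measures
the simulated populations directly (population-level analysis, used
when only the kinetics are of interest).
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .model import FragmentationFit, compare_fits, fit_fragmentation, mean_length_model
from .quantify import (
    DistributionSummary,
    LengthSample,
    build_distributions,
    flatten,
    segment_and_trace,
    traced_to_frame,
)
from .simulate import (
    DEFAULT_SCHEDULE,
    BreakageKernel,
    FibrilPopulation,
    FragmentationParams,
    apply_detection_limit,
    populations_from_csv,
    populations_to_csv,
    simulate_fragmentation,
)
from .synthesis import RenderConfig, lay_contours, read_heightmap, render_heightmap, write_heightmap

__all__ = ["SampleSpec", "RunConfig", "RunReport", "run_pipeline", "make_figures", "derive_seed"]

logger = logging.getLogger("fibrilfrag")
if not logger.handlers:
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


def derive_seed(master: int, *tags) -> int:
    """Deterministic per-stage/per-sample seed below 2**31."""
    key = ":".join([str(master), *map(str, tags)]).encode()
    return zlib.crc32(key) % (2**31 - 1)


@dataclass
class SampleSpec:
    """One fibril type in a run.

    ``truth`` carries simulator parameters; ``fit_only: true`` samples
    skip simulation and are included in comparisons with their given
    (gamma, alpha) as externally fitted parameters.
    """

    name: str
    gamma: float
    alpha: float
    fit_only: bool = False
    n_fibrils: int = 1500
    init_kind: str = "lognormal"        # or "monodisperse"
    init_median: float = 800.0          # nm (monodisperse: the length)
    init_sigma_log: float = 0.5         # lognormal sigma in ln-space
    height_mean: float = 7.8            # nm
    height_sd: float = 0.3              # nm
    clustering_strength: float = 0.0

    def validate(self) -> None:
        if not self.fit_only and self.n_fibrils <= 0:
            raise ValueError(f"sample {self.name!r}: n_fibrils must be > 0")
        if self.gamma <= 0 or self.alpha <= 0:
            raise ValueError(f"sample {self.name!r}: gamma and alpha must be > 0")
        if self.init_kind not in ("lognormal", "monodisperse"):
            raise ValueError(f"sample {self.name!r}: unknown init_kind {self.init_kind!r}")
        if self.height_mean <= 0:
            raise ValueError(f"sample {self.name!r}: height_mean must be > 0")

    def initial_population(self, seed: int) -> FibrilPopulation:
        rng = np.random.default_rng(seed)
        if self.init_kind == "monodisperse":
            lengths = np.full(self.n_fibrils, self.init_median)
        else:
            lengths = rng.lognormal(np.log(self.init_median), self.init_sigma_log, self.n_fibrils)
        heights = np.clip(rng.normal(self.height_mean, self.height_sd, self.n_fibrils), 0.5, None)
        return FibrilPopulation(time=0.0, lengths=lengths, heights=heights)


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    samples: list[SampleSpec]
    outdir: Path
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    seed: int = 0
    imaging: bool = False
    render: RenderConfig = field(default_factory=RenderConfig)
    frames_per_timepoint: int = 3
    fibrils_per_frame: int = 60
    deposition_margin: float = 800.0
    threshold: float | None = None
    bin_width: float = 25.0
    detection_limit: float = 10.0       # nm; population-route analogue of tracing limits
    kernel: BreakageKernel = field(default_factory=BreakageKernel)

    def validate(self) -> None:
        if not self.samples:
            raise ValueError("config must define at least one sample")
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("sample names must be unique")
        for s in self.samples:
            s.validate()
        sched = np.asarray(self.schedule, dtype=float)
        if np.any(np.diff(sched) <= 0) or np.any(sched < 0):
            raise ValueError("schedule must be strictly increasing and >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        samples = [SampleSpec(**s) for s in raw.pop("samples")]
        render = RenderConfig(**raw.pop("render", {}))
        kernel = BreakageKernel(**raw.pop("kernel", {}))
        outdir = path.parent / raw.pop("outdir", "run")
        schedule = tuple(raw.pop("schedule", DEFAULT_SCHEDULE))
        cfg = cls(samples=samples, outdir=outdir, schedule=schedule,
                  render=render, kernel=kernel, **raw)
        cfg.validate()
        return cfg


@dataclass
class RunReport:
    """Outputs of a full run plus a manifest of artifact hashes."""

    summaries: dict[str, list[DistributionSummary]]
    fits: dict[str, FragmentationFit]
    comparison: dict | None
    manifest: dict[str, str]

    def to_json(self, path) -> None:
        payload = {
            "fits": {k: f.to_dict() for k, f in self.fits.items()},
            "mean_lengths": {
                k: {str(s.time): s.mean_length for s in v} for k, v in self.summaries.items()
            },
            "mean_heights": {
                k: {str(s.time): s.mean_height for s in v} for k, v in self.summaries.items()
            },
            "manifest": self.manifest,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage for every sample; persist and hash artifacts."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    summaries: dict[str, list[DistributionSummary]] = {}
    fits: dict[str, FragmentationFit] = {}

    for spec in config.samples:
        if spec.fit_only:
            fits[spec.name] = FragmentationFit(
                params=FragmentationParams(gamma=spec.gamma, alpha=spec.alpha),
                se_gamma=np.nan, se_log10_alpha=np.nan, alpha_t={},
                residual_sd=np.nan, times_used=np.array([]), name=spec.name,
            )
            continue
        sdir = out / spec.name
        sdir.mkdir(exist_ok=True)

        # --- simulate ---------------------------------------------------
        pop_csv = sdir / "populations.csv"
        if pop_csv.exists():
            logger.info("[%s] simulate: reusing %s", spec.name, pop_csv)
            pops = populations_from_csv(pop_csv)
        else:
            seed = derive_seed(config.seed, "simulate", spec.name)
            logger.info("[%s] simulate: seed=%d n=%d", spec.name, seed, spec.n_fibrils)
            pop0 = spec.initial_population(derive_seed(config.seed, "init", spec.name))
            truth = FragmentationParams(gamma=spec.gamma, alpha=spec.alpha)
            sched = [t for t in config.schedule if t > 0]
            pops = [pop0] + simulate_fragmentation(
                pop0, truth, sched, kernel=config.kernel, seed=seed
            )
            populations_to_csv(
                pops, pop_csv,
                meta={"params": truth.to_dict(), "kernel": asdict(config.kernel), "seed": seed},
            )
        manifest[str(pop_csv)] = _sha256(pop_csv)

        # --- quantify (imaging or population route) ----------------------
        samples_t: list[LengthSample] = []
        summ_t: list[DistributionSummary] = []
        traced_frames = []
        for pop in pops:
            if config.imaging:
                sample, summ, paths = _quantify_imaged(spec, pop, config, sdir)
                for p in paths:
                    manifest[str(p)] = _sha256(p)
            else:
                kept = apply_detection_limit(pop, config.detection_limit)
                traced = None
                sample = LengthSample(
                    time=pop.time, lengths=kept.lengths,
                    weights=np.ones(len(kept)), heights=kept.heights,
                )
                from .quantify import DistributionSummary as _DS  # local alias

                edges = np.arange(
                    0.0,
                    (np.ceil(kept.lengths.max() / config.bin_width) + 1) * config.bin_width
                    if len(kept) else config.bin_width * 2,
                    config.bin_width,
                )
                hist, _ = np.histogram(kept.lengths, bins=edges)
                dens = hist / max(1, len(kept)) / config.bin_width
                summ = _DS(
                    time=pop.time, bin_edges=edges, density=dens,
                    cdf=np.concatenate([[0.0], np.cumsum(hist) / max(1, len(kept))]),
                    mean_length=float(kept.lengths.mean()) if len(kept) else np.nan,
                    mean_height=float(kept.heights.mean()) if len(kept) else np.nan,
                    sem_height=float(kept.heights.std(ddof=1) / np.sqrt(len(kept)))
                    if len(kept) > 1 else np.nan,
                    count=len(kept),
                )
            samples_t.append(sample)
            summ_t.append(summ)
            traced_frames.append(
                pd.DataFrame(
                    {"time_s": sample.time, "contour_length_nm": sample.lengths,
                     "mean_height_nm": sample.heights, "weight": sample.weights}
                )
            )
        traced_csv = sdir / "measured.csv"
        if not traced_csv.exists():
            pd.concat(traced_frames, ignore_index=True).to_csv(traced_csv, index=False)
        manifest[str(traced_csv)] = _sha256(traced_csv)
        dist_csv = sdir / "distributions.csv"
        if not dist_csv.exists():
            _write_distributions(summ_t, dist_csv)
        manifest[str(dist_csv)] = _sha256(dist_csv)
        summaries[spec.name] = summ_t

        # --- fit ----------------------------------------------------------
        fit_json = sdir / "fit.json"
        fit = fit_fragmentation([s for s in samples_t if s.time > 0], name=spec.name)
        fit.to_json(fit_json)
        manifest[str(fit_json)] = _sha256(fit_json)
        fits[spec.name] = fit
        logger.info(
            "[%s] fit: gamma=%.3g alpha=%.3g t_s=%g", spec.name,
            fit.params.gamma, fit.params.alpha, fit.params.t_s,
        )

    comparison = None
    if len(fits) >= 2:
        comparison = compare_fits(fits)
        cmp_csv = out / "comparison.csv"
        comparison["table"].to_csv(cmp_csv, index=False)
        comparison["summary"].to_csv(out / "comparison_summary.csv")
        manifest[str(cmp_csv)] = _sha256(cmp_csv)

    report = RunReport(summaries=summaries, fits=fits, comparison=comparison, manifest=manifest)
    report.to_json(out / "report.json")
    return report


def _quantify_imaged(spec: SampleSpec, pop: FibrilPopulation, config: RunConfig, sdir: Path):
    """Render frames for one time point, flatten, trace, pool samples."""
    paths = []
    pooled = []
    rng = np.random.default_rng(derive_seed(config.seed, "deposit", spec.name, pop.time))
    for frame in range(config.frames_per_timepoint):
        tif = sdir / f"frame_t{pop.time:g}_{frame}.tif"
        if tif.exists():
            hmap = read_heightmap(tif)
        else:
            k = min(config.fibrils_per_frame, len(pop))
            idx = rng.choice(len(pop), size=k, replace=False)
            sub = FibrilPopulation(
                time=pop.time, lengths=pop.lengths[idx],
                heights=pop.heights[idx], lineages=pop.lineages[idx],
            )
            cfg = config.render
            if spec.clustering_strength != cfg.clustering_strength:
                cfg = RenderConfig(**{**asdict(cfg), "clustering_strength": spec.clustering_strength})
            contours = lay_contours(
                sub, cfg,
                seed=derive_seed(config.seed, "lay", spec.name, pop.time, frame),
                deposition_margin=config.deposition_margin,
            )
            hmap = render_heightmap(
                contours, cfg, seed=derive_seed(config.seed, "render", spec.name, pop.time, frame)
            )
            write_heightmap(hmap, tif)
        paths.append(tif)
        flat = flatten(hmap)
        traced = segment_and_trace(flat, threshold=config.threshold)
        pooled.extend(traced)
    sample, summ = build_distributions(
        pooled, config.render.scan_size, bin_width=config.bin_width, time=pop.time
    )
    tcsv = sdir / f"traced_t{pop.time:g}.csv"
    if not tcsv.exists():
        traced_to_frame(pooled, pop.time, config.render.scan_size).to_csv(tcsv, index=False)
    paths.append(tcsv)
    return sample, summ, paths


def _write_distributions(summaries: list[DistributionSummary], path: Path) -> None:
    rows = []
    for s in summaries:
        for i in range(len(s.density)):
            rows.append(
                {"time_s": s.time, "bin_left_nm": s.bin_edges[i],
                 "bin_right_nm": s.bin_edges[i + 1], "density": s.density[i],
                 "cdf": s.cdf[i + 1]}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Figures

def make_figures(report: RunReport, outdir) -> list[Path]:
    """Emit figure files: per-sample histogram/CDF/height panels sharing
    axes across time points, a log-log mean-length decay with best-fit
    lines (thick beyond t_s), and — when at least two fits exist — the
    B(x) comparison curves."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    for name, summs in report.summaries.items():
        fig, ax = plt.subplots(figsize=(6, 4))
        for s in summs:
            mids = 0.5 * (s.bin_edges[:-1] + s.bin_edges[1:])
            ax.plot(mids, s.density, label=f"{s.time:g} s", drawstyle="steps-mid")
        ax.set(xlabel="length (nm)", ylabel="density (1/nm)", title=f"{name}: length distributions")
        ax.legend(fontsize=7)
        files.append(_save(fig, out / f"{name}_length_hist.png"))

        fig, ax = plt.subplots(figsize=(6, 4))
        for s in summs:
            ax.plot(s.bin_edges, s.cdf, label=f"{s.time:g} s")
        ax.set(xlabel="length (nm)", ylabel="CDF", title=f"{name}: cumulative distributions")
        ax.legend(fontsize=7)
        files.append(_save(fig, out / f"{name}_length_cdf.png"))

        fig, ax = plt.subplots(figsize=(6, 4))
        times = [s.time for s in summs]
        mh = [s.mean_height for s in summs]
        sem = [s.sem_height for s in summs]
        ax.errorbar(times, mh, yerr=sem, fmt="o-")
        ax.set(xlabel="sonication time (s)", ylabel="mean height (nm)",
               title=f"{name}: height stationarity")
        files.append(_save(fig, out / f"{name}_heights.png"))

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, summs in report.summaries.items():
        ts = np.array([s.time for s in summs if s.time > 0])
        mus = np.array([s.mean_length for s in summs if s.time > 0])
        ax.loglog(ts, mus, "+", label=name)
        fit = report.fits.get(name)
        if fit is not None and fit.params.C is not None:
            tt = np.geomspace(ts.min(), ts.max(), 100)
            mm = mean_length_model(tt, fit.params)
            thick = tt > fit.params.t_s
            ax.loglog(tt[~thick], mm[~thick], "-", lw=0.8, color=ax.lines[-1].get_color())
            ax.loglog(tt[thick], mm[thick], "-", lw=2.2, color=ax.lines[-1].get_color())
    ax.set(xlabel="sonication time (s)", ylabel="mean length (nm)", title="mean-length decay")
    ax.legend(fontsize=8)
    files.append(_save(fig, out / "decay_loglog.png"))

    if len(report.fits) >= 2:
        fig, ax = plt.subplots(figsize=(6, 4))
        x = np.geomspace(10, 1000, 100)
        for name, fit in report.fits.items():
            ax.loglog(x, fit.rate(x), label=name, lw=2)
        ax.set(xlabel="fibril length x (nm)", ylabel="B(x) (1/s)",
               title="fragmentation rate constants")
        ax.legend(fontsize=8)
        files.append(_save(fig, out / "rate_constants.png"))
    return files


def _save(fig, path: Path) -> Path:
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
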