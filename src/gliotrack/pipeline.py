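"""End-to-end reproducible run: simulate -> (image -> detect -> link) ->
filter -> per-track metrics -> distributions -> group statistics -> report.

The default path feeds simulated trajectories straight into the metrics
stage; rendering movies and re-tracking them is opt-in (``use_imaging``),
since detection noise belongs to front-end validation rather than to the
motion statistics themselves.  Every source of randomness funnels through
one seeded generator, so a config + seed pair fixes the report byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detect as _detect
from . import distributions as _dist
from . import metrics as _metrics
from . import simulate as _sim
from . import stats as _stats
from .io import TrackSet, write_tracks_csv

logger = logging.getLogger("gliotrack")

__all__ = ["PipelineConfig", "run_pipeline", "emit_report", "make_plots"]


@dataclass
class PipelineConfig:
    stages: tuple[str, ...] = ("OPC", "eOL", "mOL")
    n_cells: int = 10
    n_tracks: int = 1300  # simulated per cell, pre-filter
    seed: int = 0
    use_imaging: bool = False
    image_shape: tuple[int, int] = (128, 128)
    confinement_mode: str = "as_printed"
    min_frames: int = 10
    max_disp_px: float = 3.0
    n_confinement_bins: int = 10
    n_diffusion_bins: int = 12
    # category boundaries (1-based bin indices): the D distribution is
    # extremely right-skewed, so equal thirds of the linear range would label
    # almost nothing "fast"; bins 1-2 cover the slow bulk, 3-4 intermediate,
    # 5-12 fast, aligning the color groups with the mobility subpopulations
    diffusion_category_boundaries: tuple[int, int] = (2, 4)
    confinement_category_boundaries: tuple[int, int] | None = None
    drop_first_diffusion_bin: bool = True
    alpha: float = 0.05
    q: float = 4.0
    # lag cap (s) for per-track D: long-lag MSDs are few-sample and, for
    # drift-dominated tracks, grow quadratically, so they would otherwise
    # dominate a pooled-range binning; 10 lags is standard SPT practice
    max_lag_s: float | None = 0.3
    out_dir: str | None = None
    plots: bool = False

    def analysis_params(self) -> dict:
        """Config fields that define the analysis (output location excluded,
        so reports are byte-identical wherever they are written)."""
        d = asdict(self)
        d.pop("out_dir")
        d.pop("plots")
        return d

    def hash(self) -> str:
        blob = json.dumps(self.analysis_params(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _to_plain(obj):
    """Recursively convert numpy scalars/arrays and dataclasses for JSON."""
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return _to_plain(asdict(obj))
    return obj


def _simulate_cell(stage: str, cell_idx: int, cfg: PipelineConfig, cell_seed: int) -> TrackSet:
    sim_cfg = _sim.stage_preset(stage, n_tracks=cfg.n_tracks, seed=cell_seed)
    sim_cfg.cell_id = f"{stage}_{cell_idx:02d}"
    ts = _sim.simulate_tracks(sim_cfg)
    if cfg.use_imaging:
        # translate the field of view so every point sits inside the image
        # (disc geometries are centred on the origin); metrics are
        # translation-invariant so this is free
        all_min = np.min([t.xy.min(axis=0) for t in ts.tracks], axis=0)
        margin = 8 * ts.pixel_size
        for t in ts.tracks:
            t.xy = t.xy - all_min + margin
        psf = _sim.PSFModel()
        stack = _sim.render_movie(ts, psf, cfg.image_shape, seed=cell_seed + 1)
        dets = _detect.detect_stack(stack)
        ts = _detect.link_spots(
            dets,
            _detect.LinkParams(max_disp_px=cfg.max_disp_px, min_frames=cfg.min_frames),
            frame_interval=ts.frame_interval,
            pixel_size=ts.pixel_size,
        )
        ts.cell_id = sim_cfg.cell_id
        ts.stage = stage
    return ts


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and return the stage report (JSON-serializable).

    The report mirrors a summary-statistics table (n, median, IQR, median CI
    per group and metric) plus a hypothesis-test table (KW + Dunn on
    cell-level replicates; pairwise two-sample KS on particle-level
    replicates at a Bonferroni-corrected alpha) and the binned frequency
    distributions with category labels.
    """
    rng = np.random.default_rng(config.seed)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    per_cell_rows = []
    particle_frames: dict[str, list[pd.DataFrame]] = {s: [] for s in config.stages}
    counts = {s: {"n_tracks_pre": 0, "n_tracks_post": 0} for s in config.stages}
    example_tracksets: dict[str, TrackSet] = {}

    for stage in config.stages:
        for ci in range(config.n_cells):
            cell_seed = int(rng.integers(0, 2**31 - 1))
            ts = _simulate_cell(stage, ci, config, cell_seed)
            counts[stage]["n_tracks_pre"] += len(ts)
            ts = _detect.filter_tracks(ts, _detect.LinkParams(min_frames=config.min_frames))
            counts[stage]["n_tracks_post"] += len(ts)
            if len(ts) == 0:
                raise RuntimeError(f"stage {stage}, cell {ci}: no tracks survived filtering")
            example_tracksets.setdefault(stage, ts)

            df = _metrics.trackset_metrics(
                ts, q=config.q, confinement_mode=config.confinement_mode,
                max_lag=config.max_lag_s,
            )
            particle_frames[stage].append(df)
            profile = _metrics.motion_profile(ts)
            per_cell_rows.append(
                {
                    "stage": stage,
                    "cell_id": ts.cell_id,
                    "n_tracks": len(ts),
                    "r_circ": profile.r_circ,
                    "median_confinement": float(df["confinement"].median()),
                    "median_D": float(df["D"].median()),
                }
            )
            if out_dir:
                write_tracks_csv(ts, out_dir / f"tracks_{ts.cell_id}.csv")
            logger.info("stage %s cell %d: %d tracks post-filter", stage, ci, len(ts))

    cells = pd.DataFrame(per_cell_rows)
    particles = {s: pd.concat(fs, ignore_index=True) for s, fs in particle_frames.items()}

    # --- distributions over pooled-range bins ------------------------------
    pooled_conf = np.concatenate([particles[s]["confinement"].to_numpy() for s in config.stages])
    pooled_D = np.concatenate([particles[s]["D"].to_numpy() for s in config.stages])
    conf_scheme = _dist.assign_categories(
        _dist.pooled_range_bins(pooled_conf, config.n_confinement_bins),
        boundaries=config.confinement_category_boundaries,
        labels=("highly_confined", "moderately_confined", "lightly_confined"),
    )
    d_scheme = _dist.assign_categories(
        _dist.pooled_range_bins(pooled_D, config.n_diffusion_bins),
        boundaries=config.diffusion_category_boundaries,
        labels=("slow", "intermediate", "fast"),
    )

    dists = {"confinement": {}, "D": {}}
    fast_fraction = {}
    for s in config.stages:
        dists["confinement"][s] = _dist.frequency_distribution(
            particles[s]["confinement"], conf_scheme
        )
        fd = _dist.frequency_distribution(
            particles[s]["D"], d_scheme, drop_first_bin=config.drop_first_diffusion_bin
        )
        dists["D"][s] = fd
        fast_bins = [i for i, lab in d_scheme.categories.items() if lab == "fast"]
        fast_fraction[s] = float(fd.percent[fast_bins].sum() / 100.0)

    # --- summaries ----------------------------------------------------------
    summaries: dict = {}
    for s in config.stages:
        cell_s = cells[cells.stage == s]
        summaries[s] = {
            "n_cells": int(len(cell_s)),
            "n_tracks_pre": counts[s]["n_tracks_pre"],
            "n_tracks_post": counts[s]["n_tracks_post"],
            "circularity": _stats.group_summary(cell_s["r_circ"]),
            "cell_median_confinement": _stats.group_summary(cell_s["median_confinement"]),
            "cell_median_D": _stats.group_summary(cell_s["median_D"]),
            "particle_confinement": _stats.group_summary(particles[s]["confinement"]),
            "particle_D": _stats.group_summary(particles[s]["D"]),
        }

    # --- hypothesis tests ----------------------------------------------------
    tests: dict = {}
    if len(config.stages) >= 2:
        alpha_ks = _stats.bonferroni_alpha(config.alpha, 2)  # 2 comparisons per sample
        labels = list(config.stages)

        # cell-level KW + Dunn (cells as replicates)
        for metric, col in (
            ("circularity", "r_circ"),
            ("confinement", "median_confinement"),
            ("D", "median_D"),
        ):
            groups = [cells[cells.stage == s][col].to_numpy() for s in labels]
            kw = _stats.kruskal_wallis(groups)
            dunn = _stats.dunns_posthoc(groups, labels=labels, alpha=config.alpha)
            tests[f"cell_{metric}"] = {
                "kruskal_wallis": kw,
                "dunn": {f"{a}_vs_{b}": r for (a, b), r in dunn.items()},
            }

        # particle-level pairwise KS (tracks as replicates)
        for metric in ("confinement", "D"):
            pair_res = {}
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    a, b = labels[i], labels[j]
                    pair_res[f"{a}_vs_{b}"] = _stats.ks_two_sample(
                        particles[a][metric], particles[b][metric],
                        alpha=alpha_ks, corrected=True,
                    )
            tests[f"particle_{metric}_ks"] = pair_res

    report = {
        "seed": config.seed,
        "config": config.analysis_params(),
        "config_hash": config.hash(),
        "confinement_mode": config.confinement_mode,
        "stages": summaries,
        "per_cell": per_cell_rows,
        "tests": tests,
        "fast_fraction": fast_fraction,
        "distributions": {
            q: {
                s: {
                    "edges": d.scheme.edges,
                    "percent": d.percent,
                    "n_total": d.n_total,
                    "categories": d.scheme.categories,
                    "drop_first_bin": d.drop_first_bin,
                }
                for s, d in per_stage.items()
            }
            for q, per_stage in dists.items()
        },
    }
    report = _to_plain(report)

    if out_dir:
        emit_report(report, "json", out_dir / "report.json")
        emit_report(report, "markdown", out_dir / "report.md")
        for s, df in particles.items():
            df.to_csv(out_dir / f"metrics_{s}.csv", index=False)
        if config.plots:
            make_plots(report, example_tracksets, out_dir / "plots")
    return report


def emit_report(report: dict, fmt: str, path: str | Path) -> Path:
    """Write the report as machine JSON or human Markdown (same numbers)."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
    elif fmt in ("md", "markdown"):
        path.write_text(_render_markdown(report))
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return path


def _g6(x: float) -> str:
    return f"{float(x):.6g}"


def _render_markdown(report: dict) -> str:
    lines = [
        "# gliotrack stage report",
        "",
        f"- seed: {report['seed']}",
        f"- config hash: {report['config_hash']}",
        f"- confinement mode: {report['confinement_mode']}",
        "",
        "## Descriptive statistics (per stage)",
        "",
        "| stage | metric | n | median | Q1 | Q3 | CI95 lo | CI95 hi |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for s, summ in report["stages"].items():
        for metric in (
            "circularity",
            "cell_median_confinement",
            "cell_median_D",
            "particle_confinement",
            "particle_D",
        ):
            g = summ[metric]
            lines.append(
                f"| {s} | {metric} | {g['n']} | {_g6(g['median'])} | {_g6(g['q1'])} "
                f"| {_g6(g['q3'])} | {_g6(g['ci95_lo'])} | {_g6(g['ci95_hi'])} |"
            )
    if report.get("tests"):
        lines += ["", "## Hypothesis tests", ""]
        for name, block in report["tests"].items():
            if "kruskal_wallis" in block:
                kw = block["kruskal_wallis"]
                lines.append(
                    f"- **{name}** KW H = {_g6(kw['statistic'])}, df = {kw['df']}, "
                    f"p = {_g6(kw['p_value'])}"
                )
                for pair, r in block["dunn"].items():
                    lines.append(
                        f"    - Dunn {pair}: z = {_g6(r['statistic'])}, "
                        f"adj. p = {_g6(r['p_value'])}"
                    )
            else:
                for pair, r in block.items():
                    lines.append(
                        f"- **{name}** {pair}: D = {_g6(r['statistic'])}, "
                        f"p = {_g6(r['p_value'])} (alpha = {_g6(r['alpha_used'])})"
                    )
    lines += ["", "## Fast-category particle fraction", ""]
    for s, f in report["fast_fraction"].items():
        lines.append(f"- {s}: {_g6(f)}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def make_plots(report: dict, tracksets: dict[str, TrackSet], out_dir: str | Path) -> None:
    """Motion profiles, vector diagrams, histograms, ECDFs and MSD curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(tracksets)

    fig, axes = plt.subplots(1, len(stages), figsize=(4 * len(stages), 4))
    for ax, s in zip(np.atleast_1d(axes), stages):
        prof = _metrics.motion_profile(tracksets[s])
        ax.plot(prof.zeroed_points[:, 0], prof.zeroed_points[:, 1], ".", ms=1, alpha=0.3)
        if prof.outline is not None:
            v = np.array(prof.outline.vertices + (prof.outline.vertices[0],))
            ax.plot(v[:, 0], v[:, 1], "r-", lw=1)
        ax.set_title(f"{s} motion profile (r_circ={prof.r_circ:.2f})")
        ax.set_aspect("equal")
    fig.savefig(out / "motion_profiles.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(
        1, len(stages), figsize=(4 * len(stages), 4), subplot_kw={"projection": "polar"}
    )
    for ax, s in zip(np.atleast_1d(axes), stages):
        vd = _metrics.direction_vectors(tracksets[s])
        theta = np.arange(vd.n_sectors) * 2 * np.pi / vd.n_sectors
        ax.bar(theta, vd.sector_mass, width=2 * np.pi / vd.n_sectors, alpha=0.7)
        ax.set_title(f"{s} net-displacement vectors")
    fig.savefig(out / "vector_diagrams.png", dpi=120)
    plt.close(fig)

    for quantity in ("confinement", "D"):
        fig, ax = plt.subplots(figsize=(6, 4))
        for s in stages:
            d = report["distributions"][quantity][s]
            edges = np.asarray(d["edges"])
            pct = np.asarray(d["percent"])
            if d["drop_first_bin"]:
                edges, pct = edges[1:], pct[1:]
            centers = 0.5 * (edges[:-1] + edges[1:])
            ax.plot(centers, pct, "o-", label=s)
        ax.set_xlabel(quantity)
        ax.set_ylabel("% of particle population")
        if quantity == "D":
            ax.set_yscale("log")
        ax.legend()
        fig.savefig(out / f"hist_{quantity}.png", dpi=120)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for s in stages:
        ts = tracksets[s]
        vals = np.array(
            [
                _metrics.diffusion_coefficient(_metrics.msd_curve(t, ts.frame_interval))
                for t in ts
            ]
        )
        e = _dist.ecdf(vals)
        xs = np.sort(vals)
        ax.step(xs, e(xs), where="post", label=s)
    ax.set_xlabel("D (um^2/s)")
    ax.set_ylabel("cumulative frequency")
    ax.legend()
    fig.savefig(out / "ecdf_D.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, len(stages), figsize=(4 * len(stages), 4), sharey=True)
    for ax, s in zip(np.atleast_1d(axes), stages):
        ts = tracksets[s]
        for t in list(ts)[:30]:
            c = _metrics.msd_curve(t, ts.frame_interval)
            ax.plot(c.lags, c.msd, "-", lw=0.6, alpha=0.6)
        ax.set_title(f"{s} MSD vs time")
        ax.set_xlabel("lag (s)")
    np.atleast_1d(axes)[0].set_ylabel("MSD (um^2)")
    fig.savefig(out / "msd_curves.png", dpi=120)
    plt.close(fig)
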