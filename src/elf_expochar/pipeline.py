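"""End-to-end orchestration: simulate/load -> clean -> segment -> KDE -> compare.

One RunConfig drives the whole chain with a single master seed; per-stage
generators are fanned out from it, so re-running a config reproduces every
numeric output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison, density, segmentation, synthetic
from .recordings import (
    ExclusionRules,
    apply_exclusions,
    extract_full_days,
    read_recording,
)

logger = logging.getLogger(__name__)


@dataclass
class SegmentationSettings:
    penalty: float | None = None  # None -> 3*log(n) per day
    min_seg_len: int = segmentation.DEFAULT_MIN_SEG_LEN


@dataclass
class ComparisonSettings:
    m: int = 200
    reps: int = 3000
    B: int = 999
    standardize: bool = True
    fdr_lambda: float = 0.5
    fdr_threshold: float = 0.05


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    seed: int = 0
    fixtures_dir: str | None = None           # read a written cohort ...
    cohort: synthetic.CohortSpec | None = None  # ... or simulate one
    segmentation: SegmentationSettings = field(default_factory=SegmentationSettings)
    comparison: ComparisonSettings = field(default_factory=ComparisonSettings)
    compare_dimensions: tuple[str, ...] = ("daynight",)
    exclude_alarm_clock_near: bool = True
    min_pool: int = 20  # skip comparisons when a level has fewer events
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, klass in (("segmentation", SegmentationSettings),
                           ("comparison", ComparisonSettings)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        if raw.get("cohort") is not None and isinstance(raw["cohort"], dict):
            raw["cohort"] = synthetic.CohortSpec.from_dict(raw["cohort"])
        if "compare_dimensions" in raw:
            raw["compare_dimensions"] = tuple(raw["compare_dimensions"])
        return cls(**raw)


def _load_days(config: RunConfig) -> list:
    """Collect cleaned DayRecordings from fixtures or a simulated cohort."""
    rules = ExclusionRules(exclude_alarm_clock_near=config.exclude_alarm_clock_near)
    if config.fixtures_dir is not None:
        root = Path(config.fixtures_dir)
        with open(root / "manifest.json") as fh:
            manifest = json.load(fh)
        meta = pd.read_csv(root / manifest["metadata"]).set_index("subject_id")
        recs = []
        for rel in manifest["recordings"]:
            sid = Path(rel).stem.rsplit("_day", 1)[0]
            row = meta.loc[sid].to_dict()
            row["subject_id"] = sid
            recs.append(read_recording(root / rel, metadata=row))
        recs = apply_exclusions(recs, rules)
        days = []
        for rec in recs:
            days.extend(extract_full_days(rec))
        return days
    if config.cohort is None:
        raise ValueError("config needs either fixtures_dir or a cohort spec")
    days = []
    for meta, _d, _plan, day in synthetic.generate_cohort(config.cohort):
        if config.exclude_alarm_clock_near and meta.get("alarm_clock_near"):
            continue
        days.append(day)
    return days


def segment_days(days, settings: SegmentationSettings) -> list[segmentation.Event]:
    events: list[segmentation.Event] = []
    for day in days:
        seg = segmentation.pelt(day.values, penalty=settings.penalty,
                                min_seg_len=settings.min_seg_len)
        events.extend(segmentation.extract_events(day, seg))
    return events


def summarize_events(events_df: pd.DataFrame) -> pd.DataFrame:
    """Segment counts per (dimension, level, day/night)."""
    rows = []
    col_of = {"daynight": "daynight", "age": "age_group",
              "inhabitants": "inhabitants_group", "substation": "substation_group"}
    for dim, col in col_of.items():
        if col not in events_df.columns:
            continue
        sub = events_df[events_df[col] != ""]
        if dim == "daynight":
            for level, n in sub[col].value_counts().items():
                rows.append({"dimension": dim, "level": level, "daynight": level, "n_segments": int(n)})
            continue
        for (level, dn), n in sub.groupby([col, "daynight"]).size().items():
            rows.append({"dimension": dim, "level": level, "daynight": dn, "n_segments": int(n)})
    return pd.DataFrame(rows, columns=["dimension", "level", "daynight", "n_segments"])


_PARAM_COLS = ["mu_uT", "sigma2_uT2", "phi", "T_s"]


def _pools_for_dimension(events_df: pd.DataFrame, dim: str) -> dict[str, np.ndarray]:
    col = {"daynight": "daynight", "age": "age_group",
           "inhabitants": "inhabitants_group", "substation": "substation_group"}[dim]
    pools = {}
    for level, grp in events_df[events_df[col] != ""].groupby(col):
        pools[str(level)] = grp[_PARAM_COLS].to_numpy(dtype=float)
    return pools


def _write_kde(model: density.KDEModel, stem: Path) -> None:
    frames = []
    for name in model.dim_names:
        curve = density.marginal_density(model, name)
        frames.append(pd.DataFrame({"dim": name, "x": curve.grid, "density": curve.density}))
    pd.concat(frames).to_csv(stem.with_suffix(".csv"), index=False, float_format="%.8g")
    sidecar = {
        "n": model.n,
        "bandwidths": {name: (None if np.isnan(h) else float(h))
                       for name, h in zip(model.dim_names, model.bandwidths)},
        "transforms": dict(zip(model.dim_names, model.transforms)),
        "dirac": {name: [[float(a), float(b)] for a, b in model.dirac[j]]
                  for j, name in enumerate(model.dim_names)},
        "n_smooth": {name: model.n_smooth(name) for name in model.dim_names},
    }
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and write all artifacts; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "settings": {
        "segmentation": dataclasses.asdict(config.segmentation),
        "comparison": dataclasses.asdict(config.comparison),
        "compare_dimensions": list(config.compare_dimensions),
    }, "outputs": []}

    current_stage = ["start"]

    def stage(name):
        current_stage[0] = name
        logger.info("stage: %s", name)

    try:
        stage("load")
        days = _load_days(config)
        if not days:
            raise ValueError("no complete days after cleaning")
        stage("segment")
        events = segment_days(days, config.segmentation)
        events_df = segmentation.events_to_frame(events)
        events_df.to_csv(out / "events.csv", index=False, float_format="%.12g")
        manifest["outputs"].append("events.csv")
        manifest["n_days"] = len(days)
        manifest["n_events"] = len(events_df)

        stage("summarize")
        summary = summarize_events(events_df)
        summary.to_csv(out / "summary.csv", index=False)
        manifest["outputs"].append("summary.csv")

        stage("density")
        kde_dir = out / "kde"
        kde_dir.mkdir(exist_ok=True)
        n_bundles = 0
        for dim in config.compare_dimensions:
            for level, pool in _pools_for_dimension(events_df, dim).items():
                if pool.shape[0] < 2:
                    continue
                model = density.fit_kde(pool)
                safe = level.replace(" ", "_").replace("/", "-")
                _write_kde(model, kde_dir / f"{dim}_{safe}")
                manifest["outputs"].append(f"kde/{dim}_{safe}.csv")
                n_bundles += 1
        manifest["n_kde_bundles"] = n_bundles

        stage("compare")
        cmp_dir = out / "compare"
        cmp_dir.mkdir(exist_ok=True)
        cs = config.comparison
        comparisons = []
        seeds = np.random.SeedSequence(config.seed).spawn(1)[0]
        rng = np.random.default_rng(seeds)
        for dim in config.compare_dimensions:
            pools = _pools_for_dimension(events_df, dim)
            levels = sorted(pools)
            for i, a in enumerate(levels):
                for b in levels[i + 1:]:
                    if min(pools[a].shape[0], pools[b].shape[0]) < config.min_pool:
                        logger.warning("skipping %s: %s vs %s (pool below %d events)",
                                       dim, a, b, config.min_pool)
                        continue
                    res = comparison.mc_pvalue_histogram(
                        pools[a], pools[b], m=cs.m, reps=cs.reps, B=cs.B, rng=rng,
                        standardize=cs.standardize, fdr_lambda=cs.fdr_lambda,
                        fdr_threshold=cs.fdr_threshold)
                    safe = f"{dim}_{a}_vs_{b}".replace(" ", "_").replace("/", "-")
                    pd.DataFrame({"p_value": res.p_values}).to_csv(
                        cmp_dir / f"{safe}_pvalues.csv", index=False, float_format="%.8g")
                    report = {
                        "dimension": dim, "level_a": a, "level_b": b,
                        "n_a": int(pools[a].shape[0]), "n_b": int(pools[b].shape[0]),
                        "m": res.m, "reps": res.reps, "B": res.B,
                        "standardized": res.standardized,
                        "fraction_below_0.05": res.fraction_below(0.05),
                        "uniformity_distance": res.uniformity_distance,
                        "fdr_estimate": res.fdr.value, "pi0": res.fdr.pi0,
                        "no_discoveries": res.fdr.no_discoveries,
                        "notes": res.notes,
                    }
                    with open(cmp_dir / f"{safe}.json", "w") as fh:
                        json.dump(report, fh, indent=2)
                    manifest["outputs"] += [f"compare/{safe}_pvalues.csv", f"compare/{safe}.json"]
                    comparisons.append(report)
                    if config.make_plots:
                        _plot_histogram(res, cmp_dir / f"{safe}.png")
                        manifest["outputs"].append(f"compare/{safe}.png")
        manifest["comparisons"] = comparisons
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {current_stage[0]!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _plot_histogram(res: comparison.PValueHistogramResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(res.p_values, bins=res.bin_edges, color="#4477aa", edgecolor="white")
    ax.axhline(res.reps / (len(res.bin_edges) - 1), ls="--", c="0.4", lw=1)
    ax.set_xlabel("p-value")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
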