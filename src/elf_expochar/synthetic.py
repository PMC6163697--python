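"""Synthetic exposure cohorts with known ground-truth segment structure.

The real dosimetry campaigns behind this analysis are not public, so this
module generates 24-h exposure days with the statistical structure the
pipeline assumes: piecewise-stationary AR(1) segments with abrupt changes in
mean and dispersion, a day/night contrast (night segments are longer, quieter
and lower in mean level), and the dosimeter's sensitivity window of
0.01-300 µT applied by clipping.

Defaults emulate the orders of magnitude reported for European children's
personal ELF-MF exposure: typical segment mean levels around 0.013 µT by day
and 0.010 µT by night, marginal dispersions of a few nT to tens of nT, and a
handful of day segments per day against one or two long night segments at a
30-s sample interval. Segment parameter and duration laws are stand-ins with
realistic shapes (log-normal levels and dispersions, truncated-normal phi,
truncated-geometric durations); they are not estimates of any real campaign.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .recordings import (
    SECONDS_PER_DAY,
    DAY_WINDOW_START_S,
    DAY_WINDOW_END_S,
    SUBSTATION_CLASSES,
    DayRecording,
    write_recording,
)


@dataclass(frozen=True)
class SegmentSpec:
    """Ground truth for one stationary AR(1) stretch.

    Rendered as y_t = mu + phi*(y_{t-1} - mu) + sqrt(sigma2)*z_t with iid
    standard-normal z_t; the first sample is drawn from the stationary law
    N(mu, sigma2 / (1 - phi^2)).
    """

    n_samples: int
    mu: float
    sigma2: float
    phi: float

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if not (abs(self.phi) < 1):
            raise ValueError(f"|phi| must be < 1 for stationarity, got {self.phi}")
        if not (self.sigma2 >= 0 and np.isfinite(self.sigma2)):
            raise ValueError("sigma2 must be finite and non-negative")
        if self.mu < 0:
            raise ValueError("mu must be non-negative (field magnitude)")


@dataclass
class DayPlan:
    """An ordered tiling of one 24-h day by SegmentSpecs."""

    segments: list[SegmentSpec]
    sample_interval_s: int = 30
    sensor_floor: float = 0.01
    sensor_ceiling: float = 300.0

    def __post_init__(self) -> None:
        if self.sample_interval_s not in (3, 30) and SECONDS_PER_DAY % self.sample_interval_s:
            raise ValueError("sample interval must divide 86400 s")
        total = sum(s.n_samples for s in self.segments)
        expected = SECONDS_PER_DAY // self.sample_interval_s
        if total != expected:
            raise ValueError(
                f"segments hold {total} samples but a day at {self.sample_interval_s} s "
                f"holds exactly {expected}"
            )

    @property
    def n_samples(self) -> int:
        return SECONDS_PER_DAY // self.sample_interval_s

    @property
    def true_changepoints(self) -> np.ndarray:
        """Boundary indices tau_1..tau_k (excluding 0 and n)."""
        ends = np.cumsum([s.n_samples for s in self.segments])
        return ends[:-1]


@dataclass
class SegmentLaw:
    """Sampling law for one regime's (mu, sigma2, phi, duration).

    Mean level and dispersion are log-normal (log10 location/scale); sigma2 is
    zero with probability p_zero_sigma2 (these segments surface downstream as
    the below-resolution point mass of the dispersion density); phi is normal
    truncated to (-phi_max, phi_max); durations in samples are a discretized
    log-normal (median + log10 scale) floored at min_duration, giving a
    skewed law with an interior mode as activity bouts have.
    """

    log10_mu: float = -1.62  # 10**-1.62 = 0.024 µT
    log10_mu_sd: float = 0.20
    log10_sigma2: float = -5.3  # ~ (2.2 nT)^2
    log10_sigma2_sd: float = 0.50
    p_zero_sigma2: float = 0.0
    phi_mean: float = 0.45
    phi_sd: float = 0.15
    phi_max: float = 0.95
    median_duration_samples: int = 200
    log10_duration_sd: float = 0.35
    min_duration_samples: int = 8

    def sample_params(self, rng: np.random.Generator, mu_scale: float = 1.0) -> tuple[float, float, float]:
        mu = 10 ** rng.normal(self.log10_mu, self.log10_mu_sd) * mu_scale
        if self.p_zero_sigma2 > 0 and rng.random() < self.p_zero_sigma2:
            sigma2 = 0.0
        else:
            sigma2 = 10 ** rng.normal(self.log10_sigma2, self.log10_sigma2_sd)
        phi = float(np.clip(rng.normal(self.phi_mean, self.phi_sd), -self.phi_max, self.phi_max))
        return float(mu), float(sigma2), phi

    def sample_duration(self, rng: np.random.Generator) -> int:
        d = int(round(10 ** rng.normal(np.log10(self.median_duration_samples),
                                       self.log10_duration_sd)))
        return max(d, self.min_duration_samples)


def default_day_law() -> SegmentLaw:
    return SegmentLaw()


def default_night_law() -> SegmentLaw:
    # night: lower level, less dispersion, slower variation, much longer segments
    return SegmentLaw(
        log10_mu=-1.75,      # 0.018 µT
        log10_mu_sd=0.15,
        log10_sigma2=-6.4,
        log10_sigma2_sd=0.50,
        p_zero_sigma2=0.0,
        phi_mean=0.55,
        phi_sd=0.12,
        median_duration_samples=700,
        log10_duration_sd=0.30,
        min_duration_samples=8,
    )


def daynight_contrast_cohort(n_subjects: int = 60, seed: int = 0) -> "CohortSpec":
    """A cohort with a built-in day/night contrast sized for desk-scale studies.

    Night segments are longer (median 5.8 h vs 1.7 h) and lower in mean level
    (0.017 vs 0.030 µT) than day segments. The level ratio (~1.8) is larger
    than the subtle shifts reported from field campaigns because those are
    resolved with tens of thousands of events; with the few hundred events a
    small cohort yields, the qualitative pattern must be proportionally
    clearer to be resolvable. Both laws sit clear of the 0.01 µT sensor
    floor so floor saturation does not fragment the long night segments.
    """
    return CohortSpec(
        n_subjects=n_subjects,
        seed=seed,
        alarm_clock_prob=0.0,
        day_law=SegmentLaw(log10_mu=-1.52, log10_mu_sd=0.20),
        night_law=SegmentLaw(
            log10_mu=-1.75, log10_mu_sd=0.12,
            log10_sigma2=-7.0, log10_sigma2_sd=0.40,
            phi_mean=0.55, phi_sd=0.12,
            median_duration_samples=700, log10_duration_sd=0.30,
        ),
    )


@dataclass
class CohortSpec:
    """A reproducible synthetic cohort: who is measured and how exposure behaves.

    ``mu_multipliers`` optionally scales segment mean levels by metadata level
    (e.g. larger towns -> higher levels), giving cohorts with known subgroup
    contrasts for power studies.
    """

    n_subjects: int = 10
    n_days: int = 1
    sample_interval_s: int = 30
    seed: int = 0
    day_law: SegmentLaw = field(default_factory=default_day_law)
    night_law: SegmentLaw = field(default_factory=default_night_law)
    age_range: tuple[int, int] = (0, 14)
    inhabitants_choices: tuple[float, ...] = (800, 3500, 7500, 15000, 35000, 75000, 150000, 900000)
    substation_probs: tuple[float, ...] = (0.9, 0.05, 0.05)
    alarm_clock_prob: float = 0.1
    mu_multipliers: dict = field(default_factory=dict)  # field -> {level: factor}
    start_date: str = "2012-06-01"

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_days < 1:
            raise ValueError("cohort needs at least one subject and one day")
        if abs(sum(self.substation_probs) - 1.0) > 1e-9:
            raise ValueError("substation_probs must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortSpec":
        raw = dict(raw)
        for key in ("day_law", "night_law"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = SegmentLaw(**raw[key])
        for key in ("age_range", "inhabitants_choices", "substation_probs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def sample_subject_metadata(cohort: CohortSpec, subject_index: int, rng: np.random.Generator) -> dict:
    lo, hi = cohort.age_range
    return {
        "subject_id": f"S{subject_index:04d}",
        "study": "synthetic",
        "age_years": int(rng.integers(lo, hi + 1)),
        "inhabitants": float(rng.choice(cohort.inhabitants_choices)),
        "substation_class": str(rng.choice(SUBSTATION_CLASSES, p=cohort.substation_probs)),
        "alarm_clock_near": bool(rng.random() < cohort.alarm_clock_prob),
        "sample_interval_s": cohort.sample_interval_s,
    }


def _mu_scale(cohort: CohortSpec, meta: dict) -> float:
    from .recordings import assign_subgroups

    scale = 1.0
    if cohort.mu_multipliers:
        levels = {k.dimension: k.level for k in assign_subgroups(meta)}
        for dim, table in cohort.mu_multipliers.items():
            if dim in levels and levels[dim] in table:
                scale *= float(table[levels[dim]])
    return scale


def _regime_at(second_of_day: int) -> str:
    return "day" if DAY_WINDOW_START_S <= second_of_day < DAY_WINDOW_END_S else "night"


def sample_day_plan(cohort: CohortSpec, subject_meta: dict, rng: np.random.Generator) -> DayPlan:
    """Draw one day's ground-truth segment plan.

    The day is tiled left to right from 00:00; each segment's regime (day or
    night law) is chosen by the wall-clock time of its first sample, so
    segments may straddle a window boundary just as detected events can.
    A trailing remainder shorter than the minimum duration is absorbed into
    the final segment.
    """
    interval = cohort.sample_interval_s
    n_total = SECONDS_PER_DAY // interval
    min_dur = min(cohort.day_law.min_duration_samples, cohort.night_law.min_duration_samples)
    if n_total < min_dur:
        raise ValueError(
            f"cannot tile a {n_total}-sample day with segments of at least {min_dur} samples"
        )
    scale = _mu_scale(cohort, subject_meta)
    segments: list[SegmentSpec] = []
    pos = 0
    while pos < n_total:
        law = cohort.day_law if _regime_at(pos * interval) == "day" else cohort.night_law
        dur = law.sample_duration(rng)
        remaining = n_total - pos
        if remaining - dur < min_dur:
            dur = remaining  # absorb the tail so the plan tiles exactly
        mu, sigma2, phi = law.sample_params(rng, mu_scale=scale)
        segments.append(SegmentSpec(n_samples=int(dur), mu=mu, sigma2=sigma2, phi=phi))
        pos += dur
    return DayPlan(segments=segments, sample_interval_s=interval)


def random_changepoint_day(rng: np.random.Generator, n_samples: int = 2880,
                           n_segments_range: tuple[int, int] = (3, 6),
                           min_seg_len: int = 60,
                           jump_sigmas: tuple[float, float] = (5.0, 8.0),
                           sample_interval_s: int = 30) -> DayPlan:
    """A day with well-separated segments for detector-recovery studies.

    Adjacent segment means differ by 5-8 marginal standard deviations, all
    segments are at least ``min_seg_len`` samples, and levels stay well above
    the sensor floor, so the true change-points are unambiguous.
    """
    lo, hi = n_segments_range
    k = int(rng.integers(lo, hi + 1))
    # boundaries with the minimum gap enforced
    free = n_samples - k * min_seg_len
    if free < 0:
        raise ValueError("cannot place that many segments with the given minimum length")
    cuts = np.sort(rng.choice(free + 1, size=k - 1, replace=True))
    lengths = np.diff(np.concatenate([[0], cuts, [free]])) + min_seg_len
    specs = []
    mu = 0.2
    prev_sd = None
    for L in lengths:
        phi = float(rng.uniform(0.2, 0.7))
        sigma2 = float(10 ** rng.uniform(-6.0, -5.0))
        sd_marg = np.sqrt(sigma2 / (1 - phi**2))
        if prev_sd is not None:
            jump = rng.uniform(*jump_sigmas) * max(sd_marg, prev_sd)
            direction = rng.choice([-1.0, 1.0])
            if mu + direction * jump < 0.05:
                direction = 1.0
            mu = mu + direction * jump
        specs.append(SegmentSpec(n_samples=int(L), mu=mu, sigma2=sigma2, phi=phi))
        prev_sd = sd_marg
    return DayPlan(segments=specs, sample_interval_s=sample_interval_s)


def render_segment(spec: SegmentSpec, rng: np.random.Generator) -> np.ndarray:
    """Simulate one stationary AR(1) segment (unclipped)."""
    sd_marginal = np.sqrt(spec.sigma2 / (1.0 - spec.phi**2))
    y = np.empty(spec.n_samples)
    y[0] = spec.mu + sd_marginal * rng.standard_normal()
    if spec.n_samples > 1:
        eps = np.sqrt(spec.sigma2) * rng.standard_normal(spec.n_samples - 1)
        # scipy.signal.lfilter would do; the explicit recursion keeps the
        # rendering rule obvious and the rng draw order stable
        prev = y[0] - spec.mu
        for t in range(1, spec.n_samples):
            prev = spec.phi * prev + eps[t - 1]
            y[t] = spec.mu + prev
    return y


def render_day(plan: DayPlan, rng: np.random.Generator,
               subject_meta: dict | None = None,
               date: dt.date | None = None) -> DayRecording:
    """Render a DayPlan to a clipped DayRecording."""
    parts = [render_segment(s, rng) for s in plan.segments]
    values = np.clip(np.concatenate(parts), plan.sensor_floor, plan.sensor_ceiling)
    meta = dict(subject_meta or {})
    return DayRecording(
        subject_id=str(meta.get("subject_id", "synthetic")),
        date=date or dt.date(2012, 6, 1),
        sample_interval_s=plan.sample_interval_s,
        values=values,
        metadata=meta,
    )


def sample_event_parameters(law: SegmentLaw, n: int, rng: np.random.Generator,
                            sample_interval_s: int = 30, mu_scale: float = 1.0) -> np.ndarray:
    """Draw n ground-truth event quadruples (mu, sigma2, phi, T) from one law.

    Convenience for calibration studies of the comparison stage that need
    large event pools without rendering and re-segmenting days.
    """
    out = np.empty((n, 4))
    for i in range(n):
        mu, sigma2, phi = law.sample_params(rng, mu_scale=mu_scale)
        out[i, 0], out[i, 1], out[i, 2] = mu, sigma2, phi
        out[i, 3] = law.sample_duration(rng) * sample_interval_s
    return out


# ---------------------------------------------------------------------------
# Fixture cohorts on disk


def generate_cohort(cohort: CohortSpec):
    """Yield (subject_meta, day_index, plan, day_recording) for the whole cohort.

    The master seed deterministically fans out one stream per subject, so any
    subject can be regenerated independently.
    """
    master = np.random.SeedSequence(cohort.seed)
    subject_seeds = master.spawn(cohort.n_subjects)
    start = dt.date.fromisoformat(cohort.start_date)
    for i in range(cohort.n_subjects):
        rng = np.random.default_rng(subject_seeds[i])
        meta = sample_subject_metadata(cohort, i, rng)
        for d in range(cohort.n_days):
            plan = sample_day_plan(cohort, meta, rng)
            day = render_day(plan, rng, subject_meta=meta, date=start + dt.timedelta(days=d))
            yield meta, d, plan, day


def write_fixture_cohort(cohort: CohortSpec, out_dir) -> dict:
    """Write recordings, metadata, and ground-truth tables; return the manifest.

    Layout: ``recordings/<subject>_day<k>.csv`` (timestamp_iso,field_uT),
    ``metadata.csv``, ``ground_truth.csv`` (one row per true segment), and
    ``manifest.json`` listing every file with the master seed.
    """
    out = Path(out_dir)
    (out / "recordings").mkdir(parents=True, exist_ok=True)
    import pandas as pd

    meta_rows, truth_rows, files = [], [], []
    seen = set()
    for meta, d, plan, day in generate_cohort(cohort):
        rel = f"recordings/{meta['subject_id']}_day{d}.csv"
        write_recording(day, out / rel)
        files.append(rel)
        if meta["subject_id"] not in seen:
            seen.add(meta["subject_id"])
            meta_rows.append(meta)
        starts = np.concatenate([[0], plan.true_changepoints])
        for tau, seg in zip(starts, plan.segments):
            truth_rows.append({
                "subject_id": meta["subject_id"], "day_index": d, "tau_index": int(tau),
                "mu": seg.mu, "sigma2": seg.sigma2, "phi": seg.phi,
            })
    pd.DataFrame(meta_rows)[
        ["subject_id", "study", "age_years", "inhabitants", "substation_class",
         "alarm_clock_near", "sample_interval_s"]
    ].to_csv(out / "metadata.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False, float_format="%.12g")
    manifest = {
        "seed": cohort.seed,
        "n_subjects": cohort.n_subjects,
        "n_days": cohort.n_days,
        "sample_interval_s": cohort.sample_interval_s,
        "recordings": files,
        "metadata": "metadata.csv",
        "ground_truth": "ground_truth.csv",
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
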