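"""Change-point detection with PELT under a penalized Gaussian AR(1) cost.

An exposure day is modeled as a piecewise-stationary first-order
autoregression: within segment j,

    y_t = mu_j + phi_j (y_{t-1} - mu_j) + sigma_j z_t,   z_t iid N(0, 1).

Each candidate segment is scored by twice the negative conditional Gaussian
log-likelihood at the conditional-least-squares fit; segmentation minimizes
the total cost plus ``penalty`` per change-point. The PELT dynamic program
prunes candidate last-change-points while provably retaining the optimum:
pruning uses a slack constant K = -log(2*pi*var_floor) because splitting a
segment drops one boundary residual from the conditional likelihood, whose
contribution is bounded below by log(2*pi*var_floor). ``brute_force_segment``
is the unpruned O(n^2) dynamic program, kept as an exact reference.

Each retained segment becomes an Event summarized by the quadruple
(mu, sigma2, phi, T): mean level (µT), dispersion (µT²), variation speed
(dimensionless), and duration (seconds). Fits with |phi| >= 1 describe a
non-stationary segment and are removed (and logged) during event extraction.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .recordings import DayRecording, SubgroupKey, assign_daynight, assign_subgroups

logger = logging.getLogger(__name__)

DEFAULT_MIN_SEG_LEN = 4
#: variance floor inside the likelihood only; reported sigma2 stays raw.
#: (0.1 nT)^2: dispersion below the dosimeter's resolution is not evidence.
#: A much smaller floor makes every >=4-sample saturated (constant) run so
#: cheap that PELT carves it out, shredding data near the 0.01 µT floor.
DEFAULT_VAR_FLOOR = 1e-8


def default_penalty(n: int) -> float:
    """BIC-flavored default: 3 free parameters (mu, sigma2, phi) per extra segment."""
    return 3.0 * math.log(n)


@dataclass(frozen=True)
class ARParams:
    """Conditional-least-squares AR(1) fit of one segment."""

    mu: float
    sigma2: float
    phi: float


@dataclass
class Segmentation:
    """An ordered partition of [0, n) with per-segment AR(1) fits.

    ``taus`` holds the boundaries including 0 and n, so segment j covers
    sample indices [taus[j], taus[j+1]). ``total_cost`` is the penalized
    objective sum(segment costs) + penalty * k with k = len(taus) - 2
    change-points.
    """

    n: int
    taus: np.ndarray
    params: list[ARParams]
    total_cost: float
    penalty: float
    min_seg_len: int
    too_short: bool = False  # series shorter than 2*min_seg_len: forced single segment

    def __post_init__(self) -> None:
        self.taus = np.asarray(self.taus, dtype=int)
        if self.taus[0] != 0 or self.taus[-1] != self.n:
            raise ValueError("taus must start at 0 and end at n")
        if np.any(np.diff(self.taus) <= 0):
            raise ValueError("taus must be strictly increasing")

    @property
    def k(self) -> int:
        """Number of change-points."""
        return len(self.taus) - 2

    @property
    def changepoints(self) -> np.ndarray:
        return self.taus[1:-1]

    def segment_slices(self) -> list[tuple[int, int]]:
        return list(zip(self.taus[:-1], self.taus[1:]))


def fit_ar1(values: np.ndarray, min_len: int = DEFAULT_MIN_SEG_LEN) -> ARParams:
    """Fit an AR(1) by conditional least squares.

    mu is the sample mean; phi regresses (y_t - mu) on (y_{t-1} - mu);
    sigma2 is the mean squared residual of that regression. A degenerate
    zero-variance segment yields (mu, 0, 0) by convention.
    """
    v = np.asarray(values, dtype=float)
    if v.size < min_len:
        raise ValueError(f"segment of {v.size} samples is shorter than min length {min_len}")
    if v.size < 2 or np.ptp(v) == 0.0:
        return ARParams(mu=float(v[0]), sigma2=0.0, phi=0.0)
    mu = float(v.mean())
    x = v[:-1] - mu
    y = v[1:] - mu
    sxx = float(x @ x)
    if sxx == 0.0:
        return ARParams(mu=mu, sigma2=0.0, phi=0.0)
    phi = float(x @ y) / sxx
    resid = y - phi * x
    sigma2 = float(resid @ resid) / resid.size
    return ARParams(mu=mu, sigma2=sigma2, phi=phi)


class _Ar1Cost:
    """O(1) window costs for a fixed series via prefix sums.

    cost(t, s) scores the window of sample indices [t, s) (s - t >= min_len)
    with twice the negative conditional Gaussian log-likelihood at the CLS
    AR(1) fit: m * (log(2*pi*sigma2_hat) + 1) over the m = s - t - 1
    conditional residuals, with sigma2_hat floored at var_floor.
    """

    def __init__(self, values: np.ndarray, min_len: int = DEFAULT_MIN_SEG_LEN,
                 var_floor: float = DEFAULT_VAR_FLOOR) -> None:
        v = np.asarray(values, dtype=float)
        self.n = v.size
        self.min_len = min_len
        self.var_floor = var_floor
        z = np.zeros(1)
        self.c1 = np.concatenate([z, np.cumsum(v)])          # sum y_i
        self.c2 = np.concatenate([z, np.cumsum(v * v)])      # sum y_i^2
        cx = np.concatenate([z, np.cumsum(v[1:] * v[:-1])])  # sum y_i*y_{i-1}
        self.cx = np.concatenate([z, cx])                    # index shift: pairs ending at i

    def _sigma2(self, t: np.ndarray, s: int) -> np.ndarray:
        """Vectorized residual variance of windows [t_i, s)."""
        t = np.asarray(t)
        L = s - t
        m = L - 1.0
        mu = (self.c1[s] - self.c1[t]) / L
        # lagged cross-product over pairs (i-1, i) for i in [t+1, s)
        sum_cross = self.cx[s] - self.cx[t + 1]
        sum_head = self.c1[s - 1] - self.c1[t]      # y_t .. y_{s-2}
        sum_tail = self.c1[s] - self.c1[t + 1]      # y_{t+1} .. y_{s-1}
        sxy = sum_cross - mu * (sum_head + sum_tail) + m * mu * mu
        sxx = (self.c2[s - 1] - self.c2[t]) - 2 * mu * sum_head + m * mu * mu
        syy = (self.c2[s] - self.c2[t + 1]) - 2 * mu * sum_tail + m * mu * mu
        with np.errstate(divide="ignore", invalid="ignore"):
            rss = np.where(sxx > 0, syy - sxy * sxy / np.where(sxx > 0, sxx, 1.0), syy)
        # guard tiny negative round-off
        return np.maximum(rss, 0.0) / m

    def cost(self, t, s: int):
        t_arr = np.atleast_1d(np.asarray(t, dtype=int))
        if np.any(s - t_arr < self.min_len):
            raise ValueError(f"window shorter than min segment length {self.min_len}")
        m = (s - t_arr - 1).astype(float)
        sig2 = np.maximum(self._sigma2(t_arr, s), self.var_floor)
        out = m * (np.log(2.0 * np.pi * sig2) + 1.0)
        return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out

    @property
    def prune_slack(self) -> float:
        return max(0.0, -math.log(2.0 * math.pi * self.var_floor))


def segment_cost(values: np.ndarray, t: int, s: int,
                 min_seg_len: int = DEFAULT_MIN_SEG_LEN,
                 var_floor: float = DEFAULT_VAR_FLOOR) -> float:
    """Penalized-likelihood cost of window [t, s); pure function of the slice."""
    if s - t < min_seg_len:
        raise ValueError(f"window [{t}, {s}) shorter than min segment length {min_seg_len}")
    return _Ar1Cost(np.asarray(values, dtype=float)[t:s], min_seg_len, var_floor).cost(0, s - t)


def _backtrack(values: np.ndarray, prev: np.ndarray, F_n: float, penalty: float,
               min_seg_len: int, too_short: bool = False) -> Segmentation:
    n = values.size
    taus = [n]
    s = n
    while s > 0:
        s = int(prev[s])
        taus.append(s)
    taus = np.array(taus[::-1], dtype=int)
    params = [fit_ar1(values[a:b], min_len=2) for a, b in zip(taus[:-1], taus[1:])]
    return Segmentation(
        n=n, taus=taus, params=params, total_cost=float(F_n), penalty=penalty,
        min_seg_len=min_seg_len, too_short=too_short,
    )


def _single_segment(values: np.ndarray, cost: _Ar1Cost, penalty: float,
                    min_seg_len: int, too_short: bool) -> Segmentation:
    n = values.size
    c = cost.cost(0, n) if n >= max(min_seg_len, 2) else 0.0
    return Segmentation(
        n=n, taus=np.array([0, n]), params=[fit_ar1(values, min_len=1)],
        total_cost=float(c), penalty=penalty, min_seg_len=min_seg_len, too_short=too_short,
    )


def _dp(values: np.ndarray, penalty: float, min_seg_len: int, var_floor: float,
        prune: bool) -> Segmentation:
    """Shared optimal-partitioning dynamic program; PELT pruning optional.

    Ties in the objective break toward fewer change-points, then toward the
    smaller last change-point, making outputs reproducible.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if min_seg_len < 2:
        raise ValueError("min_seg_len must be at least 2 (one conditional residual)")
    cost = _Ar1Cost(v, min_seg_len, var_floor)
    if n < 2 * min_seg_len:
        logger.warning("series of %d samples cannot hold two segments of %d; "
                       "returning a single flagged segment", n, min_seg_len)
        return _single_segment(v, cost, penalty, min_seg_len, too_short=True)
    K = cost.prune_slack
    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    nseg = np.zeros(n + 1, dtype=int)
    prev = np.zeros(n + 1, dtype=int)
    cand = np.array([0], dtype=int)
    for s in range(min_seg_len, n + 1):
        new_t = s - min_seg_len
        if new_t >= min_seg_len:  # 0 seeds the list; 0 < t < min_seg_len can't end a segment
            cand = np.append(cand, new_t)
        totals = F[cand] + cost.cost(cand, s)
        best_val = totals.min()
        tie = cand[totals == best_val]
        t_star = int(tie[np.lexsort((tie, nseg[tie]))[0]])
        F[s] = best_val + penalty
        nseg[s] = nseg[t_star] + 1
        prev[s] = t_star
        if prune:
            cand = cand[totals <= F[s] + K]
    return _backtrack(v, prev, F[n], penalty, min_seg_len)


def pelt(values: np.ndarray, penalty: float | None = None,
         min_seg_len: int = DEFAULT_MIN_SEG_LEN,
         var_floor: float = DEFAULT_VAR_FLOOR) -> Segmentation:
    """Optimal penalized AR(1) segmentation via PELT.

    Minimizes sum of segment costs + penalty * (number of change-points).
    ``penalty=None`` uses the 3*log(n) default. A series shorter than
    2*min_seg_len yields a single flagged segment.
    """
    v = np.asarray(values, dtype=float)
    if penalty is None:
        penalty = default_penalty(v.size)
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    return _dp(v, penalty, min_seg_len, var_floor, prune=True)


def brute_force_segment(values: np.ndarray, penalty: float | None = None,
                        min_seg_len: int = DEFAULT_MIN_SEG_LEN,
                        var_floor: float = DEFAULT_VAR_FLOOR,
                        max_n: int = 2000) -> Segmentation:
    """Exact unpruned O(n^2) dynamic program (reference oracle for pelt)."""
    v = np.asarray(values, dtype=float)
    if v.size > max_n:
        raise ValueError(f"brute-force limit {max_n} exceeded (n={v.size})")
    if penalty is None:
        penalty = default_penalty(v.size)
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    return _dp(v, penalty, min_seg_len, var_floor, prune=False)


# ---------------------------------------------------------------------------
# Events


@dataclass
class Event:
    """One stationary segment as the quadruple p = (mu, sigma2, phi, T)."""

    subject_id: str
    mu: float
    sigma2: float
    phi: float
    duration_s: float
    start: dt.datetime
    end: dt.datetime
    labels: dict = field(default_factory=dict)  # dimension -> level

    @property
    def parameter_vector(self) -> np.ndarray:
        return np.array([self.mu, self.sigma2, self.phi, self.duration_s])


def extract_events(day: DayRecording, seg: Segmentation) -> list[Event]:
    """Turn a day's segmentation into labeled events.

    T is segment length x sample interval (seconds); the day/night label uses
    majority overlap with the 07:00-21:00 day window; subject metadata adds
    the age / town-size / substation labels. Segments whose fitted |phi| >= 1
    are non-stationary under the model and are dropped (the count is logged).
    """
    if seg.n != day.n_samples:
        raise ValueError("segmentation does not belong to this day")
    base = {k.dimension: k.level for k in assign_subgroups(day.metadata)}
    step = day.sample_interval_s
    events: list[Event] = []
    n_excluded = 0
    for (a, b), p in zip(seg.segment_slices(), seg.params):
        if abs(p.phi) >= 1.0:
            n_excluded += 1
            continue
        start = day.start_time + dt.timedelta(seconds=int(a) * step)
        end = day.start_time + dt.timedelta(seconds=int(b) * step)
        labels = dict(base)
        labels["daynight"] = assign_daynight(start, end)
        events.append(Event(
            subject_id=day.subject_id, mu=p.mu, sigma2=p.sigma2, phi=p.phi,
            duration_s=float((b - a) * step), start=start, end=end, labels=labels,
        ))
    if n_excluded:
        logger.info("excluded %d of %d segments with |phi| >= 1 for subject %s on %s",
                    n_excluded, seg.k + 1, day.subject_id, day.date)
    return events


def events_to_frame(events: list[Event]) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for e in events:
        rows.append({
            "subject_id": e.subject_id,
            "date": e.start.date().isoformat(),
            "start_time": e.start.isoformat(),
            "end_time": e.end.isoformat(),
            "mu_uT": e.mu,
            "sigma2_uT2": e.sigma2,
            "phi": e.phi,
            "T_s": e.duration_s,
            "daynight": e.labels.get("daynight", ""),
            "age_group": e.labels.get("age", ""),
            "inhabitants_group": e.labels.get("inhabitants", ""),
            "substation_group": e.labels.get("substation", ""),
        })
    return pd.DataFrame(rows)
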