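"""Do two subgroups of events share a distribution?

The decision statistic is the energy (Cramér) two-sample statistic on the
4-D event parameters: with samples X (nx x d) and Y (ny x d),

    T = nx*ny/(nx+ny) * [ mean ||x_i - y_j||
                          - 1/2 mean ||x_i - x_i'||
                          - 1/2 mean ||y_j - y_j'|| ],

zero iff the two point sets coincide, with significance from a label
permutation test (add-one p-value, so p is never exactly zero).

Because subgroup samples are large and unequal, the test is wrapped in a
Monte-Carlo subsampling scheme: draw m events from each pool, test, repeat.
The resulting p-value histogram is approximately uniform when the two pools
share a distribution and piles up near zero when they do not. The pile-up is
quantified with Storey's false discovery rate: pi0 = #{p > lambda} /
((1 - lambda) * R) estimates the fraction of true nulls and
FDR(t) = min(1, pi0 * t * R / #{p <= t}).

Distances mix parameters with very different units (durations in 1e2-1e4 s
against mean levels of ~1e-2 µT), so each subsampled draw is z-scored per
dimension on the pooled draw by default; the flag is recorded in results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist


def energy_statistic(X: np.ndarray, Y: np.ndarray) -> float:
    """Baringhaus-Franz energy statistic between two d-dimensional samples."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    nx, ny = X.shape[0], Y.shape[0]
    if nx < 1 or ny < 1:
        raise ValueError("both samples must be nonempty")
    mean_xy = cdist(X, Y).mean()
    mean_xx = 2.0 * pdist(X).sum() / (nx * nx) if nx > 1 else 0.0
    mean_yy = 2.0 * pdist(Y).sum() / (ny * ny) if ny > 1 else 0.0
    return float(nx * ny / (nx + ny) * (mean_xy - 0.5 * mean_xx - 0.5 * mean_yy))


def _energy_from_labels(D: np.ndarray, labels: np.ndarray, nx: int) -> np.ndarray:
    """Batched statistic from a pooled distance matrix.

    labels is a B x n 0/1 matrix (1 marks membership of X); rows are
    permutations of the original labeling.
    """
    n = D.shape[0]
    ny = n - nx
    Q = labels @ D                       # B x n: column sums over X rows
    s_x_all = Q.sum(axis=1)              # sum over X x (X u Y)
    s_xx = np.einsum("bi,bi->b", Q, labels)
    s_xy = s_x_all - s_xx
    s_tot = D.sum()
    s_yy = s_tot - 2 * s_xy - s_xx
    mean_xy = s_xy / (nx * ny)
    mean_xx = s_xx / (nx * nx)
    mean_yy = s_yy / (ny * ny)
    return nx * ny / (nx + ny) * (mean_xy - 0.5 * mean_xx - 0.5 * mean_yy)


@dataclass
class EnergyTestResult:
    statistic: float
    p_value: float
    nx: int
    ny: int
    B: int


def permutation_test(X: np.ndarray, Y: np.ndarray, B: int = 999,
                     rng: np.random.Generator | None = None) -> EnergyTestResult:
    """Permutation p-value for the energy statistic.

    p = (1 + #{permuted >= observed}) / (B + 1); deterministic under a
    seeded generator.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng() if rng is None else rng
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("dimension mismatch between samples")
    nx, ny = X.shape[0], Y.shape[0]
    if nx + ny < 2:
        raise ValueError("need at least two points in the pooled sample")
    Z = np.vstack([X, Y])
    n = nx + ny
    D = cdist(Z, Z)
    obs_label = np.zeros((1, n))
    obs_label[0, :nx] = 1.0
    observed = float(_energy_from_labels(D, obs_label, nx)[0])
    # B random relabelings, drawn column-wise for one vectorized pass
    perm_labels = np.zeros((B, n))
    for b in range(B):
        perm_labels[b, rng.permutation(n)[:nx]] = 1.0
    permuted = _energy_from_labels(D, perm_labels, nx)
    # relabelings that tie the observed statistic must count as extreme even
    # when a different summation order shifts them by a few ulp
    tol = 1e-9 * max(1.0, abs(observed))
    p = (1.0 + np.count_nonzero(permuted >= observed - tol)) / (B + 1.0)
    return EnergyTestResult(statistic=observed, p_value=float(p), nx=nx, ny=ny, B=B)


@dataclass
class FdrEstimate:
    value: float
    pi0: float
    n_discoveries: int
    threshold: float
    lam: float
    no_discoveries: bool = False


def estimate_fdr(p_values, lam: float = 0.5, threshold: float = 0.05) -> FdrEstimate:
    """Storey's FDR estimate at rejection threshold t.

    pi0 = #{p > lam} / ((1 - lam) * R), clipped to [0, 1];
    FDR(t) = min(1, pi0 * t * R / #{p <= t}). With no p <= t there are no
    discoveries; the estimate is reported as 1 with a flag.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if not 0 < lam < 1:
        raise ValueError("lambda must be in (0, 1)")
    R = p.size
    pi0 = min(1.0, np.count_nonzero(p > lam) / ((1.0 - lam) * R))
    n_disc = int(np.count_nonzero(p <= threshold))
    if n_disc == 0:
        return FdrEstimate(value=1.0, pi0=pi0, n_discoveries=0,
                           threshold=threshold, lam=lam, no_discoveries=True)
    value = min(1.0, pi0 * threshold * R / n_disc)
    return FdrEstimate(value=value, pi0=pi0, n_discoveries=n_disc,
                       threshold=threshold, lam=lam)


@dataclass
class PValueHistogramResult:
    """The Monte-Carlo subsampled test summary for one subgroup pair."""

    p_values: np.ndarray
    m: int
    reps: int
    B: int
    standardized: bool
    bin_edges: np.ndarray
    counts: np.ndarray
    uniformity_distance: float  # sup |ECDF - uniform CDF|
    fdr: FdrEstimate
    seed: int | None = None
    notes: list[str] = field(default_factory=list)

    def fraction_below(self, alpha: float = 0.05) -> float:
        return float(np.mean(self.p_values < alpha))


def _uniformity_distance(p: np.ndarray) -> float:
    """Kolmogorov sup-distance between the p-value ECDF and Uniform(0,1)."""
    s = np.sort(p)
    n = s.size
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    return float(max(np.max(grid_hi - s), np.max(s - grid_lo)))


def mc_pvalue_histogram(poolA: np.ndarray, poolB: np.ndarray, m: int = 200,
                        reps: int = 3000, B: int = 999,
                        rng: np.random.Generator | None = None,
                        standardize: bool = True, n_bins: int = 20,
                        fdr_lambda: float = 0.5,
                        fdr_threshold: float = 0.05) -> PValueHistogramResult:
    """Repeatedly subsample m events per pool, test, and histogram the p-values.

    Draws are without replacement within a repetition and independent across
    repetitions. If a pool holds fewer than m events, m is lowered to the
    smaller pool size (noted in the result). With ``standardize`` each
    repetition z-scores the pooled draw per dimension before computing
    distances.
    """
    rng = np.random.default_rng() if rng is None else rng
    A = np.atleast_2d(np.asarray(poolA, dtype=float))
    Bpool = np.atleast_2d(np.asarray(poolB, dtype=float))
    if A.shape[1] != Bpool.shape[1]:
        raise ValueError("dimension mismatch between pools")
    if A.shape[0] < 1 or Bpool.shape[0] < 1:
        raise ValueError("both pools must be nonempty")
    notes = []
    m_eff = min(m, A.shape[0], Bpool.shape[0])
    if m_eff < m:
        notes.append(f"subsample size reduced from {m} to {m_eff} (smaller pool)")
    p_values = np.empty(reps)
    for r in range(reps):
        ia = rng.choice(A.shape[0], size=m_eff, replace=False)
        ib = rng.choice(Bpool.shape[0], size=m_eff, replace=False)
        X, Y = A[ia], Bpool[ib]
        if standardize:
            pooled = np.vstack([X, Y])
            mean = pooled.mean(axis=0)
            sd = pooled.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            X = (X - mean) / sd
            Y = (Y - mean) / sd
        p_values[r] = permutation_test(X, Y, B=B, rng=rng).p_value
    counts, bin_edges = np.histogram(p_values, bins=n_bins, range=(0.0, 1.0))
    return PValueHistogramResult(
        p_values=p_values, m=m_eff, reps=reps, B=B, standardized=standardize,
        bin_edges=bin_edges, counts=counts,
        uniformity_distance=_uniformity_distance(p_values),
        fdr=estimate_fdr(p_values, lam=fdr_lambda, threshold=fdr_threshold),
        notes=notes,
    )
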