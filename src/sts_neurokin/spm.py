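"""1D Statistical Parametric Mapping for paired side-vs-side designs.

The test statistic is the pointwise paired t curve over the 101 cycle nodes.
Inference is non-parametric: under the null of exchangeable sides, each
subject's difference curve may have its sign flipped, and with n subjects all
2^n assignments are enumerated (exhaustively when feasible).  The
cluster-forming threshold is the (1 − α) quantile of the permutation
distribution of the curve maximum of |t|, clusters are maximal contiguous
supra-threshold runs of |t|, and a cluster's p-value is the fraction of
permutations whose longest run of sign-matched supra-threshold t values is at
least as long as the observed cluster ("directional" counting, under which a
saturated one-sided effect attains the minimum p of 1/2^n; an inclusive
two-tailed count is available via ``SpmConfig.directional_counting=False``).

Zero-variance nodes yield t = 0 when the mean difference is also zero and a
±inf sentinel otherwise; infinities compare larger than any finite t, which
is the intended behaviour in all quantile and run-length computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .config import SpmConfig

__all__ = [
    "Cluster",
    "SpmCurveResult",
    "FdrDecision",
    "paired_t_curve",
    "permutation_inference",
    "bh_fdr",
]


@dataclass(frozen=True)
class Cluster:
    """A maximal contiguous supra-threshold run of the t curve (inclusive bounds)."""

    node_start: int
    node_end: int
    extent: int
    p_value: float
    sign: int


@dataclass
class SpmCurveResult:
    t_curve: np.ndarray
    crit: float
    clusters: list[Cluster]
    n_permutations: int
    exhaustive: bool

    @property
    def min_p(self) -> float | None:
        return min((c.p_value for c in self.clusters), default=None)

    def significant(self, alpha: float = 0.05) -> bool:
        return any(c.p_value <= alpha for c in self.clusters)


@dataclass
class FdrDecision:
    variables: list[str]
    p_values: np.ndarray
    reject: np.ndarray
    alpha: float
    adjusted: np.ndarray = field(default_factory=lambda: np.empty(0))


def _t_from_diffs(diffs: np.ndarray) -> np.ndarray:
    """Paired t per node from an (n, Q) difference array, with sd=0 sentinels."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where((sd == 0) & (mean == 0), 0.0, t)
    t = np.where((sd == 0) & (mean > 0), np.inf, t)
    t = np.where((sd == 0) & (mean < 0), -np.inf, t)
    return t


def paired_t_curve(curves_more: np.ndarray, curves_less: np.ndarray) -> np.ndarray:
    """Pointwise paired t statistic of more-impaired minus less-impaired curves."""
    a = np.atleast_2d(np.asarray(curves_more, dtype=float))
    b = np.atleast_2d(np.asarray(curves_less, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.shape[0] < 2:
        raise ValueError("need at least two paired subjects")
    return _t_from_diffs(a - b)


def _sign_matrix(n: int) -> np.ndarray:
    """All 2^n sign assignments; row 0 is the identity (all +1)."""
    idx = np.arange(2**n, dtype=np.int64)
    bits = (idx[:, None] >> np.arange(n)) & 1
    return (1 - 2 * bits).astype(np.int8)


def _max_run_lengths(above: np.ndarray) -> np.ndarray:
    """Longest run of True per row of a (m, Q) boolean array."""
    m = above.shape[0]
    best = np.zeros(m, dtype=np.int32)
    run = np.zeros(m, dtype=np.int32)
    for j in range(above.shape[1]):
        run = np.where(above[:, j], run + 1, 0)
        best = np.maximum(best, run)
    return best


def _clusters_from_curve(t: np.ndarray, crit: float) -> list[tuple[int, int, int]]:
    """(start, end, sign) for maximal runs with |t| > crit, split at sign changes."""
    above = np.abs(t) > crit
    out: list[tuple[int, int, int]] = []
    i = 0
    Q = len(t)
    while i < Q:
        if not above[i]:
            i += 1
            continue
        sign = 1 if t[i] > 0 else -1
        j = i
        while j + 1 < Q and above[j + 1] and (t[j + 1] > 0) == (sign > 0):
            j += 1
        out.append((i, j, sign))
        i = j + 1
    return out


def permutation_inference(
    diff_curves: np.ndarray,
    config: SpmConfig = SpmConfig(),
) -> SpmCurveResult:
    """Exhaustive (or Monte-Carlo) sign-flip permutation SPM on difference curves.

    ``diff_curves`` is (n_subjects, n_nodes).  Raises when 2^n exceeds the
    exhaustive cap while ``config.exhaustive`` is set; switch the flag off to
    sample ``config.n_monte_carlo`` assignments instead (the identity is
    always included, so p-values stay valid).
    """
    D = np.atleast_2d(np.asarray(diff_curves, dtype=float))
    n, Q = D.shape
    if n < 2:
        raise ValueError("need at least two paired subjects")

    n_total = 2**n
    if config.exhaustive:
        if n_total > config.max_exhaustive:
            raise ValueError(
                f"2^{n} = {n_total} permutations exceed the exhaustive cap "
                f"({config.max_exhaustive}); set exhaustive=False for "
                f"Monte-Carlo sampling with n_monte_carlo iterations")
        S = _sign_matrix(n)
        exhaustive = True
    else:
        rng = np.random.default_rng(config.seed)
        S = rng.choice(np.array([-1, 1], dtype=np.int8),
                       size=(config.n_monte_carlo, n))
        S[0] = 1  # identity first, as in the exhaustive enumeration
        exhaustive = False
    n_perm = S.shape[0]

    sumsq = (D**2).sum(axis=0)

    # permutation t curves in chunks to bound memory
    chunk = max(1, min(n_perm, 1 << 14))
    max_abs = np.empty(n_perm)
    t_chunks: list[tuple[int, np.ndarray]] = []
    for s0 in range(0, n_perm, chunk):
        Sc = S[s0 : s0 + chunk].astype(float)
        mean = Sc @ D / n
        var = (sumsq - n * mean**2) / (n - 1)
        var = np.clip(var, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(var / n)
        t = np.where((var == 0) & (mean == 0), 0.0, t)
        t = np.where((var == 0) & (mean > 0), np.inf, t)
        t = np.where((var == 0) & (mean < 0), -np.inf, t)
        max_abs[s0 : s0 + chunk] = np.max(np.abs(t), axis=1)
        t_chunks.append((s0, t))

    # the observed curve is the identity assignment's row, so cluster
    # formation and permutation counting share identical numerics
    t_obs = t_chunks[0][1][0]

    crit = float(np.quantile(max_abs, 1.0 - config.alpha, method="higher"))

    # per-permutation longest supra-threshold run, by direction
    pos_extent = np.empty(n_perm, dtype=np.int32)
    neg_extent = np.empty(n_perm, dtype=np.int32)
    abs_extent = np.empty(n_perm, dtype=np.int32)
    for s0, t in t_chunks:
        sl = slice(s0, s0 + t.shape[0])
        pos_extent[sl] = _max_run_lengths(t > crit)
        neg_extent[sl] = _max_run_lengths(t < -crit)
        abs_extent[sl] = _max_run_lengths(np.abs(t) > crit)

    clusters = []
    for i, j, sign in _clusters_from_curve(t_obs, crit):
        extent = j - i + 1
        if config.directional_counting:
            ref = pos_extent if sign > 0 else neg_extent
        else:
            ref = abs_extent
        p = float(np.count_nonzero(ref >= extent)) / n_perm
        clusters.append(Cluster(i, j, extent, p, sign))

    return SpmCurveResult(
        t_curve=t_obs, crit=crit, clusters=clusters,
        n_permutations=n_perm, exhaustive=exhaustive)


def bh_fdr(p_values: dict[str, float] | np.ndarray, alpha: float = 0.05) -> FdrDecision:
    """Benjamini–Hochberg step-up FDR decision over a family of variables."""
    if isinstance(p_values, dict):
        names = list(p_values)
        p = np.array([p_values[k] for k in names], dtype=float)
    else:
        p = np.asarray(p_values, dtype=float)
        names = [f"var{i}" for i in range(p.size)]
    if p.size == 0:
        return FdrDecision(variables=[], p_values=p, reject=np.empty(0, bool),
                           alpha=alpha)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return FdrDecision(variables=names, p_values=p, reject=reject,
                       alpha=alpha, adjusted=adjusted)
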