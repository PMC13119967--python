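"""Independent brute-force oracle for the sign-flip permutation SPM test.

Written deliberately without sharing any code with the package: plain loops
over itertools sign assignments, scalar t computation, and a manual run-length
scan.  Used to cross-check cluster p-values exactly on small datasets.
"""

import itertools
import math


def brute_force_cluster_ps(diffs, alpha=0.05, directional=True):
    """Return (crit, [(start, end, p), ...]) for an n-by-Q list of lists."""
    n = len(diffs)
    q = len(diffs[0])
    assignments = list(itertools.product([1.0, -1.0], repeat=n))
    # identity (all +1) comes first in this ordering
    assert assignments[0] == tuple([1.0] * n)

    def t_curve(signs):
        curve = []
        for k in range(q):
            vals = [signs[i] * diffs[i][k] for i in range(n)]
            m = sum(vals) / n
            var = sum((v - m) ** 2 for v in vals) / (n - 1)
            if var == 0.0:
                curve.append(0.0 if m == 0.0 else math.copysign(math.inf, m))
            else:
                curve.append(m / math.sqrt(var / n))
        return curve

    curves = [t_curve(s) for s in assignments]
    maxima = sorted(max(abs(v) for v in curve) for curve in curves)
    # empirical (1 - alpha) quantile, "higher" convention
    crit = maxima[math.ceil((1.0 - alpha) * (len(maxima) - 1))]

    def longest_run(curve, pred):
        best = run = 0
        for v in curve:
            run = run + 1 if pred(v) else 0
            best = max(best, run)
        return best

    observed = curves[0]
    clusters = []
    k = 0
    while k < q:
        if abs(observed[k]) > crit:
            sign = 1 if observed[k] > 0 else -1
            j = k
            while (j + 1 < q and abs(observed[j + 1]) > crit
                   and (observed[j + 1] > 0) == (sign > 0)):
                j += 1
            extent = j - k + 1
            count = 0
            for curve in curves:
                if directional:
                    if sign > 0:
                        run = longest_run(curve, lambda v: v > crit)
                    else:
                        run = longest_run(curve, lambda v: v < -crit)
                else:
                    run = longest_run(curve, lambda v: abs(v) > crit)
                if run >= extent:
                    count += 1
            clusters.append((k, j, count / len(assignments)))
            k = j + 1
        else:
            k += 1
    return crit, clusters
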