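"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity from its definition by direct enumeration
or literal formula application, sharing no code with the implementation under
test.
"""

import itertools
import math

import numpy as np
from scipy.stats import binom


def conditional_binomial_pvalue(a_sum: int, t: int, n_a: int, n_b: int) -> float:
    """Two-sided conditional test at dispersion zero.

    Conditional on the total t, under equal per-sample Poisson means the group-A
    sum is Binomial(t, n_a/(n_a+n_b)); p sums the probabilities of all splits no
    more likely than the observed one.
    """
    if t == 0:
        return 1.0
    pm = binom.pmf(np.arange(t + 1), t, n_a / (n_a + n_b))
    obs = pm[a_sum]
    return float(min(1.0, pm[pm <= obs * (1 + 1e-9)].sum()))


def bh_stepup_bruteforce(pvalues) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m*p_(j)/j."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: (p[i], i))
    q = [0.0] * m
    for rank_pos, idx in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return np.array(q)


def hypergeom_tail_enumeration(k: int, n_universe: int, big_k: int, n_draw: int) -> float:
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    universe = list(range(n_universe))
    term = set(universe[:big_k])
    total = 0
    hits = 0
    for draw in itertools.combinations(universe, n_draw):
        total += 1
        if len(term.intersection(draw)) >= k:
            hits += 1
    return hits / total


def tmm_bruteforce(counts: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05):
    """Plain-loop re-derivation of the trimmed-mean-of-M-values recipe.

    Reference: sample whose 75th percentile of nonzero CPM is closest to the
    mean of those percentiles (lowest index on ties). Per sample: M/A over
    genes nonzero in both, double trim (by M then by A, stable tie-break by
    index), precision weights, factor 2^(weighted mean M), then rescale all
    factors to geometric mean 1.
    """
    Y = np.asarray(counts, dtype=float)
    n_genes, n_samples = Y.shape
    lib = [sum(Y[g][j] for g in range(n_genes)) for j in range(n_samples)]
    uq = []
    for j in range(n_samples):
        nz = [1e6 * Y[g][j] / lib[j] for g in range(n_genes) if Y[g][j] > 0]
        uq.append(float(np.percentile(nz, 75)))
    mean_uq = sum(uq) / n_samples
    ref = min(range(n_samples), key=lambda j: (abs(uq[j] - mean_uq), j))

    factors = [1.0] * n_samples
    for j in range(n_samples):
        if j == ref:
            continue
        pairs = [
            g for g in range(n_genes) if Y[g][j] > 0 and Y[g][ref] > 0
        ]
        M = {g: math.log2((Y[g][j] / lib[j]) / (Y[g][ref] / lib[ref])) for g in pairs}
        A = {
            g: 0.5 * math.log2((Y[g][j] / lib[j]) * (Y[g][ref] / lib[ref]))
            for g in pairs
        }
        n = len(pairs)
        lo_m = int(math.floor(n * trim_m))
        lo_a = int(math.floor(n * trim_a))
        by_m = sorted(pairs, key=lambda g: (M[g], g))
        by_a = sorted(pairs, key=lambda g: (A[g], g))
        keep = set(by_m[lo_m : n - lo_m]) & set(by_a[lo_a : n - lo_a])
        if not keep:
            continue
        num = 0.0
        den = 0.0
        for g in keep:
            w = 1.0 / (
                (lib[j] - Y[g][j]) / (lib[j] * Y[g][j])
                + (lib[ref] - Y[g][ref]) / (lib[ref] * Y[g][ref])
            )
            num += w * M[g]
            den += w
        factors[j] = 2.0 ** (num / den)
    log_mean = sum(math.log(f) for f in factors) / n_samples
    return np.array([f / math.exp(log_mean) for f in factors]), ref


def welch_bruteforce(a, b):
    """Literal Welch t and Satterthwaite df."""
    a = list(map(float, a))
    b = list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df
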