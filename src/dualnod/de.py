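"""Two-group negative-binomial differential expression.

Counts are modelled as NB(mean mu, variance mu + phi*mu^2). Per-gene
dispersions come from a method-of-moments estimate pooled across the two
treatment groups and shrunk toward the median positive dispersion; the test
is a conditional exact test: libraries are equalized to the geometric-mean
effective size, and conditional on the total count of a gene the probability
of every split between the groups is enumerated under NB-sum distributions.
The two-sided p-value is the summed probability of all splits at most as
likely as the observed one.

This construction is deliberately simple enough to audit by enumeration: at
dispersion zero it collapses exactly to the conditional binomial (Poisson)
test, which serves as an independent oracle in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom, poisson

from .io import (
    CountMatrix,
    TREATMENT_A,
    TREATMENT_B,
    ValidationError,
    treatment_groups,
)
from .normalize import NormFactors, cpm

logger = logging.getLogger("dualnod")

FDR_THRESHOLD = 0.05
LFC_THRESHOLD = 1.0
LOG2FC_PSEUDO_CPM = 0.5
DISPERSION_SHRINKAGE = 0.3

#: DEG status labels; log2FC = log2(WWL2/WE2), so negative = higher in WE2.
HIGHER_IN_A = f"higher_in_{TREATMENT_A}"
HIGHER_IN_B = f"higher_in_{TREATMENT_B}"
NOT_SIGNIFICANT = "ns"


@dataclass
class DispersionEstimate:
    per_gene: pd.Series  # raw method-of-moments phi_g
    common: float  # median of positive phi_g
    shrinkage: float  # weight on the common value
    shrunk: pd.Series  # (1-w)*phi_g + w*common


@dataclass
class DEGSummary:
    n_total: int
    n_higher_in_A: int  # log2FC <= -1: higher in WE2
    n_higher_in_B: int  # log2FC >= +1: higher in WWL2


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------


def estimate_dispersion(
    counts: CountMatrix,
    samples: pd.DataFrame,
    factors: NormFactors | None = None,
    shrinkage: float = DISPERSION_SHRINKAGE,
) -> DispersionEstimate:
    """Method-of-moments NB dispersion, pooled across groups, shrunk to median.

    phi_g = max(0, (s2_g - mu_g) / mu_g^2) on effective-library-normalized
    counts, where s2_g pools the within-group variances and mu_g averages the
    group means. Shrunk value: (1-w)*phi_g + w*median(positive phi).
    """
    groups = treatment_groups(samples)
    for t, ids in groups.items():
        if len(ids) < 2:
            raise ValidationError(f"treatment {t} has fewer than 2 replicates")
    lib = counts.library_sizes.astype(float)
    eff = lib if factors is None else factors.effective_sizes(lib)
    geo = float(np.exp(np.log(eff.to_numpy()).mean()))
    norm = counts.counts * (geo / eff)

    means, variances, dofs = [], [], []
    for ids in groups.values():
        sub = norm[ids].to_numpy(float)
        means.append(sub.mean(axis=1))
        variances.append(sub.var(axis=1, ddof=1))
        dofs.append(len(ids) - 1)
    mu = np.mean(means, axis=0)
    s2 = np.average(variances, axis=0, weights=dofs)

    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(mu > 0, np.maximum(0.0, (s2 - mu) / mu**2), 0.0)
    positive = phi[phi > 0]
    common = float(np.median(positive)) if positive.size else 0.0
    shrunk = (1.0 - shrinkage) * phi + shrinkage * common
    idx = counts.counts.index
    return DispersionEstimate(
        per_gene=pd.Series(phi, index=idx),
        common=common,
        shrinkage=shrinkage,
        shrunk=pd.Series(shrunk, index=idx),
    )


# ---------------------------------------------------------------------------
# Conditional exact test
# ---------------------------------------------------------------------------


def _group_sum_logpmf(s: np.ndarray, n: int, mu_per_sample: float, phi: float) -> np.ndarray:
    """log P(sum of n iid NB(mu, phi) counts = s).

    The sum is NB with mean n*mu and dispersion phi/n (size n/phi); at phi = 0
    it is Poisson(n*mu).
    """
    if phi <= 0:
        return poisson.logpmf(s, n * mu_per_sample)
    size = n / phi
    p = size / (size + n * mu_per_sample)
    return nbinom.logpmf(s, size, p)


def nb_exact_test(
    a,
    b,
    dispersion: float,
    sizes_a=None,
    sizes_b=None,
) -> float:
    """Two-sided conditional exact NB test for group A vs group B counts.

    Counts are first equalized to the geometric mean of the effective library
    sizes (rounded to the nearest integer so the enumeration stays exact).
    Conditional on the total t, p is the summed probability of all splits
    (s, t-s) no more probable than the observed one.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("counts must be nonnegative")
    n_a, n_b = len(a), len(b)
    if sizes_a is None:
        sizes_a = np.ones(n_a)
    if sizes_b is None:
        sizes_b = np.ones(n_b)
    sizes_a = np.asarray(sizes_a, dtype=float)
    sizes_b = np.asarray(sizes_b, dtype=float)
    if (sizes_a <= 0).any() or (sizes_b <= 0).any():
        raise ValidationError("effective library sizes must be positive")

    geo = np.exp(np.mean(np.log(np.concatenate([sizes_a, sizes_b]))))
    a_eq = np.rint(a * geo / sizes_a)
    b_eq = np.rint(b * geo / sizes_b)
    t_a = int(a_eq.sum())
    t = t_a + int(b_eq.sum())
    if t == 0:
        return 1.0

    mu = t / (n_a + n_b)
    s = np.arange(t + 1)
    logp = _group_sum_logpmf(s, n_a, mu, dispersion) + _group_sum_logpmf(
        s[::-1], n_b, mu, dispersion
    )
    log_obs = logp[t_a]
    selected = logp <= log_obs + 1e-8  # tolerance absorbs logpmf rounding at ties
    p = float(np.exp(logsumexp(logp[selected]) - logsumexp(logp)))
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Multiple testing and DEG calling
# ---------------------------------------------------------------------------


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, mapped back to input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def log2fc(mean_a_cpm, mean_b_cpm, pseudo: float = LOG2FC_PSEUDO_CPM):
    """log2((WWL2 + pseudo)/(WE2 + pseudo)); negative = higher in WE2."""
    mean_a_cpm = np.asarray(mean_a_cpm, dtype=float)
    mean_b_cpm = np.asarray(mean_b_cpm, dtype=float)
    return np.log2((mean_b_cpm + pseudo) / (mean_a_cpm + pseudo))


def call_degs(
    table: pd.DataFrame,
    fdr_threshold: float = FDR_THRESHOLD,
    lfc_threshold: float = LFC_THRESHOLD,
) -> tuple[pd.DataFrame, DEGSummary]:
    """Label DEGs: FDR < threshold and |log2FC| >= threshold (inclusive).

    ``table`` needs columns ``log2FC`` and ``FDR``.
    """
    out = table.copy()
    sig = (out["FDR"] < fdr_threshold) & (out["log2FC"].abs() >= lfc_threshold)
    status = np.full(len(out), NOT_SIGNIFICANT, dtype=object)
    status[sig.to_numpy() & (out["log2FC"] <= -lfc_threshold).to_numpy()] = HIGHER_IN_A
    status[sig.to_numpy() & (out["log2FC"] >= lfc_threshold).to_numpy()] = HIGHER_IN_B
    out["status"] = status
    summary = DEGSummary(
        n_total=int(sig.sum()),
        n_higher_in_A=int((out["status"] == HIGHER_IN_A).sum()),
        n_higher_in_B=int((out["status"] == HIGHER_IN_B).sum()),
    )
    return out, summary


# ---------------------------------------------------------------------------
# Full two-group analysis
# ---------------------------------------------------------------------------


def differential_expression(
    counts: CountMatrix,
    samples: pd.DataFrame,
    factors: NormFactors | None = None,
    fdr_threshold: float = FDR_THRESHOLD,
    lfc_threshold: float = LFC_THRESHOLD,
) -> tuple[pd.DataFrame, DEGSummary]:
    """Per-gene exact-test DE table for WE2 vs WWL2.

    Returns a DataFrame (gene_id index; log2FC, PValue, FDR, mean_cpm, status)
    and the DEG summary counts.
    """
    groups = treatment_groups(samples)
    ids_a, ids_b = groups[TREATMENT_A], groups[TREATMENT_B]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValidationError("each treatment needs >= 2 replicates")
    disp = estimate_dispersion(counts, samples, factors)
    lib = counts.library_sizes.astype(float)
    eff = lib if factors is None else factors.effective_sizes(lib)
    Y = counts.counts
    pvals = np.empty(len(Y))
    phi = disp.shrunk.to_numpy()
    arr_a = Y[ids_a].to_numpy(float)
    arr_b = Y[ids_b].to_numpy(float)
    sz_a = eff[ids_a].to_numpy()
    sz_b = eff[ids_b].to_numpy()
    for i in range(len(Y)):
        pvals[i] = nb_exact_test(arr_a[i], arr_b[i], phi[i], sz_a, sz_b)

    cpm_mat = cpm(counts, factors)
    mean_a = cpm_mat[ids_a].mean(axis=1)
    mean_b = cpm_mat[ids_b].mean(axis=1)
    table = pd.DataFrame(
        {
            "log2FC": log2fc(mean_a, mean_b),
            "PValue": pvals,
            "FDR": bh_adjust(pvals),
            "mean_cpm": cpm_mat.mean(axis=1),
        },
        index=Y.index,
    )
    table.index.name = "gene_id"
    labeled, summary = call_degs(table, fdr_threshold, lfc_threshold)
    logger.info(
        "%s DE: %d DEGs (%d higher in %s, %d higher in %s) of %d genes",
        counts.partner,
        summary.n_total,
        summary.n_higher_in_A,
        TREATMENT_A,
        summary.n_higher_in_B,
        TREATMENT_B,
        len(labeled),
    )
    return labeled, summary


# ---------------------------------------------------------------------------
# Sample-level QC
# ---------------------------------------------------------------------------


def pca_samples(log_expr: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on a genes x samples log-expression matrix.

    Genes are centered; sample coordinates come from the SVD of the centered
    matrix. Returns (coordinates: samples x PCs, percent variance per PC).
    """
    X = log_expr.to_numpy(float)
    if X.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if X.shape[1] < 3:
        logger.warning("PCA on fewer than 3 samples is degenerate")
    Xc = X - X.mean(axis=1, keepdims=True)
    _, sing, vt = np.linalg.svd(Xc, full_matrices=False)
    coords = vt.T * sing
    var = sing**2
    pct = 100.0 * var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    frame = pd.DataFrame(
        coords,
        index=log_expr.columns,
        columns=[f"PC{i+1}" for i in range(coords.shape[1])],
    )
    return frame, pct
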