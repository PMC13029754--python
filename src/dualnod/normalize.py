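"""Low-expression filtering, TMM normalization factors, CPM/FPKM.

The symbiont library of a nodule sample is small (a few percent of the reads),
so low-count noise is severe there; filtering uses a CPM threshold adjusted
for library size and group size, in the style of edgeR's ``filterByExpr``
defaults: a gene is kept iff its CPM reaches ``C = 10 / median library size in
millions`` in at least ``k`` samples (k = smallest group size) and its total
count across samples is at least 15.

Between-sample normalization is the trimmed mean of M-values (TMM): against a
reference sample, per-gene log-ratios (M) are trimmed 30% on each side by M
and 5% by average abundance (A), then combined with inverse-variance
(delta-method binomial) weights. Factors are rescaled to geometric mean 1 so
they redistribute, rather than change, the total sequencing depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneAnnotation, ValidationError, treatment_groups

logger = logging.getLogger("dualnod")

MIN_CPM_NUMERATOR = 10.0
MIN_TOTAL_COUNT = 15
TRIM_M = 0.30
TRIM_A = 0.05


@dataclass
class NormFactors:
    """Per-sample TMM factors (geometric mean 1) and the reference sample."""

    factors: pd.Series
    reference_sample: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValidationError("normalization factors must be positive")
        log_gm = np.log(self.factors.to_numpy()).mean()
        if abs(log_gm) > 1e-12:
            raise ValidationError("factors must have geometric mean 1")

    def effective_sizes(self, library_sizes: pd.Series) -> pd.Series:
        return library_sizes * self.factors.reindex(library_sizes.index)


def unit_factors(sample_ids) -> NormFactors:
    ids = list(sample_ids)
    return NormFactors(pd.Series(1.0, index=ids), ids[0])


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_low_expression(counts: CountMatrix, samples: pd.DataFrame) -> list[str]:
    """Gene ids passing the group-aware CPM filter.

    Keep gene g iff CPM_gj >= C in at least k samples (C = 10 / median library
    size in millions, k = smallest treatment group size) and the total count of
    g across all samples is >= 15.
    """
    groups = treatment_groups(samples)
    sizes = [len(v) for v in groups.values() if v]
    if not sizes:
        raise ValidationError("no samples assigned to treatments")
    k = min(sizes)
    lib = counts.library_sizes.to_numpy(float)
    if (lib <= 0).any():
        raise ValidationError("zero library size")
    c_thresh = MIN_CPM_NUMERATOR / (np.median(lib) / 1e6)
    cpm_mat = 1e6 * counts.counts.to_numpy(float) / lib
    n_above = (cpm_mat >= c_thresh).sum(axis=1)
    total = counts.counts.sum(axis=1).to_numpy()
    keep = (n_above >= k) & (total >= MIN_TOTAL_COUNT)
    kept = [g for g, flag in zip(counts.gene_ids, keep) if flag]
    if not kept:
        raise ValidationError("all genes removed by the expression filter")
    logger.info(
        "%s filter: kept %d / %d genes (CPM >= %.3g in >= %d samples, total >= %d)",
        counts.partner,
        len(kept),
        len(counts.gene_ids),
        c_thresh,
        k,
        MIN_TOTAL_COUNT,
    )
    return kept


# ---------------------------------------------------------------------------
# Expression units
# ---------------------------------------------------------------------------


def cpm(counts: CountMatrix, factors: NormFactors | None = None) -> pd.DataFrame:
    """Counts per million: CPM_gj = 1e6 * y_gj / (N_j * f_j)."""
    lib = counts.library_sizes.astype(float)
    if (lib <= 0).any():
        raise ValidationError("zero library size")
    eff = lib if factors is None else factors.effective_sizes(lib)
    return 1e6 * counts.counts / eff


def fpkm(
    counts: CountMatrix,
    lengths: GeneAnnotation | pd.Series,
    factors: NormFactors | None = None,
) -> pd.DataFrame:
    """FPKM/RPKM: 1e9 * y_gj / (N_j * f_j * len_g).

    For the host (fragment-based library) this is FPKM; for the symbiont
    (read-based library) the same arithmetic is conventionally called RPKM.
    """
    if isinstance(lengths, GeneAnnotation):
        lengths = lengths.lengths(counts.partner)
    missing = [g for g in counts.gene_ids if g not in lengths.index]
    if missing:
        raise ValidationError(f"missing gene lengths for: {missing[:10]}")
    len_bp = lengths.reindex(counts.gene_ids).astype(float)
    return cpm(counts, factors).mul(1e3 / len_bp, axis=0)


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def tmm_factors(
    counts: CountMatrix, trim_m: float = TRIM_M, trim_a: float = TRIM_A
) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors.

    Reference sample: the one whose upper quartile of nonzero CPM is closest
    to the mean of those upper quartiles (lowest index on ties). Genes zero in
    either member of a pair are excluded (no pseudocounts).
    """
    Y = counts.counts.to_numpy(float)
    N = Y.sum(axis=0)
    if (N <= 0).any():
        raise ValidationError("each sample needs at least one nonzero gene")
    uq = np.array(
        [np.percentile(1e6 * Y[Y[:, j] > 0, j] / N[j], 75) for j in range(Y.shape[1])]
    )
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    yr, Nr = Y[:, ref], N[ref]

    raw = np.ones(Y.shape[1])
    for j in range(Y.shape[1]):
        if j == ref:
            continue
        yk, Nk = Y[:, j], N[j]
        both = (yk > 0) & (yr > 0)
        if not both.any():
            logger.warning("TMM: no shared nonzero genes for sample %s; factor 1",
                           counts.sample_ids[j])
            continue
        fk, fr = yk[both] / Nk, yr[both] / Nr
        M = np.log2(fk / fr)
        A = 0.5 * np.log2(fk * fr)
        keep = _trim_mask(M, trim_m) & _trim_mask(A, trim_a)
        if not keep.any():
            logger.warning("TMM: no genes survive trimming for sample %s; factor 1",
                           counts.sample_ids[j])
            continue
        ykb, yrb = yk[both], yr[both]
        w = 1.0 / ((Nk - ykb) / (Nk * ykb) + (Nr - yrb) / (Nr * yrb))
        raw[j] = 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))

    rescaled = raw / np.exp(np.log(raw).mean())
    return NormFactors(
        pd.Series(rescaled, index=counts.sample_ids),
        counts.sample_ids[ref],
    )


def _trim_mask(values: np.ndarray, fraction: float) -> np.ndarray:
    """Keep the central part after discarding ``fraction`` on each side.

    Stable sort, so ties are broken by original index.
    """
    n = len(values)
    lo = int(np.floor(n * fraction))
    hi = n - lo
    order = np.argsort(values, kind="stable")
    mask = np.zeros(n, dtype=bool)
    if hi > lo:
        mask[order[lo:hi]] = True
    return mask
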