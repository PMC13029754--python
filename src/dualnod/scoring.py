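"""Gene-set module scores and cross-partner coupling.

A module score summarizes the coordinated expression tendency of a predefined
gene set in one sample: expression (FPKM/RPKM) is log2(x+1)-transformed, each
gene is z-scored across the samples, and the z values of the module's genes
are averaged per sample. Because every gene's z-scores sum to zero across
samples, each module's scores sum to zero too; with equal group sizes the two
treatment means are exact negatives of each other — the +/- mirror pattern
seen in per-treatment module-score tables.

Coupling between a host module and a symbiont module (e.g. host substrate
supply / microaerobic homeostasis vs rhizobial nitrogen fixation / microaerobic
respiration) is tested with the Pearson correlation of their per-sample
scores, with the exact Student-t transform for the two-sided p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ModuleDefinition, TREATMENT_A, TREATMENT_B, ValidationError, treatment_groups
from .pheno import welch_t

logger = logging.getLogger("dualnod")

SCORE_SD_DDOF = 1  # sample SD (n-1) in the per-gene z-scores


@dataclass
class ModuleScoreTable:
    """Per-module, per-sample scores plus bookkeeping of excluded genes."""

    scores: pd.DataFrame  # modules x samples
    genes_used: dict[str, list[str]]
    genes_excluded: dict[str, list[str]]  # zero-variance genes per module


@dataclass
class CouplingResult:
    module_pair: tuple[str, str]
    r: float
    p: float
    n: int
    degenerate: bool = False  # |r| = 1: p reported as 0


def module_scores(
    expr: pd.DataFrame,
    modules: list[ModuleDefinition],
    log_transform: bool = True,
    ddof: int = SCORE_SD_DDOF,
) -> ModuleScoreTable:
    """Score each module in each sample as the mean per-gene z of log2(x+1).

    ``expr`` is a genes x samples matrix of FPKM (host) or RPKM (symbiont);
    the statistic is unit-agnostic. Genes with zero variance across samples
    carry no information and are excluded with a warning; a module in which
    every gene is constant has no defined score and is an error.
    """
    if expr.shape[1] < 2:
        raise ValidationError("module scores need >= 2 samples")
    t_mat = np.log2(expr + 1.0) if log_transform else expr.astype(float)
    mean_g = t_mat.mean(axis=1)
    sd_g = t_mat.std(axis=1, ddof=ddof)

    missing = [m.module_id for m in modules
               if not any(g in expr.index for g in m.gene_ids)]
    if missing:
        raise ValidationError(f"modules with no genes in the expression matrix: {missing}")

    rows, used, excluded = {}, {}, {}
    for m in modules:
        present = [g for g in expr.index if g in m.gene_ids]
        sds = sd_g.loc[present]
        informative = [g for g in present if sds[g] > 0]
        dropped = [g for g in present if sds[g] == 0]
        if dropped:
            logger.warning(
                "module %s: excluded %d zero-variance gene(s)", m.module_id, len(dropped)
            )
        if not informative:
            raise ValidationError(
                f"module {m.module_id!r}: all genes have zero variance; score undefined"
            )
        z = t_mat.loc[informative].sub(mean_g.loc[informative], axis=0).div(
            sd_g.loc[informative], axis=0
        )
        rows[m.module_id] = z.mean(axis=0)
        used[m.module_id] = informative
        excluded[m.module_id] = dropped
    scores = pd.DataFrame(rows).T
    scores.index.name = "module_id"
    return ModuleScoreTable(scores=scores, genes_used=used, genes_excluded=excluded)


def group_summary(
    table: ModuleScoreTable, samples: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-module treatment means +/- SD with significance letters.

    Letters come from a two-tailed Welch t-test on the per-sample scores: the
    higher-scoring treatment gets 'a' and the other 'b' when p < alpha;
    otherwise both get 'a'.
    """
    groups = treatment_groups(samples)
    ids_a, ids_b = groups[TREATMENT_A], groups[TREATMENT_B]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValidationError("each treatment needs >= 2 replicates")
    records = []
    for module_id, row in table.scores.iterrows():
        a = row[ids_a].to_numpy(float)
        b = row[ids_b].to_numpy(float)
        t_stat, dof, p = welch_t(a, b)
        if p < alpha:
            letter_a, letter_b = ("a", "b") if a.mean() >= b.mean() else ("b", "a")
        else:
            letter_a = letter_b = "a"
        records.append(
            {
                "module_id": module_id,
                f"mean_{TREATMENT_A}": a.mean(),
                f"sd_{TREATMENT_A}": a.std(ddof=1),
                f"letter_{TREATMENT_A}": letter_a,
                f"mean_{TREATMENT_B}": b.mean(),
                f"sd_{TREATMENT_B}": b.std(ddof=1),
                f"letter_{TREATMENT_B}": letter_b,
                "t": t_stat,
                "df": dof,
                "p": p,
            }
        )
    return pd.DataFrame.from_records(records).set_index("module_id")


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via t = r*sqrt(n-2)/sqrt(1-r^2), df = n-2."""
    if n < 3:
        raise ValidationError("Pearson p-value needs n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValidationError("correlation must lie in [-1, 1]")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def coupling(scores_m1, scores_m2, module_pair: tuple[str, str] = ("m1", "m2")) -> CouplingResult:
    """Pearson coupling between two modules' per-sample scores.

    Inputs must be aligned per-sample vectors (same samples, same order).
    Perfect collinearity is flagged and reported with p = 0.
    """
    x = np.asarray(scores_m1, dtype=float)
    y = np.asarray(scores_m2, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("score vectors must be aligned")
    n = len(x)
    if n < 3:
        raise ValidationError("coupling needs >= 3 samples")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("correlation undefined for a zero-variance score vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    degenerate = bool(abs(r) >= 1.0 - 1e-12)
    p = 0.0 if degenerate else pearson_pvalue(r, n)
    if degenerate:
        logger.warning("coupling %s: |r| = 1 (collinear scores); p reported as 0",
                       module_pair)
    return CouplingResult(module_pair=module_pair, r=r, p=p, n=n, degenerate=degenerate)
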