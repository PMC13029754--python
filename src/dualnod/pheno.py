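"""Phenotype and qPCR statistics.

Covers the wet-lab-side arithmetic of a nodule symbiosis comparison: Welch's
t-test for replicate-level traits (shoot fresh weight, nitrogenase activity),
the acetylene-reduction (ARA) rate normalization to per-gram-nodule per-hour,
2^-ddCt relative quantification of RT-qPCR assays, and the sign-concordance
check between qPCR fold changes and RNA-seq log2FC.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .io import TREATMENT_A, TREATMENT_B, ValidationError

logger = logging.getLogger("dualnod")

QPCR_COLUMNS = ["target_gene", "reference_gene", "treatment", "replicate",
                "ct1", "ct2", "ct3"]
PHENOTYPE_COLUMNS = ["replicate_id", "treatment", "shoot_fw", "ethylene_rate"]


def welch_t(a, b) -> tuple[float, float, float]:
    """Two-tailed unpaired Welch's t-test.

    Returns (t, Welch-Satterthwaite df, two-sided p). Degenerate case of two
    zero-variance groups: p = 1 for equal means, p = 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("Welch's t-test needs >= 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0 and vb == 0:
        dof = float(na + nb - 2)
        if a.mean() == b.mean():
            return 0.0, dof, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), dof, 0.0
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    dof = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return float(t), float(dof), p


def ara_rate(ethylene_amount: float, incubation_h: float, nodule_fw_g: float) -> float:
    """Ethylene production rate per gram nodule fresh weight per hour.

    Units are the caller's: the result is amount / (h * g) in whatever amount
    unit the gas chromatograph reports.
    """
    if incubation_h <= 0 or nodule_fw_g <= 0:
        raise ValidationError("incubation time and nodule mass must be positive")
    if ethylene_amount < 0:
        raise ValidationError("ethylene amount must be nonnegative")
    return ethylene_amount / (incubation_h * nodule_fw_g)


def validate_qpcr(qpcr: pd.DataFrame) -> pd.DataFrame:
    missing = set(QPCR_COLUMNS) - set(qpcr.columns)
    if missing:
        raise ValidationError(f"qPCR table missing columns {sorted(missing)}")
    cts = qpcr[["ct1", "ct2", "ct3"]].to_numpy(float)
    if not ((cts > 0) & (cts < 45)).all():
        raise ValidationError("Ct values must lie in (0, 45)")
    return qpcr


def ddct(
    qpcr: pd.DataFrame, calibrator_treatment: str = TREATMENT_A
) -> pd.DataFrame:
    """2^-ddCt relative expression per target gene and treatment.

    Technical Ct triplets are averaged first; dCt = Ct_target - Ct_reference
    per biological replicate; ddCt subtracts the calibrator treatment's mean
    dCt; RQ = 2^-ddCt. Reference-gene measurements are the rows whose
    target_gene equals their reference_gene. Returns, per (gene, treatment),
    mean RQ +/- SEM over biological replicates.
    """
    validate_qpcr(qpcr)
    q = qpcr.copy()
    q["ct"] = q[["ct1", "ct2", "ct3"]].mean(axis=1)
    records = []
    for (target, reference), sub in q.groupby(["target_gene", "reference_gene"]):
        if target == reference:
            continue
        ref_rows = q[(q["target_gene"] == reference)]
        ref_ct = ref_rows.set_index(["treatment", "replicate"])["ct"]
        dct = {}
        for _, row in sub.iterrows():
            key = (row["treatment"], row["replicate"])
            if key not in ref_ct.index:
                raise ValidationError(
                    f"reference gene {reference!r} not measured for treatment "
                    f"{key[0]!r} replicate {key[1]}"
                )
            dct[key] = row["ct"] - float(ref_ct.loc[key])
        dct_s = pd.Series(dct)
        cal = dct_s[[k for k in dct_s.index if k[0] == calibrator_treatment]]
        if cal.empty:
            raise ValidationError(
                f"no measurements of {target!r} in calibrator treatment "
                f"{calibrator_treatment!r}"
            )
        ddct_s = dct_s - cal.mean()
        rq = 2.0 ** (-ddct_s)
        for treatment in sorted({k[0] for k in rq.index}):
            vals = rq[[k for k in rq.index if k[0] == treatment]].to_numpy()
            records.append(
                {
                    "target_gene": target,
                    "reference_gene": reference,
                    "treatment": treatment,
                    "mean_rq": vals.mean(),
                    "sem_rq": vals.std(ddof=1) / math.sqrt(len(vals))
                    if len(vals) > 1
                    else np.nan,
                    "n": len(vals),
                }
            )
    return pd.DataFrame.from_records(records)


def qpcr_log2_ratio(
    rq_table: pd.DataFrame,
    numerator: str = TREATMENT_A,
    denominator: str = TREATMENT_B,
) -> pd.Series:
    """Per-gene log2 of mean-RQ ratio between treatments (default WE2/WWL2)."""
    wide = rq_table.pivot(index="target_gene", columns="treatment", values="mean_rq")
    for t in (numerator, denominator):
        if t not in wide.columns:
            raise ValidationError(f"treatment {t!r} absent from RQ table")
    return np.log2(wide[numerator] / wide[denominator]).rename("qpcr_log2_ratio")


def concordance(qpcr_log2_ratios: pd.Series, rnaseq_log2fc: pd.Series) -> float:
    """Fraction of shared genes whose qPCR and RNA-seq directions agree.

    Orientation: the qPCR ratio is calibrator-over-other (WE2/WWL2) while the
    RNA-seq log2FC is WWL2/WE2, so agreement means
    sign(log2 RQ ratio) == sign(-log2FC).
    """
    shared = qpcr_log2_ratios.index.intersection(rnaseq_log2fc.index)
    if len(shared) == 0:
        raise ValidationError("no shared genes between qPCR and RNA-seq results")
    q_sign = np.sign(qpcr_log2_ratios.loc[shared].to_numpy(float))
    r_sign = np.sign(-rnaseq_log2fc.loc[shared].to_numpy(float))
    return float(np.mean(q_sign == r_sign))
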