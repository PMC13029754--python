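"""Gene-set over-representation analysis (ORA) for DEG lists.

Each user-supplied term (GMT gene set) is tested for over-representation of
DEGs against the expressed-gene universe with the one-sided hypergeometric
upper tail P(X >= k), followed by Benjamini-Hochberg FDR across all tested
terms. Only over-representation is tested: depletion is not a reported
outcome of a DEG enrichment screen here.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust
from .io import ModuleDefinition, ValidationError

logger = logging.getLogger("dualnod")

ENRICHMENT_FDR = 0.05
DIRECTIONS = ("all", "up", "down")


def ora(
    de_genes: set,
    universe: set,
    terms: list[ModuleDefinition],
    direction: str = "all",
    fdr_threshold: float = ENRICHMENT_FDR,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``de_genes`` in each term.

    The universe is the set of expressed (filter-surviving) genes; terms are
    intersected with it before testing and empty intersections are skipped.
    The BH family is the set of all tested terms (K >= 1).
    """
    if direction not in DIRECTIONS:
        raise ValidationError(f"direction must be one of {DIRECTIONS}")
    universe = set(universe)
    de_genes = set(de_genes)
    if not universe:
        raise ValidationError("empty universe")
    outside = de_genes - universe
    if outside:
        raise ValidationError(
            f"DEGs not in the universe: {sorted(outside)[:10]}"
        )
    n_universe = len(universe)
    n_de = len(de_genes)
    records = []
    for term in terms:
        term_genes = set(term.gene_ids) & universe
        big_k = len(term_genes)
        if big_k == 0:
            continue
        hits = sorted(term_genes & de_genes)
        k = len(hits)
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n_de))
        records.append(
            {
                "term_id": term.module_id,
                "k": k,
                "K": big_k,
                "n": n_de,
                "N": n_universe,
                "pvalue": min(p, 1.0),
                "genes": ",".join(hits),
                "direction": direction,
            }
        )
    result = pd.DataFrame.from_records(
        records, columns=["term_id", "k", "K", "n", "N", "pvalue", "genes", "direction"]
    )
    if len(result):
        result["fdr"] = bh_adjust(result["pvalue"].to_numpy())
        result["significant"] = result["fdr"] < fdr_threshold
        result = result.sort_values("pvalue", kind="stable").reset_index(drop=True)
    else:
        result["fdr"] = []
        result["significant"] = []
    return result[
        ["term_id", "k", "K", "n", "N", "pvalue", "fdr", "significant", "genes", "direction"]
    ]
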