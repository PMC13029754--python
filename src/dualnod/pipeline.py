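"""End-to-end orchestration: simulate-or-load -> filter -> normalize -> DE ->
enrich -> score -> couple -> phenotype/qPCR -> report.

``run_all`` executes every stage under one configuration, writes tab-separated
outputs plus a machine-readable JSON summary (stage counts, thresholds, seed,
config hash, versions), and logs to console and a run log. A rerun with an
identical configuration is deterministic.

Candidate genes operationalize pathway-node screening as a set intersection:
a gene is a candidate iff it is a DEG, belongs to a scored module, and its
fold-change direction agrees with the module's treatment-mean direction.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .de import differential_expression, pca_samples
from .enrichment import ora
from .io import (
    HOST,
    SYMBIONT,
    CountMatrix,
    TREATMENT_B,
    mapped_rates,
    read_counts,
    read_gene_lengths,
    read_gene_sets,
    read_samples,
    write_counts,
    write_gene_sets,
    write_samples,
)
from .normalize import cpm, filter_low_expression, fpkm, tmm_factors
from .pheno import concordance, ddct, qpcr_log2_ratio, welch_t
from .scoring import coupling, group_summary, module_scores
from .simulate import SimConfig, simulate_experiment

logger = logging.getLogger("dualnod")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_STAGE_FAILURE = 3


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    simulate: bool = True
    sim: SimConfig | None = None
    host_counts: str | None = None
    symbiont_counts: str | None = None
    samples_path: str | None = None
    gene_lengths: str | None = None
    modules_gmt: str | None = None
    phenotypes_path: str | None = None
    qpcr_path: str | None = None
    fdr: float = 0.05
    lfc: float = 1.0
    enrich_fdr: float = 0.05
    coupled_pair: tuple[str, str] = ("host_supply_microaerobic", "sym_nfix_respiration")

    def __post_init__(self) -> None:
        if self.fdr <= 0 or self.lfc <= 0 or self.enrich_fdr <= 0:
            raise ValueError("thresholds must be positive")
        if self.simulate and self.sim is None:
            self.sim = SimConfig(seed=self.seed)
        if not self.simulate:
            needed = [self.host_counts, self.symbiont_counts, self.samples_path,
                      self.gene_lengths, self.modules_gmt]
            if any(p is None for p in needed):
                raise ValueError(
                    "non-simulate runs need host/symbiont counts, samples, "
                    "gene lengths and a modules GMT"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig(**raw["sim"])
        if "coupled_pair" in raw:
            raw["coupled_pair"] = tuple(raw["coupled_pair"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {
            "outdir": self.outdir,
            "seed": self.seed,
            "simulate": self.simulate,
            "host_counts": self.host_counts,
            "symbiont_counts": self.symbiont_counts,
            "samples_path": self.samples_path,
            "gene_lengths": self.gene_lengths,
            "modules_gmt": self.modules_gmt,
            "phenotypes_path": self.phenotypes_path,
            "qpcr_path": self.qpcr_path,
            "fdr": self.fdr,
            "lfc": self.lfc,
            "enrich_fdr": self.enrich_fdr,
            "coupled_pair": list(self.coupled_pair),
            "sim": self.sim.to_dict() if self.sim is not None else None,
        }
        return d


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _setup_run_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    if logger.level == logging.NOTSET or logger.level > logging.INFO:
        logger.setLevel(logging.INFO)
    return handler


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; returns the summary dict (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(outdir)
    summary: dict = {
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "thresholds": {
            "fdr": config.fdr,
            "lfc": config.lfc,
            "enrich_fdr": config.enrich_fdr,
        },
        "config_sha256": _config_hash(config),
        "stages": {},
        "complete": False,
    }
    try:
        try:
            inputs = _stage_inputs(config, outdir)
        except Exception as exc:
            raise StageError("inputs", exc) from exc
        summary["stages"]["inputs"] = {
            "n_host_genes": len(inputs["host"].gene_ids),
            "n_symbiont_genes": len(inputs["symbiont"].gene_ids),
            "n_samples": len(inputs["samples"]),
            "symbiont_mapped_rate_min": float(
                mapped_rates(inputs["samples"], SYMBIONT).min()
            ),
            "symbiont_mapped_rate_max": float(
                mapped_rates(inputs["samples"], SYMBIONT).max()
            ),
        }

        de_tables: dict[str, pd.DataFrame] = {}
        scores_frames = []
        summaries_frames = []
        expr_by_partner = {}
        for partner in (HOST, SYMBIONT):
            counts: CountMatrix = inputs[partner]
            try:
                kept = filter_low_expression(counts, inputs["samples"])
                filtered = counts.subset_genes(kept)
                factors = tmm_factors(filtered)
                de_table, deg_summary = differential_expression(
                    filtered, inputs["samples"], factors, config.fdr, config.lfc
                )
                log_cpm = np.log2(cpm(filtered, factors) + 1.0)
                pca_coords, pct = pca_samples(log_cpm)
            except Exception as exc:
                raise StageError(f"de_{partner}", exc) from exc
            de_tables[partner] = de_table
            de_table.to_csv(outdir / f"de_{partner}.tsv", sep="\t")
            factors_out = pd.DataFrame(
                {
                    "sample_id": filtered.sample_ids,
                    "lib_size": filtered.library_sizes.to_numpy(),
                    "tmm_factor": factors.factors.to_numpy(),
                }
            )
            factors_out.to_csv(outdir / f"factors_{partner}.tsv", sep="\t", index=False)
            pca_out = pca_coords[["PC1", "PC2"]].copy()
            pca_out["pct_var_1"] = pct[0]
            pca_out["pct_var_2"] = pct[1] if len(pct) > 1 else 0.0
            pca_out.rename_axis("sample_id").to_csv(outdir / f"pca_{partner}.tsv", sep="\t")
            summary["stages"][f"de_{partner}"] = {
                "n_genes_tested": len(de_table),
                "n_filtered_out": len(counts.gene_ids) - len(de_table),
                "n_deg": deg_summary.n_total,
                "n_higher_in_WE2": deg_summary.n_higher_in_A,
                "n_higher_in_WWL2": deg_summary.n_higher_in_B,
            }

            try:
                partner_modules = [m for m in inputs["modules"] if m.partner == partner]
                universe = set(de_table.index)
                degs = set(de_table.index[de_table["status"] != "ns"])
                enr_frames = []
                for direction, subset in (
                    ("all", degs),
                    ("up", set(de_table.index[de_table["log2FC"] >= config.lfc]) & degs),
                    ("down", set(de_table.index[de_table["log2FC"] <= -config.lfc]) & degs),
                ):
                    if partner_modules:
                        enr_frames.append(
                            ora(subset, universe, partner_modules, direction,
                                config.enrich_fdr)
                        )
                enr = (
                    pd.concat(enr_frames, ignore_index=True)
                    if enr_frames
                    else pd.DataFrame()
                )
            except Exception as exc:
                raise StageError(f"enrichment_{partner}", exc) from exc
            enr.to_csv(outdir / f"enrichment_{partner}.tsv", sep="\t", index=False)
            summary["stages"][f"enrichment_{partner}"] = {
                "n_terms_tested": int(len(enr[enr["direction"] == "all"])) if len(enr) else 0,
                "n_significant_all": int(
                    enr[(enr["direction"] == "all") & enr["significant"]].shape[0]
                )
                if len(enr)
                else 0,
            }

            try:
                lengths = inputs["annotation"].lengths(partner)
                expr = fpkm(filtered, lengths, factors)
                expr_by_partner[partner] = expr
                if partner_modules:
                    table = module_scores(expr, partner_modules)
                    scores_frames.append(table.scores)
                    summaries_frames.append(group_summary(table, inputs["samples"]))
            except Exception as exc:
                raise StageError(f"scores_{partner}", exc) from exc

        scores = pd.concat(scores_frames) if scores_frames else pd.DataFrame()
        scores.to_csv(outdir / "scores.tsv", sep="\t")
        score_summaries = (
            pd.concat(summaries_frames) if summaries_frames else pd.DataFrame()
        )
        score_summaries.to_csv(outdir / "score_groups.tsv", sep="\t")
        summary["stages"]["scores"] = {"n_modules": int(len(scores))}

        try:
            couple_rows = []
            m1, m2 = config.coupled_pair
            if m1 in scores.index and m2 in scores.index:
                res = coupling(scores.loc[m1], scores.loc[m2], (m1, m2))
                couple_rows.append(
                    {
                        "module_1": m1,
                        "module_2": m2,
                        "r": res.r,
                        "p": res.p,
                        "n": res.n,
                        "degenerate": res.degenerate,
                    }
                )
            coupling_df = pd.DataFrame.from_records(couple_rows)
        except Exception as exc:
            raise StageError("coupling", exc) from exc
        coupling_df.to_csv(outdir / "coupling.tsv", sep="\t", index=False)
        summary["stages"]["coupling"] = (
            couple_rows[0] if couple_rows else {"r": None, "p": None}
        )

        try:
            candidates = screen_candidates(de_tables, inputs["modules"], score_summaries)
        except Exception as exc:
            raise StageError("candidates", exc) from exc
        candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        summary["stages"]["candidates"] = {"n_candidates": int(len(candidates))}

        if len(inputs["phenotypes"]):
            try:
                pheno_df = _phenotype_stats(inputs["phenotypes"])
            except Exception as exc:
                raise StageError("phenotypes", exc) from exc
            pheno_df.to_csv(outdir / "pheno.tsv", sep="\t", index=False)
            summary["stages"]["phenotypes"] = {
                row["trait"]: {"p": row["p"]} for _, row in pheno_df.iterrows()
            }
        else:
            summary["stages"]["phenotypes"] = "not provided"

        if len(inputs["qpcr"]):
            try:
                rq = ddct(inputs["qpcr"].drop(columns=["partner"], errors="ignore"))
                rq.to_csv(outdir / "qpcr.tsv", sep="\t", index=False)
                all_de = pd.concat([de_tables[HOST], de_tables[SYMBIONT]])
                ratios = qpcr_log2_ratio(rq)
                shared = ratios.index.intersection(all_de.index)
                agreement = (
                    concordance(ratios.loc[shared], all_de.loc[shared, "log2FC"])
                    if len(shared)
                    else None
                )
            except Exception as exc:
                raise StageError("qpcr", exc) from exc
            summary["stages"]["qpcr"] = {
                "n_assayed": int(rq["target_gene"].nunique()),
                "rnaseq_sign_concordance": agreement,
            }
        else:
            summary["stages"]["qpcr"] = "not provided"

        summary["complete"] = True
        return summary
    finally:
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        logger.removeHandler(handler)
        handler.close()


def screen_candidates(
    de_tables: dict[str, pd.DataFrame],
    modules,
    score_summaries: pd.DataFrame,
) -> pd.DataFrame:
    """Pathway-node candidates: DEG + module member + direction-consistent.

    A module's direction is the sign of its WWL2 mean score (equivalently of
    WWL2 mean minus WE2 mean, since the group means mirror); a member gene is
    a candidate when the sign of its log2FC matches it.
    """
    rows = []
    for m in modules:
        if m.module_id not in score_summaries.index:
            continue
        direction = np.sign(score_summaries.loc[m.module_id, f"mean_{TREATMENT_B}"])
        de_table = de_tables[m.partner]
        members = [g for g in de_table.index if g in m.gene_ids]
        for g in members:
            row = de_table.loc[g]
            if row["status"] == "ns":
                continue
            if np.sign(row["log2FC"]) != direction:
                continue
            rows.append(
                {
                    "gene_id": g,
                    "module_id": m.module_id,
                    "partner": m.partner,
                    "log2FC": row["log2FC"],
                    "FDR": row["FDR"],
                    "status": row["status"],
                }
            )
    return pd.DataFrame.from_records(
        rows, columns=["gene_id", "module_id", "partner", "log2FC", "FDR", "status"]
    )


def _phenotype_stats(phenotypes: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for trait in ("shoot_fw", "ethylene_rate"):
        groups = {
            t: phenotypes.loc[phenotypes["treatment"] == t, trait].to_numpy()
            for t in phenotypes["treatment"].unique()
        }
        (t_a, vals_a), (t_b, vals_b) = sorted(groups.items())
        t_stat, dof, p = welch_t(vals_a, vals_b)
        rows.append(
            {
                "trait": trait,
                f"mean_{t_a}": vals_a.mean(),
                f"sem_{t_a}": vals_a.std(ddof=1) / np.sqrt(len(vals_a)),
                f"mean_{t_b}": vals_b.mean(),
                f"sem_{t_b}": vals_b.std(ddof=1) / np.sqrt(len(vals_b)),
                "t": t_stat,
                "df": dof,
                "p": p,
            }
        )
    return pd.DataFrame.from_records(rows)


def _stage_inputs(config: RunConfig, outdir: Path) -> dict:
    if config.simulate:
        sim = simulate_experiment(config.sim)
        write_counts(sim.host, outdir / "counts_host.tsv")
        write_counts(sim.symbiont, outdir / "counts_symbiont.tsv")
        write_samples(sim.samples, outdir / "samples.tsv")
        write_gene_sets(sim.modules, outdir / "modules.gmt")
        sim.truth.frame().to_csv(outdir / "truth.tsv", sep="\t")
        sim.annotation.table.to_csv(outdir / "gene_lengths.tsv", sep="\t", index=False)
        return {
            "host": sim.host,
            "symbiont": sim.symbiont,
            "samples": sim.samples,
            "modules": sim.modules,
            "annotation": sim.annotation,
            "phenotypes": sim.phenotypes,
            "qpcr": sim.qpcr,
        }
    host = read_counts(config.host_counts, HOST)
    symbiont = read_counts(config.symbiont_counts, SYMBIONT)
    samples = read_samples(config.samples_path)
    annotation = read_gene_lengths(config.gene_lengths)
    modules = read_gene_sets(config.modules_gmt)
    phenotypes = (
        pd.read_csv(config.phenotypes_path, sep="\t")
        if config.phenotypes_path
        else pd.DataFrame(columns=["replicate_id", "treatment", "shoot_fw",
                                   "ethylene_rate"])
    )
    qpcr = (
        pd.read_csv(config.qpcr_path, sep="\t") if config.qpcr_path else pd.DataFrame()
    )
    return {
        "host": host,
        "symbiont": symbiont,
        "samples": samples,
        "modules": modules,
        "annotation": annotation,
        "phenotypes": phenotypes,
        "qpcr": qpcr,
    }
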