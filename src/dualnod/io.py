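"""Readers and writers for the on-disk artifacts of a dual-transcriptome analysis.

A nodule RNA-seq experiment produces one count matrix per partner (the plant
host and the bacterial symbiont), a sample sheet with the read-accounting
needed to express the symbiont signal as a fraction of the whole library,
gene lengths for FPKM/RPKM, and GMT gene-set files defining the functional
modules that are scored downstream.

All identifiers are case-sensitive and taken verbatim: real nodule data mixes
host ids like ``MsG0880046740.01`` with bacterial locus tags like
``SM2011_RS02280``, so no character is ever sanitized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("dualnod")

HOST = "host"
SYMBIONT = "symbiont"
PARTNERS = (HOST, SYMBIONT)

#: Treatment labels: nodules induced by rhizobial strain WE2 (group A, the
#: high-fixation strain) vs strain WWL2 (group B). Fold changes everywhere in
#: this package are oriented log2(WWL2/WE2).
TREATMENT_A = "WE2"
TREATMENT_B = "WWL2"
TREATMENTS = (TREATMENT_A, TREATMENT_B)

SAMPLE_COLUMNS = [
    "sample_id",
    "treatment",
    "replicate",
    "total_clean_reads",
    "host_mapped",
    "symbiont_mapped",
]


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


class ParseError(ValueError):
    """A file does not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample counts for one partner.

    ``counts`` is a genes-by-samples DataFrame with unique string indices.
    """

    counts: pd.DataFrame
    partner: str

    def __post_init__(self) -> None:
        if self.partner not in PARTNERS:
            raise ValidationError(f"unknown partner {self.partner!r}")
        df = self.counts
        if df.shape[0] < 1 or df.shape[1] < 2:
            raise ValidationError(
                f"count matrix must have >=1 gene and >=2 samples, got {df.shape}"
            )
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.floor(arr)):
                df = df.astype(np.int64)
                arr = df.to_numpy()
            else:
                raise ValidationError("counts must be integers")
        if (arr < 0).any():
            raise ValidationError("counts must be nonnegative")
        self.counts = df.astype(np.int64)
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)
        self.counts.index.name = "gene_id"
        self.counts.columns.name = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        """Restrict to the given genes, preserving the original gene order."""
        keep = [g for g in self.gene_ids if g in set(gene_ids)]
        if not keep:
            raise ValidationError("gene subset is empty")
        return CountMatrix(self.counts.loc[keep].copy(), self.partner)


@dataclass(frozen=True)
class ModuleDefinition:
    """A named gene set tied to one partner: the unit of scoring/enrichment."""

    module_id: str
    partner: str
    gene_ids: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if self.partner not in PARTNERS:
            raise ValidationError(f"unknown partner {self.partner!r}")
        if not self.gene_ids:
            raise ValidationError(f"module {self.module_id!r} has no genes")


@dataclass
class GeneAnnotation:
    """Per-gene lengths (bp) used for FPKM/RPKM."""

    table: pd.DataFrame  # columns: gene_id, length_bp, partner

    def __post_init__(self) -> None:
        t = self.table
        missing = {"gene_id", "length_bp", "partner"} - set(t.columns)
        if missing:
            raise ValidationError(f"gene annotation missing columns {sorted(missing)}")
        if (t["length_bp"] < 1).any():
            raise ValidationError("gene lengths must be >= 1 bp")
        if t["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene ids in annotation")

    def lengths(self, partner: str | None = None) -> pd.Series:
        t = self.table
        if partner is not None:
            t = t[t["partner"] == partner]
        return pd.Series(
            t["length_bp"].to_numpy(), index=t["gene_id"].to_numpy(), name="length_bp"
        )


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet (treatments, replicates, read accounting)."""
    missing = set(SAMPLE_COLUMNS) - set(samples.columns)
    if missing:
        raise ValidationError(f"sample table missing columns {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids")
    bad = set(samples["treatment"]) - set(TREATMENTS)
    if bad:
        raise ValidationError(f"unknown treatments {sorted(bad)}; expected {TREATMENTS}")
    if (samples["replicate"] < 1).any():
        raise ValidationError("replicate numbers must be positive")
    for col in ("host_mapped", "symbiont_mapped"):
        if (samples[col] > samples["total_clean_reads"]).any():
            raise ValidationError(f"{col} exceeds total_clean_reads")
    return samples


def treatment_groups(samples: pd.DataFrame) -> dict[str, list[str]]:
    """Map treatment -> ordered sample ids."""
    return {
        t: samples.loc[samples["treatment"] == t, "sample_id"].tolist()
        for t in TREATMENTS
    }


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_samples(df)


def write_samples(samples: pd.DataFrame, path) -> None:
    validate_samples(samples).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


def read_counts(path, partner: str, dialect: str = "tsv") -> CountMatrix:
    """Read a count matrix.

    ``tsv``: gene_id in the first column, one column per sample, tab-separated.
    ``triplet``: sparse ``gene<TAB>sample<TAB>count`` rows after two
    declaration lines ``%genes ...`` and ``%samples ...`` fixing the full
    (ordered) gene and sample universe; unmentioned cells are zero.
    """
    if dialect == "tsv":
        return _read_counts_tsv(path, partner)
    if dialect == "triplet":
        return _read_counts_triplet(path, partner)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_counts_tsv(path, partner: str) -> CountMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    fields = header.split("\t")
    if len(fields) < 3 or fields[0] != "gene_id":
        raise ParseError(
            f"{path}:1: header must be 'gene_id<TAB>sample...', got {header!r}"
        )
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_integer_cells(df, path)
    return CountMatrix(df, partner)


def _read_counts_triplet(path, partner: str) -> CountMatrix:
    genes: list[str] | None = None
    samples: list[str] | None = None
    entries: list[tuple[str, str, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%%") or line.startswith("#"):
                continue  # MatrixMarket-style banner / comments
            if line.startswith("%genes"):
                genes = line.split("\t")[1:]
                continue
            if line.startswith("%samples"):
                samples = line.split("\t")[1:]
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected gene<TAB>sample<TAB>count")
            g, s, v = parts
            try:
                count = int(v)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer count {v!r}") from exc
            entries.append((g, s, count))
    if genes is None or samples is None:
        raise ParseError(f"{path}: missing %genes / %samples declaration lines")
    df = pd.DataFrame(0, index=pd.Index(genes, dtype=str), columns=samples, dtype=np.int64)
    seen: set[tuple[str, str]] = set()
    for g, s, count in entries:
        if g not in df.index:
            raise ParseError(f"{path}: undeclared gene id {g!r}")
        if s not in df.columns:
            raise ParseError(f"{path}: undeclared sample id {s!r}")
        if (g, s) in seen:
            raise ParseError(f"{path}: duplicate entry for ({g}, {s})")
        seen.add((g, s))
        df.loc[g, s] = count
    return CountMatrix(df, partner)


def _check_integer_cells(df: pd.DataFrame, path) -> None:
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ParseError(f"{path}: non-numeric cells in count matrix")
    if np.issubdtype(arr.dtype, np.floating) and not np.all(arr == np.floor(arr)):
        raise ValidationError(f"{path}: non-integer counts")


def write_counts(counts: CountMatrix, path, dialect: str = "tsv") -> None:
    if dialect == "tsv":
        out = counts.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")
    elif dialect == "triplet":
        with open(path, "w") as fh:
            fh.write("%genes\t" + "\t".join(counts.gene_ids) + "\n")
            fh.write("%samples\t" + "\t".join(counts.sample_ids) + "\n")
            arr = counts.counts.to_numpy()
            for i, g in enumerate(counts.gene_ids):
                for j, s in enumerate(counts.sample_ids):
                    if arr[i, j] != 0:
                        fh.write(f"{g}\t{s}\t{arr[i, j]}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Gene sets (GMT) and gene lengths
# ---------------------------------------------------------------------------


def read_gene_sets(path, partner: str = HOST) -> list[ModuleDefinition]:
    """Read GMT gene sets: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicated genes within a line are dropped with a warning; a repeated set
    name is an error. The partner tag is not part of GMT; callers say which
    organism the file describes (or encode it in the description field as
    ``partner=host|symbiont``, which takes precedence).
    """
    modules: list[ModuleDefinition] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, desc, genes = parts[0], parts[1], parts[2:]
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene set {name!r}")
            seen.add(name)
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                logger.warning(
                    "gene set %s: %d duplicated gene ids collapsed",
                    name,
                    len(genes) - len(unique),
                )
            line_partner = partner
            for token in desc.split():
                if token.startswith("partner="):
                    line_partner = token.split("=", 1)[1]
            modules.append(
                ModuleDefinition(name, line_partner, frozenset(unique), desc)
            )
    return modules


def write_gene_sets(modules: list[ModuleDefinition], path) -> None:
    with open(path, "w") as fh:
        for m in modules:
            desc = m.description or f"partner={m.partner}"
            if "partner=" not in desc:
                desc = f"{desc} partner={m.partner}".strip()
            fh.write("\t".join([m.module_id, desc, *sorted(m.gene_ids)]) + "\n")


def read_gene_lengths(path) -> GeneAnnotation:
    return GeneAnnotation(pd.read_csv(path, sep="\t"))


def write_gene_lengths(annotation: GeneAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Read accounting
# ---------------------------------------------------------------------------


def mapped_rate(mapped: int, total: int) -> float:
    """Partner-mapped reads as a percentage of total clean reads.

    In a mixed host/symbiont library this measures the share of the bacterial
    (or host) signal in the whole library, not an alignment quality rate.
    """
    if total <= 0:
        raise ValidationError("mapped rate undefined for total <= 0")
    if mapped < 0 or mapped > total:
        raise ValidationError("mapped reads must satisfy 0 <= mapped <= total")
    return 100.0 * mapped / total


def mapped_rates(samples: pd.DataFrame, partner: str = SYMBIONT) -> pd.Series:
    """Per-sample mapped rate (%) for one partner from the sample sheet."""
    validate_samples(samples)
    col = "symbiont_mapped" if partner == SYMBIONT else "host_mapped"
    vals = [
        mapped_rate(m, t)
        for m, t in zip(samples[col], samples["total_clean_reads"])
    ]
    return pd.Series(vals, index=samples["sample_id"].to_numpy(), name=f"{partner}_rate")
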