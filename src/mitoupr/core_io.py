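"""Domain types and TSV readers/writers shared by the whole pipeline.

The pipeline starts from gene-level expression (counts per million, genes x
samples), per-condition up-regulated gene lists, a ChIP-bound gene list, and
qPCR Ct tables.  Everything here is plain tab-separated text: UTF-8, '.'
decimal, no quoting, floats written with 6 significant digits so that a
write/read round trip is stable.

Gene identifiers come in two namespaces in C. elegans work (sequence names
like ``C07G1.7`` and locus names like ``clec-17``); :class:`GeneAliasMap`
folds aliases onto a canonical ID (the sequence name, by policy) before any
set logic runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default genotype vocabulary: wild type, the atfs-1(gk3094) loss-of-function
#: mutant, the mitochondrial mutant nuo-6, the nuo-6;atfs-1 epistasis double,
#: the constitutively active atfs-1 alleles et15/et17, spg-7 RNAi knockdown,
#: and the long-lived validation mutant isp-1.
DEFAULT_GENOTYPES = (
    "WT",
    "atfs-1",
    "nuo-6",
    "nuo-6;atfs-1",
    "et15",
    "et17",
    "spg-7i",
    "isp-1",
)

SIGNATURE_COLUMNS = (
    "gene_id",
    "score",
    "vc_score",
    "rank_score",
    "rank_vc",
    "chip_bound",
    "validated",
)

QPCR_COLUMNS = ("strain", "target_gene", "reference_gene", "replicate", "ct")

FLOAT_FORMAT = "%.6g"


class GeneAliasMap:
    """Functional mapping alias -> canonical gene ID.

    Canonical IDs are fixed points: an ID that appears as a canonical value
    may not itself be an alias of something else.  IDs not present in the
    map pass through unchanged.
    """

    def __init__(self, pairs: Mapping[str, str] | Iterable[tuple[str, str]] = ()):
        mapping: dict[str, str] = {}
        items = pairs.items() if isinstance(pairs, Mapping) else pairs
        for alias, canonical in items:
            if alias in mapping and mapping[alias] != canonical:
                raise ValueError(
                    f"alias {alias!r} maps to both {mapping[alias]!r} and {canonical!r}"
                )
            mapping[alias] = canonical
        for alias, canonical in mapping.items():
            if canonical in mapping and mapping[canonical] != canonical:
                raise ValueError(
                    f"canonical ID {canonical!r} is itself aliased to "
                    f"{mapping[canonical]!r}; canonical IDs must be fixed points"
                )
        self._map = mapping

    @classmethod
    def from_tsv(cls, path) -> "GeneAliasMap":
        """Read a two-column (alias, canonical) TSV, '#' comments ignored."""
        pairs = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(f"alias map line is not two columns: {line!r}")
                pairs.append((fields[0], fields[1]))
        return cls(pairs)

    def canonical(self, gene_id: str) -> str:
        return self._map.get(gene_id, gene_id)

    def normalize(self, gene_ids: Iterable[str]) -> list[str]:
        return [self.canonical(g) for g in gene_ids]

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._map


@dataclass
class ExpressionMatrix:
    """Genes x samples CPM matrix with per-sample genotype/replicate metadata.

    ``values`` is indexed by gene ID with sample IDs as columns;
    ``sample_meta`` is indexed by sample ID with columns ``genotype`` and
    ``replicate``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    genotypes: tuple[str, ...] = DEFAULT_GENOTYPES

    def __post_init__(self):
        self.validate()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("expression values must be finite")
        if (vals < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene IDs: {sorted(dupes)}")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples absent from metadata: {sorted(missing)}")
        meta = self.sample_meta.loc[list(self.values.columns)]
        unknown = set(meta["genotype"]) - set(self.genotypes)
        if unknown:
            raise ValueError(f"genotype labels outside vocabulary: {sorted(unknown)}")
        if (meta["replicate"].astype(int) < 1).any():
            raise ValueError("replicate indices must be positive integers")
        for genotype, group in meta.groupby("genotype"):
            if group["replicate"].duplicated().any():
                raise ValueError(f"duplicate replicate index within genotype {genotype!r}")

    def samples_for(self, genotype: str) -> list[str]:
        meta = self.sample_meta.loc[list(self.values.columns)]
        return list(meta.index[meta["genotype"] == genotype])

    def submatrix(self, genotype: str) -> pd.DataFrame:
        """CPM values for one genotype's replicates (genes x replicates)."""
        return self.values[self.samples_for(genotype)]


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated, alias-normalized collection of gene IDs."""

    name: str
    genes: frozenset[str]
    condition: str = ""
    source: str = ""

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __iter__(self):
        return iter(sorted(self.genes))


@dataclass
class QpcrTable:
    """Ct measurements: one row per (strain, target_gene, replicate).

    The reference gene's own Ct is stored as rows whose ``target_gene``
    equals their ``reference_gene``; every target row must have a matching
    reference row for its strain/replicate.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)[list(QPCR_COLUMNS)].copy()
        self.df["replicate"] = self.df["replicate"].astype(int)
        self.df["ct"] = self.df["ct"].astype(float)
        self.validate()

    def validate(self) -> None:
        ct = self.df["ct"].to_numpy()
        if not np.all(np.isfinite(ct)):
            raise ValueError("Ct values must be finite")
        if ((ct < 5) | (ct > 40)).any():
            warnings.warn("Ct values outside the typical 5-40 range", stacklevel=2)
        if (self.df["replicate"] < 1).any():
            raise ValueError("replicate indices must be positive")
        ref_rows = self.df[self.df["target_gene"] == self.df["reference_gene"]]
        have_ref = set(zip(ref_rows["strain"], ref_rows["reference_gene"], ref_rows["replicate"]))
        for _, row in self.df.iterrows():
            key = (row["strain"], row["reference_gene"], row["replicate"])
            if key not in have_ref:
                raise ValueError(
                    f"no reference-gene Ct for strain={row['strain']!r} "
                    f"reference={row['reference_gene']!r} replicate={row['replicate']}"
                )


def _normalize_index(ids: Iterable[str], alias_map: GeneAliasMap | None) -> list[str]:
    ids = [str(g).strip() for g in ids]
    if alias_map is None:
        return ids
    normalized = alias_map.normalize(ids)
    n_changed = sum(a != b for a, b in zip(ids, normalized))
    if n_changed:
        logger.info("alias-normalized %d gene IDs", n_changed)
    return normalized


def read_expression_matrix(
    path,
    meta_path,
    alias_map: GeneAliasMap | None = None,
    genotypes: tuple[str, ...] = DEFAULT_GENOTYPES,
) -> ExpressionMatrix:
    """Read a CPM matrix TSV (first column gene IDs, header = sample IDs)
    plus a sample-metadata TSV with columns sample_id, genotype, replicate.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = _normalize_index(values.index, alias_map)
    if pd.Index(values.index).duplicated().any():
        dupes = pd.Index(values.index)
        collisions = sorted(dupes[dupes.duplicated()].unique())
        raise ValueError(
            f"duplicate gene IDs after alias normalization: {collisions}"
        )
    meta = pd.read_csv(meta_path, sep="\t")
    required = {"sample_id", "genotype", "replicate"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    meta = meta.set_index("sample_id")
    return ExpressionMatrix(values=values, sample_meta=meta, genotypes=genotypes)


def write_expression_matrix(matrix: ExpressionMatrix, path, meta_path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene_id")
    matrix.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_gene_set(
    path,
    name: str,
    condition: str = "",
    alias_map: GeneAliasMap | None = None,
) -> GeneSet:
    """Read a one-gene-per-line TSV.  '#' comments and blank lines are
    ignored; a leading ``gene_id``/``gene`` header line is skipped.  An empty
    file yields an empty set with a warning.
    """
    genes: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            token = line.strip().split("\t")[0].strip()
            if not token or token.startswith("#"):
                continue
            if i == 0 and token.lower() in {"gene_id", "gene"}:
                continue
            genes.append(token)
    if not genes:
        warnings.warn(f"gene list {path!s} is empty", stacklevel=2)
    genes = _normalize_index(genes, alias_map)
    return GeneSet(name=name, genes=frozenset(genes), condition=condition, source=str(path))


def write_gene_set(gene_set: GeneSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\n")
        for gene in gene_set:
            fh.write(f"{gene}\n")


def signature_sort(table: pd.DataFrame) -> pd.DataFrame:
    """Deterministic row order: descending score, then lexicographic gene ID."""
    return table.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def write_signature_table(table: pd.DataFrame, path) -> None:
    """Write a signature table TSV in deterministic order (score desc,
    gene ID as tie-break), floats at 6 significant digits."""
    missing = set(SIGNATURE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"signature table missing columns: {sorted(missing)}")
    out = signature_sort(table)[list(SIGNATURE_COLUMNS)]
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_signature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(SIGNATURE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"signature table missing columns: {sorted(missing)}")
    if len(table):
        for col in ("chip_bound", "validated"):
            table[col] = table[col].astype(bool)
        for col in ("rank_score", "rank_vc"):
            table[col] = table[col].astype(int)
    return table


def read_qpcr_table(path) -> QpcrTable:
    df = pd.read_csv(path, sep="\t")
    missing = set(QPCR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    return QpcrTable(df=df)


def write_qpcr_table(table: QpcrTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def load_primer_table() -> pd.DataFrame:
    """Packaged qPCR primer metadata (target gene, forward, reverse)."""
    with resources.files("mitoupr.data").joinpath("primers.tsv").open("r") as fh:
        return pd.read_csv(fh, sep="\t")
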