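"""Readers, writers and container types for expression cohorts.

Everything downstream operates on three containers: an :class:`ExpressionMatrix`
(genes x samples, TPM or log2(TPM+1)), a clinical table (plain
:class:`pandas.DataFrame` with a fixed column contract, see
:func:`validate_clinical`), and a :class:`GeneSetCollection` backed by GMT
files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_gene_sets",
    "write_gene_sets",
    "log_transform",
    "validate_clinical",
    "CLINICAL_COLUMNS",
    "CONTAMINATION_TISSUES",
]

CONTAMINATION_TISSUES = ["hepatic", "pancreatic", "duodenal", "lymphatic", "neural"]

#: required columns of a clinical table
CLINICAL_COLUMNS = [
    "sample_id",
    "age",
    "sex",
    "site",
    "stage_group",
    "differentiation",
    "os_days",
    "event",
    "death_unrelated",
] + [f"contamination_{t}" for t in CONTAMINATION_TISSUES]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression matrix.

    Parameters
    ----------
    data
        DataFrame indexed by unique gene symbols, columns are sample IDs.
    scale
        ``"tpm"`` for raw transcripts-per-million, ``"log2p1"`` after
        :func:`log_transform`.
    """

    data: pd.DataFrame
    scale: str = "tpm"

    def __post_init__(self) -> None:
        if self.scale not in ("tpm", "log2p1"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.data.isna().any().any():
            gene, sample = _first_missing(self.data)
            raise ValueError(f"missing value at gene {gene!r}, sample {sample!r}")
        if self.scale == "tpm" and (self.data.values < 0).any():
            raise ValueError("negative TPM values")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene symbol after collapse: {dup!r}")
        self.data.index.name = "gene"
        self.data.columns.name = None

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(samples)].copy(), self.scale)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes), :].copy(), self.scale)


def _first_missing(df: pd.DataFrame) -> tuple[str, str]:
    mask = df.isna()
    for gene, row in mask.iterrows():
        if row.any():
            return str(gene), str(row[row].index[0])
    raise AssertionError("no missing value")  # pragma: no cover


@dataclass
class GeneSetCollection:
    """Named, ordered gene sets with optional up/down direction tags."""

    sets: dict[str, list[str]]
    directions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            # de-duplicate preserving order
            self.sets[name] = list(dict.fromkeys(str(g) for g in genes))
        for name, d in self.directions.items():
            if d not in ("up", "down"):
                raise ValueError(f"direction of {name!r} must be 'up' or 'down'")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


def read_expression(path, collapse: str = "max_mean") -> ExpressionMatrix:
    """Read a TSV/CSV expression matrix (genes as rows, samples as columns).

    Duplicate gene rows are collapsed: ``max_mean`` keeps the row with the
    highest mean expression, ``first`` keeps the first occurrence.
    """
    if collapse not in ("max_mean", "first"):
        raise ValueError(f"unknown collapse policy {collapse!r}")
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    if df.isna().any().any():
        gene, sample = _first_missing(df)
        raise ValueError(f"missing value at gene {gene!r}, sample {sample!r} in {path}")
    if df.index.duplicated().any():
        if collapse == "max_mean":
            means = df.mean(axis=1)
            order = np.argsort(-means.values, kind="stable")
            df = df.iloc[order]
        df = df[~df.index.duplicated(keep="first")]
        df = df.sort_index()
    return ExpressionMatrix(df.astype(float), scale="tpm")


def write_expression(expr: ExpressionMatrix, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    expr.data.to_csv(path, sep=sep, index_label="gene")


def read_gene_sets(path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, list[str]] = {}
    directions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {lineno}: fewer than 3 fields")
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"malformed GMT line {lineno}: empty gene list")
            sets[name] = genes
            if desc in ("up", "down"):
                directions[name] = desc
    return GeneSetCollection(sets, directions)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.directions.get(name, "na")
            fh.write("\t".join([name, desc] + list(genes)) + "\n")


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Return log2(TPM+1) matrix. Re-applying to already-log data is an error."""
    if expr.scale != "tpm":
        raise ValueError("log_transform requires a TPM-scale matrix")
    return ExpressionMatrix(np.log2(expr.data + 1.0), scale="log2p1")


def validate_clinical(clin: pd.DataFrame) -> pd.DataFrame:
    """Validate/normalize a clinical table against the column contract.

    Adds ``contamination_overall`` (sum of per-tissue fractions, capped at 1)
    when absent. Returns a copy indexed by ``sample_id``.
    """
    missing = [c for c in CLINICAL_COLUMNS if c not in clin.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    clin = clin.copy()
    if "contamination_overall" not in clin.columns:
        frac = clin[[f"contamination_{t}" for t in CONTAMINATION_TISSUES]].sum(axis=1)
        clin["contamination_overall"] = frac.clip(upper=1.0)
    co = clin["contamination_overall"]
    if co.isna().any():
        bad = clin.loc[co.isna(), "sample_id"].iloc[0]
        raise ValueError(f"sample {bad!r} missing contamination_overall")
    if ((co < 0) | (co > 1)).any():
        raise ValueError("contamination_overall outside [0, 1]")
    if (clin["os_days"] < 0).any():
        raise ValueError("negative os_days")
    if not clin["event"].isin([0, 1]).all():
        raise ValueError("event must be 0/1")
    if not clin["death_unrelated"].isin([0, 1]).all():
        raise ValueError("death_unrelated must be 0/1")
    if clin["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in clinical table")
    return clin.set_index("sample_id", drop=False)


def join_check(expr: ExpressionMatrix, clin: pd.DataFrame) -> None:
    """Every expression sample must have a clinical record."""
    missing = set(expr.samples) - set(clin["sample_id"])
    if missing:
        raise ValueError(f"samples without clinical record: {sorted(missing)[:5]}")


def warn_dropped(n: int, what: str) -> None:
    if n:
        warnings.warn(f"dropped {n} {what} during join", stacklevel=3)
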