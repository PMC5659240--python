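"""Readers and writers for count matrices, sample sheets, gene sets and configs.

All on-disk formats are plain text: TSV/CSV count tables (first column gene
ids, header row of sample ids), two-column sample sheets, GMT or two-column
TSV gene sets, YAML configuration and JSON result serialization. Gene
identifiers are opaque strings matched exactly and case-sensitively.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "SampleSheet",
    "LayerGeneSets",
    "CountParseError",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gene_sets",
    "write_gene_sets",
    "read_yaml",
    "write_yaml",
    "write_json",
]


class CountParseError(ValueError):
    """Raised when a count table or sample sheet violates its invariants."""


@dataclass
class CountMatrix:
    """Integer gene-by-sample count matrix.

    ``counts`` is a pandas DataFrame indexed by gene id with one column per
    sample. Counts must be non-negative integers; gene and sample ids must
    be unique.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise CountParseError(f"duplicate gene ids: {dup[:5]}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise CountParseError(f"duplicate sample ids: {dup[:5]}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                bad = df.index[np.any(values != np.floor(values), axis=1)]
                raise CountParseError(
                    f"non-integer counts (first offending gene: {bad[0] if len(bad) else '?'})"
                )
            df = df.astype(np.int64)
            object.__setattr__(self, "counts", df)
        if df.size and (df.to_numpy() < 0).any():
            bad = df.index[(df.to_numpy() < 0).any(axis=1)][0]
            raise CountParseError(f"negative count for gene {bad!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def select_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return CountMatrix(self.counts[list(sample_ids)])

    def select_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)])


@dataclass
class SampleSheet:
    """Assignment of sample ids to sample-type labels (e.g. ``Sepw1-pure``)."""

    types: dict[str, str]

    def samples_of_type(self, sample_type: str) -> list[str]:
        return [s for s, t in self.types.items() if t == sample_type]

    @property
    def sample_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.types.values():
            seen.setdefault(t)
        return list(seen)

    def validate_against(self, matrix: CountMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.types]
        if missing:
            raise CountParseError(f"samples missing from sample sheet: {missing}")


@dataclass
class LayerGeneSets:
    """Named gene lists, e.g. one 400-gene list per cortical layer."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        deduped: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(g)
            if len(seen) < len(genes):
                logger.warning(
                    "gene set %r: collapsed %d duplicate entries", name, len(genes) - len(seen)
                )
            deduped[name] = list(seen)
        self.sets = deduped

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_counts(path: str | Path, sep: str | None = None) -> CountMatrix:
    """Read a gene-by-sample count table (TSV by default, CSV by extension)."""
    path = Path(path)
    sep = _sep_for(path, sep)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})
    except pd.errors.ParserError as exc:  # ragged rows etc. — pandas reports the line
        raise CountParseError(f"{path}: {exc}") from exc
    if df.empty and df.shape[1] == 0:
        raise CountParseError(f"{path}: no sample columns found")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            line = df.index.get_loc(bad[0]) + 2 if len(bad) else "?"
            raise CountParseError(
                f"{path}: non-numeric count in sample {col!r} (line {line})"
            )
    if df.isna().to_numpy().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise CountParseError(f"{path}: missing value for gene {gene!r}")
    try:
        return CountMatrix(df)
    except CountParseError as exc:
        raise CountParseError(f"{path}: {exc}") from exc


def write_counts(matrix: CountMatrix, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    matrix.counts.to_csv(path, sep=_sep_for(path, sep), index_label="gene_id")


def read_sample_sheet(path: str | Path, sep: str | None = None) -> SampleSheet:
    """Read a two-column (sample_id, sample_type) sheet with header."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str)
    if df.shape[1] < 2:
        raise CountParseError(f"{path}: expected columns sample_id, sample_type")
    ids, types = df.iloc[:, 0], df.iloc[:, 1]
    if ids.duplicated().any():
        raise CountParseError(
            f"{path}: duplicate sample id {ids[ids.duplicated()].iloc[0]!r}"
        )
    return SampleSheet(dict(zip(ids, types)))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(sheet.types), "sample_type": list(sheet.types.values())}
    ).to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> LayerGeneSets:
    """Read gene sets from GMT lines or a two-column (set_name, gene_id) TSV.

    GMT format: ``name<TAB>description<TAB>gene1<TAB>gene2...``. A file whose
    lines carry three or more fields is treated as GMT; two-field lines as
    (set_name, gene_id) pairs. Duplicates within a set are collapsed with a
    logged warning.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise CountParseError(f"{path}: empty gene-set file")
    rows = [ln.split("\t") for ln in lines]
    sets: dict[str, list[str]] = {}
    if max(len(r) for r in rows) >= 3:  # GMT
        for r in rows:
            if len(r) < 3:
                raise CountParseError(f"{path}: GMT line with fewer than 3 fields: {r}")
            sets.setdefault(r[0], []).extend(r[2:])
    else:
        start = 1 if rows[0][0].lower() in {"set_name", "set", "layer"} else 0
        for r in rows[start:]:
            if len(r) != 2:
                raise CountParseError(f"{path}: expected 2 columns, got {r}")
            sets.setdefault(r[0], []).append(r[1])
    return LayerGeneSets(sets)


def write_gene_sets(gene_sets: LayerGeneSets, path: str | Path) -> None:
    """Write gene sets as GMT (name, description placeholder, genes...)."""
    with open(path, "w") as fh:
        for name, genes in gene_sets.sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def write_de_table(de, path: str | Path) -> None:
    """Write a differential-enrichment result as TSV.

    Columns mirror the deposited enrichment tables: gene_id, baseMeanA,
    baseMeanB, foldChange, pval, padj, enriched. Comparison metadata is
    stored in ``# key: value`` header lines.
    """
    path = Path(path)
    out = de.table.rename(
        columns={
            "mean_norm_A": "baseMeanA",
            "mean_norm_B": "baseMeanB",
            "fold_enrichment": "foldChange",
        }
    )[["baseMeanA", "baseMeanB", "foldChange", "pval", "padj", "enriched"]]
    with open(path, "w") as fh:
        fh.write(f"# type_a: {de.type_a}\n# type_b: {de.type_b}\n# alpha: {de.alpha}\n")
        fh.write(
            f"# dispersion_trend: {de.dispersion_trend[0]:.10g} {de.dispersion_trend[1]:.10g}\n"
        )
        out.to_csv(fh, sep="\t", index_label="gene_id")


def read_de_table(path: str | Path):
    """Read a TSV written by :func:`write_de_table` back into a DEResult."""
    from .diffexp import DEResult  # local import to avoid a cycle

    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition(":")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.rename(
        columns={
            "baseMeanA": "mean_norm_A",
            "baseMeanB": "mean_norm_B",
            "foldChange": "fold_enrichment",
        }
    )
    trend = tuple(float(x) for x in meta.get("dispersion_trend", "0 0").split())
    return DEResult(
        table=df,
        type_a=meta.get("type_a", "A"),
        type_b=meta.get("type_b", "B"),
        alpha=float(meta.get("alpha", 0.1)),
        size_factors={},
        dispersion_trend=(trend[0], trend[1]),
    )


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain one-gene-per-line list (first column if tab-separated)."""
    genes = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if ln:
            genes.append(ln.split("\t")[0])
    return genes


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise CountParseError(f"{path}: expected a YAML mapping")
    return data


def write_yaml(data: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(data), fh, sort_keys=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="list"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


def write_json(obj, path: str | Path) -> None:
    """Serialize any result dataclass / mapping to pretty-printed JSON."""
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
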