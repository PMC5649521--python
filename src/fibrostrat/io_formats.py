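"""Readers and writers for the pipeline's external artifacts.

Formats: plain TSV and GCT 1.2 for expression matrices, CSV for the
clinical table, GMT for gene sets, TSV for differential-expression
tables and JSON for reports.  Gene identifiers are gene-symbol strings,
case-sensitive, used verbatim as the join key everywhere.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: numeric format preserving doubles exactly through a decimal round trip
_FLOAT_FMT = "%.17g"

CLINICAL_COLUMNS = [
    "sample_id",
    "group",
    "fev1_pct",
    "fvc_pct",
    "dlco_pct",
    "age",
    "sex",
    "smoking",
]
_REQUIRED_CLINICAL = ["sample_id", "group"]
_PERCENT_COLUMNS = ["fev1_pct", "fvc_pct", "dlco_pct"]
VALID_GROUPS = {"control", "disease"}


class FormatError(ValueError):
    """Malformed external file (bad header, dimension mismatch, bad cell)."""


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """Genes x samples continuous expression values.

    Values are raw intensities before preprocessing and log2 intensities
    afterwards.  Sample ids must be unique; duplicate gene ids are
    permitted until :func:`fibrostrat.preprocess.aggregate_duplicate_genes`
    collapses them.
    """

    def __init__(self, data: pd.DataFrame):
        if data.columns.duplicated().any():
            dupes = data.columns[data.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dupes[:5]}")
        df = data.astype(float)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        self._data = df

    # -- construction -------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
    ) -> "ExpressionMatrix":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise FormatError(
                f"value shape {values.shape} does not match "
                f"{len(gene_ids)} genes x {len(sample_ids)} samples"
            )
        return cls(pd.DataFrame(values, index=list(gene_ids), columns=list(sample_ids)))

    # -- accessors ----------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def gene_ids(self) -> list[str]:
        return self._data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    @property
    def has_duplicate_genes(self) -> bool:
        return bool(self._data.index.duplicated().any())

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self._data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self._data.loc[:, list(sample_ids)])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        index = self._data.index
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self._data.loc[list(gene_ids)])

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self._data.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.shape
        return f"<ExpressionMatrix {g} genes x {s} samples>"

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self._data.equals(other._data)


def _parse_numeric_block(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    """Convert a string-valued frame to floats, naming the first bad cell."""
    out = {}
    for col in df.columns:
        try:
            # Python's strtod is correctly rounded; to_numeric's fast
            # path is not, and a 1-ulp loss breaks decimal round trips
            out[col] = df[col].astype(float)
            if out[col].isna().any():
                row = df.index[out[col].isna().to_numpy().nonzero()[0][0]]
                raise FormatError(f"{path}: empty cell at gene {row!r}, sample {col!r}")
            continue
        except (TypeError, ValueError):
            pass
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & ~df[col].isna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-numeric value {df.loc[row, col]!r} "
                f"at gene {row!r}, sample {col!r}"
            )
        if converted.isna().any():
            row = df.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise FormatError(f"{path}: empty cell at gene {row!r}, sample {col!r}")
        out[col] = converted
    return pd.DataFrame(out, index=df.index)


def read_expression_matrix(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV or GCT 1.2.

    Input row order is preserved and duplicate gene ids are permitted at
    this stage.  GCT files must declare dimensions that match the data
    block.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        raw.index = raw.index.astype(str)
        return ExpressionMatrix(_parse_numeric_block(raw, path))
    if format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise FormatError(f"{path}: malformed GCT dimension line")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            body = pd.read_csv(fh, sep="\t", dtype=str)
        if body.shape[0] != n_genes:
            raise FormatError(
                f"{path}: GCT header declares {n_genes} genes but data has {body.shape[0]} rows"
            )
        if body.shape[1] - 2 != n_samples:
            raise FormatError(
                f"{path}: GCT header declares {n_samples} samples but data has "
                f"{body.shape[1] - 2} value columns"
            )
        values = body.iloc[:, 2:]
        values.index = body.iloc[:, 0].astype(str)
        return ExpressionMatrix(_parse_numeric_block(values, path))
    raise ValueError(f"unknown matrix format {format!r}")


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, format: str = "tsv"
) -> None:
    path = Path(path)
    if format == "tsv":
        m.data.to_csv(path, sep="\t", index_label="gene", float_format=_FLOAT_FMT)
        return
    if format == "gct":
        n_genes, n_samples = m.shape
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{n_genes}\t{n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(m.sample_ids) + "\n")
            for gene, row in zip(m.gene_ids, m.values):
                cells = "\t".join(_FLOAT_FMT % v for v in row)
                fh.write(f"{gene}\tna\t{cells}\n")
        return
    raise ValueError(f"unknown matrix format {format!r}")


# ---------------------------------------------------------------------------
# ClinicalTable
# ---------------------------------------------------------------------------


class ClinicalTable:
    """Per-sample diagnosis group and clinical measures.

    Percent-predicted lung-function values (FEV1, FVC, D_LCO) are kept
    as explicit missing (NaN) when absent; they are never imputed and
    must lie in [0, 200] when present.
    """

    def __init__(self, data: pd.DataFrame):
        df = data.copy()
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        df.index.name = "sample_id"
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids in clinical table: {dupes[:5]}")
        missing_cols = [c for c in _REQUIRED_CLINICAL if c != "sample_id" and c not in df.columns]
        if missing_cols:
            raise FormatError(f"clinical table missing required columns: {missing_cols}")
        bad_groups = set(df["group"].unique()) - VALID_GROUPS
        if bad_groups:
            raise FormatError(f"unknown diagnosis groups: {sorted(bad_groups)}")
        for col in _PERCENT_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
            out_of_range = df[col].notna() & ~df[col].between(0, 200)
            if out_of_range.any():
                logger.warning(
                    "%d %s values outside [0, 200] recorded as missing", out_of_range.sum(), col
                )
                df.loc[out_of_range, col] = np.nan
        for col in ("age", "sex", "smoking"):
            if col not in df.columns:
                df[col] = np.nan if col == "age" else "unknown"
        self._data = df

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def sample_ids(self) -> list[str]:
        return self._data.index.tolist()

    @property
    def groups(self) -> pd.Series:
        return self._data["group"]

    def disease_samples(self) -> list[str]:
        return self._data.index[self._data["group"] == "disease"].tolist()

    def control_samples(self) -> list[str]:
        return self._data.index[self._data["group"] == "control"].tolist()

    def measure(self, name: str) -> pd.Series:
        if name not in self._data.columns:
            raise KeyError(name)
        return self._data[name]

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self._data.loc[list(sample_ids)].reset_index())

    def equals(self, other: "ClinicalTable") -> bool:
        return self._data.equals(other._data)

    def __len__(self) -> int:
        return len(self._data)


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read the per-sample clinical CSV.

    Unparseable percent values are recorded as missing with a logged
    warning count; duplicate sample ids and missing required columns are
    errors.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in _REQUIRED_CLINICAL if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    n_bad = 0
    for col in _PERCENT_COLUMNS:
        if col in raw.columns:
            parsed = pd.to_numeric(raw[col], errors="coerce")
            n_bad += int((parsed.isna() & raw[col].notna() & (raw[col].str.strip() != "")).sum())
            raw[col] = parsed
    if n_bad:
        logger.warning("%s: %d unparseable percent values recorded as missing", path, n_bad)
    if "age" in raw.columns:
        raw["age"] = pd.to_numeric(raw["age"], errors="coerce")
    return ClinicalTable(raw)


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    out = table.data.reset_index()
    cols = [c for c in CLINICAL_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# GeneSetCollection / GMT
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, in insertion order."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def add(self, name: str, description: str, genes: Iterable[str]) -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        seen: dict[str, None] = {}
        n_dupes = 0
        for g in genes:
            if g in seen:
                n_dupes += 1
            else:
                seen[g] = None
        if n_dupes:
            logger.warning("gene set %r: %d duplicate genes dropped", name, n_dupes)
        self.sets[name] = (description, list(seen))

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out.update(genes)
        return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            name, description = fields[0], fields[1]
            coll.add(name, description, [g for g in fields[2:] if g])
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (description, genes) in coll.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# DE tables and JSON reports
# ---------------------------------------------------------------------------

DE_COLUMNS = ["gene", "contrast", "lfc", "t", "p", "q", "deg", "direction"]


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in DE_COLUMNS if c not in de.columns]
    if missing:
        raise FormatError(f"DE table missing columns {missing}")
    de[DE_COLUMNS].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_de_table(path: str | Path) -> pd.DataFrame:
    de = pd.read_csv(path, sep="\t", dtype={"gene": str, "contrast": str})
    missing = [c for c in DE_COLUMNS if c not in de.columns]
    if missing:
        raise FormatError(f"{path}: DE table missing columns {missing}")
    de["deg"] = de["deg"].astype(bool)
    return de


def _jsonify(obj):
    if isinstance(obj, Mapping):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonify(obj.to_dict())
    return obj


def write_json_report(report: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonify(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
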