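"""Readers, writers and validated in-memory containers for every external format
the pipeline touches.

All downstream modules consume the typed objects defined here; nothing else in
the package parses a file. Supported formats:

* expression TSV — genes x samples, first column gene symbol, header of sample ids
* GMT — one gene set per line: ``name<TAB>description<TAB>gene<TAB>gene...``
* MAF — tab-separated somatic mutation records with the five mandatory columns
  ``Tumor_Sample_Barcode``, ``Hugo_Symbol``, ``Variant_Classification``,
  ``t_ref_count``, ``t_alt_count`` (extra columns ignored, ``#`` comments skipped)
* copy-number TSV — thresholded integer calls in {-2,...,2}, features x samples,
  at gene or chromosome-arm level (GISTIC "thresholded by genes" layout)
* clinical TSV — one row per sample with survival, grade, IDH status, histology

Every writer emits the TSV plus a small JSON run-metadata sidecar
(``<path>.meta.json``) recording the package version and write parameters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LoadError",
    "ExpressionMatrix",
    "GeneSetCollection",
    "MutationTable",
    "CopyNumberTable",
    "ClinicalTable",
    "read_expression",
    "read_gmt",
    "read_maf",
    "read_copy_number",
    "read_clinical",
]

MAF_REQUIRED_COLUMNS = (
    "Tumor_Sample_Barcode",
    "Hugo_Symbol",
    "Variant_Classification",
    "t_ref_count",
    "t_alt_count",
)

CN_CALL_RANGE = (-2, -1, 0, 1, 2)


class LoadError(ValueError):
    """Raised when an input file violates its format contract."""


def _write_sidecar(path: Path, **metadata) -> None:
    from . import __version__

    meta = {"writer": f"immunotype {__version__}", **metadata}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1) + "\n")


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued expression table, assumed log-scale.

    ``values`` is indexed by gene symbol with sample ids as columns. Duplicate
    gene or sample ids are rejected; missing values must have been resolved
    (dropped and counted) before construction.
    """

    values: pd.DataFrame
    is_log2: bool = True
    n_dropped_rows: int = 0

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise LoadError(f"duplicate gene ids after load: {dupes[:5]}")
        if v.columns.has_duplicates:
            dupes = v.columns[v.columns.duplicated()].unique().tolist()
            raise LoadError(f"duplicate sample ids: {dupes[:5]}")
        if v.isna().any().any():
            raise LoadError("missing values present; load with drop_incomplete=True")
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise LoadError(f"need at least 2 genes and 2 samples, got shape {v.shape}")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def linear_values(self) -> pd.DataFrame:
        """Expression on linear scale (2**x when the matrix is declared log2)."""
        return np.power(2.0, self.values) if self.is_log2 else self.values

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.values.to_csv(path, sep="\t", index_label="gene_id")
        _write_sidecar(path, kind="expression", is_log2=self.is_log2,
                       n_genes=self.shape[0], n_samples=self.shape[1])


def read_expression(path: str | Path, drop_incomplete: bool = True,
                    log2_offset: float | None = None,
                    is_log2: bool = True) -> ExpressionMatrix:
    """Load a genes x samples expression TSV.

    Rows with any missing value are dropped and counted when
    ``drop_incomplete``; duplicate gene rows are collapsed by per-gene mean.
    ``log2_offset`` applies ``log2(x + offset)`` for raw-scale inputs.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment=None)
    except Exception as exc:  # malformed beyond repair
        raise LoadError(f"{path}: cannot parse as TSV ({exc})") from exc
    if raw.shape[1] < 2:
        raise LoadError(f"{path}: header row defines {raw.shape[1]} sample column(s); need >= 2")

    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            gene = raw.index[bad.to_numpy()][0]
            raise LoadError(
                f"{path}: non-numeric cell at gene '{gene}', sample column '{col}'")
        numeric[col] = converted

    n_dropped = 0
    incomplete = numeric.isna().any(axis=1)
    if incomplete.any():
        if not drop_incomplete:
            gene = numeric.index[incomplete.to_numpy()][0]
            raise LoadError(f"{path}: missing value in row for gene '{gene}'")
        n_dropped = int(incomplete.sum())
        numeric = numeric.loc[~incomplete]

    if numeric.index.has_duplicates:
        numeric = numeric.groupby(level=0, sort=False).mean()

    if log2_offset is not None:
        numeric = np.log2(numeric + log2_offset)
        is_log2 = True

    numeric.index = numeric.index.astype(str)
    numeric.index.name = "gene_id"
    return ExpressionMatrix(values=numeric, is_log2=is_log2, n_dropped_rows=n_dropped)


# ---------------------------------------------------------------------------
# Gene sets


@dataclass
class GeneSetCollection:
    """Named gene lists (immune-cell signatures, pathways, marker sets)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    n_duplicates_removed: int = 0

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise LoadError(f"gene set '{name}' is empty")
            if len(set(genes)) != len(genes):
                raise LoadError(f"gene set '{name}' has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        names = list(names)
        missing = [n for n in names if n not in self.sets]
        if missing:
            raise KeyError(f"gene sets not in collection: {missing}")
        return GeneSetCollection(
            sets={n: list(self.sets[n]) for n in names},
            descriptions={n: self.descriptions.get(n, "") for n in names},
        )

    def to_gmt(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for name, genes in self.sets.items():
                desc = self.descriptions.get(name, "na") or "na"
                fh.write("\t".join([name, desc, *genes]) + "\n")
        _write_sidecar(path, kind="gmt", n_sets=len(self.sets))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a line are removed (first occurrence kept) and
    counted; an empty file yields an empty collection.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    n_dupes = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise LoadError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        seen: dict[str, None] = {}
        for g in genes:
            if g in seen:
                n_dupes += 1
            else:
                seen[g] = None
        if name in sets:
            raise LoadError(f"{path}:{lineno}: duplicate set name '{name}'")
        if not seen:
            raise LoadError(f"{path}:{lineno}: gene set '{name}' has no genes")
        sets[name] = list(seen)
        descriptions[name] = desc
    if n_dupes:
        warnings.warn(f"{path}: removed {n_dupes} duplicate gene(s) within sets")
    return GeneSetCollection(sets=sets, descriptions=descriptions,
                             n_duplicates_removed=n_dupes)


# ---------------------------------------------------------------------------
# Mutations (MAF)


@dataclass
class MutationTable:
    """Somatic mutation records from a MAF file.

    ``records`` has columns ``sample_id, gene, variant_class, ref_count,
    alt_count, vaf``; ``vaf`` is NaN where ref+alt == 0 (retained but flagged
    VAF-undefined).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        needed = {"sample_id", "gene", "variant_class", "ref_count", "alt_count"}
        missing = needed - set(self.records.columns)
        if missing:
            raise LoadError(f"MutationTable missing columns: {sorted(missing)}")
        r = self.records
        if (r["ref_count"] < 0).any() or (r["alt_count"] < 0).any():
            raise LoadError("negative read counts in mutation records")
        if "vaf" not in r.columns:
            self.records = r.assign(vaf=_vaf(r))

    @property
    def sample_ids(self) -> list[str]:
        return self.records["sample_id"].unique().tolist()

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.records[self.records["sample_id"] == sample_id]

    def to_maf(self, path: str | Path) -> None:
        path = Path(path)
        out = self.records.rename(columns={
            "sample_id": "Tumor_Sample_Barcode", "gene": "Hugo_Symbol",
            "variant_class": "Variant_Classification",
            "ref_count": "t_ref_count", "alt_count": "t_alt_count",
        })[list(MAF_REQUIRED_COLUMNS)]
        out.to_csv(path, sep="\t", index=False)
        _write_sidecar(path, kind="maf", n_records=len(out))


def _vaf(records: pd.DataFrame) -> pd.Series:
    depth = records["ref_count"] + records["alt_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = records["alt_count"] / depth
    return vaf.where(depth > 0, np.nan)


def read_maf(path: str | Path) -> MutationTable:
    """Read a MAF; requires the five standard columns, skips ``#`` comments.

    Records with ref+alt == 0 are retained with ``vaf`` set to NaN.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(
            f"{path}: missing mandatory MAF column(s) {missing}; "
            f"found columns {df.columns.tolist()}")
    records = pd.DataFrame({
        "sample_id": df["Tumor_Sample_Barcode"].astype(str),
        "gene": df["Hugo_Symbol"].astype(str),
        "variant_class": df["Variant_Classification"].astype(str),
        "ref_count": pd.to_numeric(df["t_ref_count"]).astype(int),
        "alt_count": pd.to_numeric(df["t_alt_count"]).astype(int),
    })
    if (records["sample_id"].str.strip() == "").any() or (records["gene"].str.strip() == "").any():
        raise LoadError(f"{path}: empty sample or gene symbol in MAF body")
    return MutationTable(records=records)


# ---------------------------------------------------------------------------
# Copy number


@dataclass
class CopyNumberTable:
    """Thresholded somatic copy-number calls at gene or arm level.

    ``calls`` is features x samples with integer entries in {-2,-1,0,1,2}
    (GISTIC thresholded convention: +-2 high-level, +-1 low-level, 0 neutral).
    """

    level: str
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if self.level not in ("gene", "arm"):
            raise LoadError(f"copy-number level must be 'gene' or 'arm', got {self.level!r}")
        if self.calls.index.has_duplicates:
            raise LoadError("duplicate feature ids in copy-number table")
        vals = self.calls.to_numpy()
        if not np.isin(vals, CN_CALL_RANGE).all():
            bad = sorted(set(vals.ravel()) - set(CN_CALL_RANGE))
            raise LoadError(f"copy-number calls outside {{-2..2}}: {bad[:5]}")

    @property
    def feature_ids(self) -> list[str]:
        return self.calls.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.calls.columns.tolist()

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.calls.to_csv(path, sep="\t", index_label="feature_id")
        _write_sidecar(path, kind="copy_number", level=self.level)


def read_copy_number(path: str | Path, level: str = "gene") -> CopyNumberTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        calls = df.astype(int)
    except ValueError as exc:
        raise LoadError(f"{path}: non-integer copy-number call ({exc})") from exc
    if not (calls == df).all().all():
        raise LoadError(f"{path}: fractional copy-number call; thresholded calls required")
    calls.index = calls.index.astype(str)
    return CopyNumberTable(level=level, calls=calls)


# ---------------------------------------------------------------------------
# Clinical


CLINICAL_COLUMNS = ("os_time", "os_status", "dfs_time", "dfs_status",
                    "grade", "idh_status", "histology")


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations.

    ``data`` is indexed by sample id with columns ``os_time, os_status,
    dfs_time, dfs_status, grade, idh_status, histology``. Missing fields are
    permitted (NaN) and excluded per-analysis, never imputed. ``time_unit``
    declares the survival-time unit (no conversion is ever applied).
    """

    data: pd.DataFrame
    time_unit: str = "months"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise LoadError("duplicate sample ids in clinical table")
        for endpoint in ("os", "dfs"):
            t, s = f"{endpoint}_time", f"{endpoint}_status"
            if t not in self.data.columns or s not in self.data.columns:
                continue
            status = self.data[s].dropna()
            if not status.isin([0, 1]).all():
                raise LoadError(f"{s} must be 0/1")
            time_missing = self.data.loc[status.index, t].isna()
            if time_missing.any():
                raise LoadError(f"{t} missing for samples with {s} present")
            if (self.data[t].dropna() < 0).any():
                raise LoadError(f"{t} must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    def endpoint(self, which: str = "OS") -> pd.DataFrame:
        """Return (time, status) for an endpoint, dropping incomplete rows."""
        key = which.lower()
        if key not in ("os", "dfs"):
            raise ValueError(f"endpoint must be 'OS' or 'DFS', got {which!r}")
        cols = self.data[[f"{key}_time", f"{key}_status"]].dropna()
        return cols.rename(columns={f"{key}_time": "time", f"{key}_status": "status"})

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, sep="\t", index_label="sample_id")
        _write_sidecar(path, kind="clinical", time_unit=self.time_unit)


def read_clinical(path: str | Path, time_unit: str = "months") -> ClinicalTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ClinicalTable(data=df, time_unit=time_unit)
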