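"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 0-based half-open internally; the SEG dialect on
disk is 1-based inclusive and is converted at the boundary. Matrices are
features x samples. Validation is strict: duplicate identifiers, non-numeric
cells and inconsistent coordinates are hard errors, never silently repaired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_markers", "seg_mean"]

MISSING = float("nan")  # explicit missing-value sentinel for typed tables


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so ``chr13`` and ``13`` share a key."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


# ---------------------------------------------------------------------------
# AnalyteMatrix


@dataclass
class AnalyteMatrix:
    """Features x samples numeric matrix (log2-scale intensities or ratios)."""

    data: pd.DataFrame  # index = feature ids, columns = sample ids

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise ValueError(f"duplicate feature ids: {dups}")
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise ValueError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("matrix body must be numeric")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at feature {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def _validate_numeric_body(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    """Coerce to float, reporting the first offending cell by row/column."""
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & ~df.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at feature "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if coerced.isna().to_numpy().any():
        r, c = np.argwhere(coerced.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at feature {df.index[r]!r}, "
            f"sample {df.columns[c]!r} (ragged row?)"
        )
    return coerced.astype(float)


def read_matrix(path: str | Path, format: str = "tsv") -> AnalyteMatrix:
    """Read a features x samples matrix from TSV or GCT 1.2.

    TSV: header row of sample ids, first column feature ids. GCT: ``#1.2``
    version line, dimension line, then Name/Description columns before the
    sample columns; the Description column is discarded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=object)
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ValueError(f"{path}: expected GCT version line '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise ValueError(f"{path}: malformed GCT dimension line")
            n_rows, n_cols = int(dims[0]), int(dims[1])
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0, dtype=object)
        df = df.drop(columns=df.columns[0])  # Description
        if df.shape != (n_rows, n_cols):
            raise ValueError(
                f"{path}: GCT dimension line says {(n_rows, n_cols)}, body is {df.shape}"
            )
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return AnalyteMatrix(_validate_numeric_body(df, path))


def write_matrix(matrix: AnalyteMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        matrix.data.to_csv(path, sep="\t", index_label="feature_id")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
            out = matrix.data.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ValueError(f"unknown matrix format {format!r}")


# ---------------------------------------------------------------------------
# Gene sets (GMT)


@dataclass
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Repeated members within a set are deduplicated (order kept) with a
    logged warning; duplicate set names are a hard error.
    """
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >=3"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            deduped = tuple(dict.fromkeys(members))
            if len(deduped) < len(members):
                logger.warning(
                    "gene set %s: %d repeated members deduplicated",
                    name, len(members) - len(deduped),
                )
            sets[name] = GeneSet(name, description, deduped)
    if not sets:
        logger.warning("%s: empty gene-set file", path)
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# Segments (SEG)


@dataclass
class SegmentTable:
    """Per-sample copy-number segments, 0-based half-open coordinates."""

    data: pd.DataFrame  # columns SEG_COLUMNS, internal coordinates

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in SEG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"segment table missing columns: {missing}")
        df = df[SEG_COLUMNS].copy()
        df["chrom"] = df["chrom"].map(normalize_chrom)
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        df["n_markers"] = df["n_markers"].astype(int)
        df["seg_mean"] = df["seg_mean"].astype(float)
        if (df["start"] >= df["end"]).any():
            row = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(
                f"segment with start >= end: {row['sample']} {row['chrom']}:"
                f"{row['start']}-{row['end']}"
            )
        if (df["n_markers"] < 1).any():
            raise ValueError("segment with n_markers < 1")
        if not np.isfinite(df["seg_mean"]).all():
            raise ValueError("non-finite seg_mean")
        for (sample, chrom), grp in df.groupby(["sample", "chrom"], sort=False):
            g = grp.sort_values("start")
            overlap = g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]
            if overlap.any():
                i = int(np.argmax(overlap))
                a, b = g.iloc[i], g.iloc[i + 1]
                raise ValueError(
                    f"overlapping segments for sample {sample} chr{chrom}: "
                    f"[{a['start']},{a['end']}) and [{b['start']},{b['end']})"
                )
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.data[self.data["sample"] == sample_id]


def read_segments(path: str | Path) -> SegmentTable:
    """Read a SEG file (1-based inclusive on disk -> half-open internally)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    rename = {c: c.strip().lower() for c in df.columns}
    df = df.rename(columns=rename)
    aliases = {
        "id": "sample", "loc.start": "start", "loc.end": "end",
        "num.mark": "n_markers", "num_mark": "n_markers",
        "seg.mean": "seg_mean", "log2_ratio": "seg_mean",
    }
    df = df.rename(columns=aliases)
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: SEG file missing columns {missing}")
    df = df[SEG_COLUMNS].copy()
    if (df["start"].astype(int) > df["end"].astype(int)).any():
        row = df[df["start"].astype(int) > df["end"].astype(int)].iloc[0]
        raise ValueError(f"{path}: segment with start > end for sample {row['sample']}")
    df["start"] = df["start"].astype(int) - 1  # 1-based inclusive -> 0-based half-open
    df["sample"] = df["sample"].astype(str)
    return SegmentTable(df)


def write_segments(segments: SegmentTable, path: str | Path) -> None:
    """Write a SEG file, converting back to 1-based inclusive coordinates."""
    out = segments.data.copy()
    out["start"] = out["start"] + 1
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Typed tables (clinical / methylation / qPCR)


CLINICAL_REQUIRED = ["sample_id", "arm", "pfs_time", "pfs_event", "os_time", "os_event"]
METHYLATION_REQUIRED = ["chrom", "pos", "reads", "meth_fraction"]
QPCR_REQUIRED = ["target", "ct"]


@dataclass
class ClinicalTable:
    """Per-sample arm, PFS/OS endpoints and 0/1/missing genetic covariates."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dups = sorted(set(df["sample_id"][df["sample_id"].duplicated()]))
            raise ValueError(f"duplicate sample ids in clinical table: {dups}")
        for col in ("pfs_time", "os_time"):
            df[col] = pd.to_numeric(df[col], errors="raise")
            if (df[col].dropna() < 0).any():
                raise ValueError(f"negative {col}")
        for col in ("pfs_event", "os_event"):
            df[col] = pd.to_numeric(df[col], errors="raise")
            vals = df[col].dropna()
            if not vals.isin([0, 1]).all():
                raise ValueError(f"non-binary {col}")
        self.data = df.reset_index(drop=True)

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in CLINICAL_REQUIRED]


def read_typed_table(path: str | Path, schema: str) -> pd.DataFrame | ClinicalTable:
    """Read a TSV with schema validation.

    ``clinical`` returns a :class:`ClinicalTable`; ``methylation`` and
    ``qpcr`` return typed DataFrames. Missing values stay as NaN sentinels
    and are never dropped here.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if schema == "clinical":
        return ClinicalTable(df)
    if schema == "methylation":
        missing = [c for c in METHYLATION_REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: methylation table missing columns {missing}")
        df["chrom"] = df["chrom"].map(normalize_chrom)
        df["pos"] = df["pos"].astype(int)
        df["reads"] = df["reads"].astype(int)
        df["meth_fraction"] = pd.to_numeric(df["meth_fraction"], errors="raise")
        if ((df["meth_fraction"] < 0) | (df["meth_fraction"] > 1)).any():
            raise ValueError(f"{path}: meth_fraction outside [0, 1]")
        return df
    if schema == "qpcr":
        missing = [c for c in QPCR_REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: qPCR table missing columns {missing}")
        try:
            df["ct"] = pd.to_numeric(df["ct"], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric Ct value ({exc})") from exc
        if "molecules" in df.columns:
            df["molecules"] = pd.to_numeric(df["molecules"], errors="raise")
        return df
    raise ValueError(f"unknown table schema {schema!r}")
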