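"""Readers, writers and validation for the tabular formats the pipeline touches.

Formats supported:

* expression matrices as plain TSV (first column = gene id, header = sample
  ids) or GCT v1.2,
* gene-set collections as GMT,
* clinical tables, MAF-lite mutation tables and SEG copy-number segment
  tables as TSV.

All readers validate their input and raise :class:`FormatError` with a line
number where that is cheap to provide.  Expression values are assumed to be
on a log2 scale already; callers may request ``log2(x + 1)`` at read time for
raw counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "GeneSetCollection",
    "ClinicalTable",
    "MutationTable",
    "CNVSegmentTable",
    "VARIANT_CLASSES",
    "NONSYNONYMOUS_CLASSES",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "read_maf_lite",
    "write_maf_lite",
    "read_seg",
    "write_seg",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


#: Declared vocabulary for MAF-lite ``Variant_Classification``.
VARIANT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "Splice_Site",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Nonstop_Mutation",
        "Silent",
        "3'UTR",
        "5'UTR",
        "Intron",
        "RNA",
        "Translation_Start_Site",
    }
)

#: Default nonsynonymous subset used for tumor mutational burden.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "Splice_Site",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Nonstop_Mutation",
    }
)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued abundance with a cohort label per sample.

    ``values`` is a pandas DataFrame indexed by gene id with sample ids as
    columns.  ``cohort_of`` maps every sample id to a cohort (cancer-type)
    label; samples with no known cohort default to ``"ALL"``.
    """

    values: pd.DataFrame
    cohort_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape[0] < 2 or self.values.shape[1] < 1:
            raise FormatError(
                "expression matrix needs at least 2 genes and 1 sample, got "
                f"shape {self.values.shape}"
            )
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "sample")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric values")
        if not np.all(np.isfinite(arr)):
            raise FormatError("expression matrix contains non-finite values")
        # default cohort for unannotated samples
        for s in self.values.columns:
            self.cohort_of.setdefault(str(s), "ALL")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cohorts(self) -> pd.Series:
        """Cohort label per sample, in column order."""
        return pd.Series(
            [self.cohort_of[s] for s in self.sample_ids],
            index=self.sample_ids,
            name="cohort",
        )

    def with_cohorts(self, cohort_of: Mapping[str, str]) -> "ExpressionMatrix":
        """Return a copy annotated with the given sample -> cohort mapping."""
        mapping = {s: cohort_of.get(s, "ALL") for s in self.sample_ids}
        return ExpressionMatrix(self.values.copy(), mapping)


@dataclass
class GeneSetCollection:
    """Named, ordered, duplicate-free gene lists with free-text descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sets:
            raise FormatError("gene-set collection is empty")
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            _check_unique(genes, f"gene in set {name!r}")
            self.descriptions.setdefault(name, "")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ClinicalTable:
    """Per-sample overall-survival time/event, stage and cohort.

    ``table`` columns: sample_id, os_time (days, >= 0), os_event (0/1),
    stage (ordinal category, may be missing), cohort.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "os_time", "os_event")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise FormatError(f"clinical table missing column {col!r}")
        if "stage" not in t.columns:
            t = t.assign(stage=pd.NA)
        if "cohort" not in t.columns:
            t = t.assign(cohort="ALL")
        _check_unique(list(t["sample_id"].astype(str)), "sample")
        times = pd.to_numeric(t["os_time"], errors="coerce")
        if times.isna().any():
            bad = int(t.index[times.isna()][0]) + 1
            raise FormatError(f"clinical row {bad}: unparsable os_time")
        if (times < 0).any():
            bad = int(t.index[times < 0][0]) + 1
            raise FormatError(f"clinical row {bad}: negative os_time")
        events = pd.to_numeric(t["os_event"], errors="coerce")
        if events.isna().any() or not events.isin([0, 1]).all():
            mask = events.isna() | ~events.isin([0, 1])
            bad = int(t.index[mask][0]) + 1
            raise FormatError(f"clinical row {bad}: os_event outside {{0,1}}")
        t = t.assign(os_time=times.astype(float), os_event=events.astype(int))
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table["sample_id"]]


@dataclass
class MutationTable:
    """Long-format somatic variant records (sample, gene, classification)."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "gene_id", "variant_classification")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise FormatError(f"mutation table missing column {col!r}")
        for col in ("sample_id", "gene_id"):
            vals = t[col].astype(str)
            if (vals.str.strip() == "").any():
                bad = int(t.index[vals.str.strip() == ""][0]) + 1
                raise FormatError(f"mutation row {bad}: empty {col}")
        unknown = set(t["variant_classification"]) - set(VARIANT_CLASSES)
        if unknown:
            raise FormatError(
                f"unknown variant classifications: {sorted(unknown)}"
            )
        t = t.assign(
            nonsynonymous=t["variant_classification"].isin(NONSYNONYMOUS_CLASSES)
        )
        self.table = t.reset_index(drop=True)


@dataclass
class CNVSegmentTable:
    """Copy-number segments: sample, chromosome, [start, end), log2 seg mean.

    Segment length is ``end - start``; per sample, segments on one chromosome
    must not overlap.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "chromosome", "start", "end", "seg_mean")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise FormatError(f"segment table missing column {col!r}")
        start = pd.to_numeric(t["start"], errors="coerce")
        end = pd.to_numeric(t["end"], errors="coerce")
        mean = pd.to_numeric(t["seg_mean"], errors="coerce")
        if start.isna().any() or end.isna().any():
            raise FormatError("segment table: unparsable coordinates")
        if mean.isna().any() or not np.isfinite(mean).all():
            raise FormatError("segment table: non-finite seg_mean")
        bad = start >= end
        if bad.any():
            row = int(t.index[bad][0]) + 1
            raise FormatError(f"segment row {row}: start >= end")
        t = t.assign(start=start.astype(int), end=end.astype(int),
                     seg_mean=mean.astype(float))
        for (sample, chrom), grp in t.groupby(["sample_id", "chromosome"]):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                raise FormatError(
                    f"overlapping segments for sample {sample!r} "
                    f"chromosome {chrom!r}"
                )
        self.table = t.reset_index(drop=True)


# ---------------------------------------------------------------------------
# expression matrices


def _parse_matrix_lines(
    lines: list[str], path: Path, first_line: int
) -> pd.DataFrame:
    header = lines[0].rstrip("\n").split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise FormatError(f"{path}: header has no sample columns")
    _check_unique(sample_ids, "sample")
    genes: list[str] = []
    rows: list[list[float]] = []
    ncol = len(sample_ids)
    for offset, line in enumerate(lines[1:], start=first_line + 1):
        fields = line.rstrip("\n").split("\t")
        if len(fields) - 1 != ncol:
            raise FormatError(
                f"{path}:{offset + 1}: expected {ncol} value columns, "
                f"got {len(fields) - 1}"
            )
        genes.append(fields[0])
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{offset + 1}: non-numeric cell ({exc})")
    _check_unique(genes, "gene")
    return pd.DataFrame(rows, index=genes, columns=sample_ids, dtype=float)


def read_expression(
    path: str | Path,
    format: str = "tsv",
    log2: bool = False,
    cohort_of: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV or GCT v1.2.

    Parameters
    ----------
    path : file path.
    format : ``"tsv"`` (gene id column + sample header) or ``"gct"``.
    log2 : apply ``log2(x + 1)`` after reading (for raw counts).
    cohort_of : optional sample -> cohort mapping.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() != ""]
    if format == "tsv":
        df = _parse_matrix_lines(lines, path, 0)
    elif format == "gct":
        if len(lines) < 3 or not lines[0].startswith("#1.2"):
            raise FormatError(f"{path}: not a GCT v1.2 file")
        dims = lines[1].split("\t")
        header = lines[2].split("\t")
        # drop the Description column if present
        body = []
        has_desc = len(header) >= 2 and header[1].lower() == "description"
        for ln in lines[2:]:
            fields = ln.split("\t")
            if has_desc:
                fields = [fields[0]] + fields[2:]
            body.append("\t".join(fields))
        df = _parse_matrix_lines(body, path, 2)
        try:
            ngenes, nsamples = int(dims[0]), int(dims[1])
        except (ValueError, IndexError):
            raise FormatError(f"{path}: malformed GCT dimension line")
        if df.shape != (ngenes, nsamples):
            raise FormatError(
                f"{path}: GCT header declares {(ngenes, nsamples)}, "
                f"matrix is {df.shape}"
            )
    else:
        raise ValueError(f"unknown expression format: {format!r}")
    if log2:
        if (df.to_numpy() < 0).any():
            raise FormatError(f"{path}: negative values; cannot log2(x+1)")
        df = np.log2(df + 1.0)
    return ExpressionMatrix(df, dict(cohort_of or {}))


def write_expression(
    em: ExpressionMatrix, path: str | Path, format: str = "tsv"
) -> None:
    """Write an expression matrix as TSV or GCT v1.2."""
    path = Path(path)
    if format == "tsv":
        em.values.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{em.shape[0]}\t{em.shape[1]}\n")
            fh.write("Name\tDescription\t" + "\t".join(em.sample_ids) + "\n")
            for gene, row in em.values.iterrows():
                vals = "\t".join(repr(float(v)) for v in row)
                fh.write(f"{gene}\tna\t{vals}\n")
    else:
        raise ValueError(f"unknown expression format: {format!r}")


# ---------------------------------------------------------------------------
# gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB gene TAB gene ...``.

    Duplicate genes within a line are dropped (first occurrence kept) with a
    logged warning; duplicate set names are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.strip() == "":
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has < 3 fields")
        name, desc, genes = fields[0], fields[1], fields[2:]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        deduped = list(dict.fromkeys(g for g in genes if g != ""))
        if len(deduped) < len([g for g in genes if g != ""]):
            logger.warning(
                "%s:%d: duplicate genes in set %r de-duplicated",
                path, lineno, name,
            )
        sets[name] = deduped
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in gsc.names():
            desc = gsc.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + gsc[name]) + "\n")


# ---------------------------------------------------------------------------
# clinical / mutation / segment tables


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", dtype=str)


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV with columns sample_id, os_time, os_event
    and optional stage, cohort."""
    df = _read_tsv(path)
    df.columns = [c.strip() for c in df.columns]
    if "sample_id" in df.columns:
        df["sample_id"] = df["sample_id"].str.strip()
    return ClinicalTable(df)


def write_clinical(ct: ClinicalTable, path: str | Path) -> None:
    ct.table.to_csv(path, sep="\t", index=False)


def read_maf_lite(path: str | Path) -> MutationTable:
    """Read a MAF-lite TSV (Tumor_Sample_Barcode, Hugo_Symbol,
    Variant_Classification)."""
    df = _read_tsv(path)
    rename = {
        "Tumor_Sample_Barcode": "sample_id",
        "Hugo_Symbol": "gene_id",
        "Variant_Classification": "variant_classification",
    }
    missing = [c for c in rename if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: MAF-lite missing columns {missing}")
    df = df.rename(columns=rename)[list(rename.values())]
    df["sample_id"] = df["sample_id"].str.strip()
    df["gene_id"] = df["gene_id"].str.strip()
    return MutationTable(df)


def write_maf_lite(mt: MutationTable, path: str | Path) -> None:
    out = mt.table.rename(
        columns={
            "sample_id": "Tumor_Sample_Barcode",
            "gene_id": "Hugo_Symbol",
            "variant_classification": "Variant_Classification",
        }
    )[["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]]
    out.to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path) -> CNVSegmentTable:
    """Read a SEG TSV (Sample, Chromosome, Start, End, Seg.Mean)."""
    df = _read_tsv(path)
    rename = {
        "Sample": "sample_id",
        "Chromosome": "chromosome",
        "Start": "start",
        "End": "end",
        "Seg.Mean": "seg_mean",
    }
    missing = [c for c in rename if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: SEG missing columns {missing}")
    df = df.rename(columns=rename)[list(rename.values())]
    df["sample_id"] = df["sample_id"].str.strip()
    return CNVSegmentTable(df)


def write_seg(seg: CNVSegmentTable, path: str | Path) -> None:
    out = seg.table.rename(
        columns={
            "sample_id": "Sample",
            "chromosome": "Chromosome",
            "start": "Start",
            "end": "End",
            "seg_mean": "Seg.Mean",
        }
    )[["Sample", "Chromosome", "Start", "End", "Seg.Mean"]]
    out.to_csv(path, sep="\t", index=False)


def join_samples(
    reference_ids: Iterable[str], other_ids: Iterable[str], what: str = "table"
) -> list[str]:
    """Exact-match (whitespace-trimmed) sample-id intersection, preserving
    ``reference_ids`` order; logs the number of unmatched samples dropped."""
    ref = [str(s).strip() for s in reference_ids]
    other = {str(s).strip() for s in other_ids}
    kept = [s for s in ref if s in other]
    dropped = len(ref) - len(kept)
    if dropped:
        logger.info("join with %s: dropped %d unmatched samples", what, dropped)
    return kept
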