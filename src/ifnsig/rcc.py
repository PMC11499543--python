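"""Reading and writing nCounter data.

Supports the two raw-count inputs — native RCC files (one lane per file,
bracket-delimited sections with a ``Code_Summary`` CSV block) and plain CSV
count tables — plus the CSV sample sheet carrying subject, date, group,
batch, stimulation and optional therapy annotations, and the CSV score table
the pipeline emits.

Counts are held in a :class:`RawCountMatrix`: a genes x samples integer
DataFrame together with per-gene code classes and a sample -> batch mapping.
One cartridge run is one batch (at most 12 lanes).
"""

from __future__ import annotations

import csv
import datetime as dt
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MAX_LANES_PER_BATCH = 12

#: Accepted CodeClass spellings in RCC exports, mapped to canonical classes.
#: Unknown classes are preserved verbatim but excluded from every computation.
CODE_CLASS_DIALECT = {
    "endogenous": "endogenous",
    "endogenous1": "endogenous",
    "endogenous2": "endogenous",
    "housekeeping": "housekeeping",
    "positive": "positive_control",
    "positive_control": "positive_control",
    "negative": "negative_control",
    "negative_control": "negative_control",
}

GROUP_ALIASES = {
    "patient": "patient",
    "healthy": "healthy_reference",
    "healthy_reference": "healthy_reference",
    "healthy_control": "healthy_reference",
    "control": "healthy_reference",
}

STIMULATION_ALIASES = {
    "": "none",
    "none": "none",
    "unstimulated_cultured": "unstimulated_cultured",
    "cultured": "unstimulated_cultured",
    "ifnb_stimulated": "IFNb_stimulated",
    "ifnb": "IFNb_stimulated",
    "stimulated": "IFNb_stimulated",
}

SCORE_TABLE_COLUMNS = [
    "sample_id", "subject_id", "date", "panel", "geomean_score", "z_score",
    "n_genes_used", "batch", "stimulation", "days_since_last_infusion",
]


class FormatError(ValueError):
    """An input file violates the documented layout."""


# ---------------------------------------------------------------------------
# Count matrix


@dataclass
class RawCountMatrix:
    """Gene x sample nonnegative integer counts with code classes and batches.

    ``counts``    — DataFrame indexed by probe symbol, one column per sample.
    ``gene_info`` — DataFrame aligned to ``counts.index`` with columns
                    ``code_class`` (canonical or verbatim-unknown) and
                    ``accession``.
    ``batch_of``  — sample id -> batch id (cartridge).
    """

    counts: pd.DataFrame
    gene_info: pd.DataFrame
    batch_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = sorted(self.counts.index[self.counts.index.duplicated()].unique())
            raise FormatError(f"duplicated probe symbols: {dupes}")
        if not self.counts.index.equals(self.gene_info.index):
            raise FormatError("counts and gene_info indexes differ")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise FormatError("counts must be integers")
        if (vals < 0).any():
            raise FormatError("counts must be nonnegative")
        for s in self.counts.columns:
            self.batch_of.setdefault(s, "unassigned")
        sizes = pd.Series(self.batch_of).value_counts()
        big = sizes[sizes > MAX_LANES_PER_BATCH]
        if len(big):
            warnings.warn(
                f"batches exceed {MAX_LANES_PER_BATCH} lanes: {dict(big)}",
                stacklevel=2,
            )

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def genes_of_class(self, code_class: str) -> list[str]:
        return list(self.gene_info.index[self.gene_info["code_class"] == code_class])

    def batches(self) -> pd.Series:
        """Per-sample batch ids, aligned to column order."""
        return pd.Series({s: self.batch_of[s] for s in self.samples}, name="batch")


def map_code_class(raw: str) -> str:
    """Canonicalize an RCC CodeClass spelling; unknown spellings pass through."""
    canonical = CODE_CLASS_DIALECT.get(raw.strip().lower())
    if canonical is None:
        warnings.warn(
            f"unknown CodeClass {raw!r}: probes kept but excluded from analysis",
            stacklevel=2,
        )
        return raw.strip()
    return canonical


# ---------------------------------------------------------------------------
# RCC files

_RCC_REQUIRED_SECTIONS = ("Header", "Code_Summary")


def _parse_rcc_sections(text: str, path: Path) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for line in text.splitlines():
        line = line.strip("\r\n")
        stripped = line.strip()
        if stripped.startswith("<") and stripped.endswith(">"):
            tag = stripped[1:-1]
            if tag.startswith("/"):
                current = None
            else:
                current = tag
                sections[current] = []
            continue
        if current is not None and stripped:
            sections[current].append(line)
    for name in _RCC_REQUIRED_SECTIONS:
        if name not in sections:
            raise FormatError(f"{path}: missing <{name}> section")
    return sections


def _kv(lines: list[str]) -> dict[str, str]:
    out = {}
    for line in lines:
        parts = line.split(",", 1)
        if len(parts) == 2:
            out[parts[0].strip()] = parts[1].strip()
    return out


def _parse_code_summary(lines: list[str], path: Path) -> pd.DataFrame:
    rows = list(csv.reader(lines))
    if not rows:
        raise FormatError(f"{path}: empty Code_Summary")
    header = [h.strip() for h in rows[0]]
    try:
        i_class = header.index("CodeClass")
        i_name = header.index("Name")
        i_count = header.index("Count")
    except ValueError as exc:
        raise FormatError(f"{path}: Code_Summary header missing column: {exc}") from exc
    i_acc = header.index("Accession") if "Accession" in header else None
    seen: set[tuple[str, str]] = set()
    recs = []
    for rownum, row in enumerate(rows[1:], start=2):
        if not any(cell.strip() for cell in row):
            continue
        raw_class, name = row[i_class].strip(), row[i_name].strip()
        key = (raw_class, name)
        if key in seen:
            raise FormatError(f"{path}: duplicate (CodeClass, Name) {key} in Code_Summary")
        seen.add(key)
        count_str = row[i_count].strip()
        try:
            count = int(count_str)
        except ValueError:
            raise FormatError(
                f"{path}: Code_Summary row {rownum}: count {count_str!r} is not an integer"
            ) from None
        if count < 0:
            raise FormatError(f"{path}: Code_Summary row {rownum}: negative count {count}")
        acc = row[i_acc].strip() if i_acc is not None and i_acc < len(row) else ""
        recs.append((name, map_code_class(raw_class), acc, count))
    return pd.DataFrame(recs, columns=["gene", "code_class", "accession", "count"])


def read_rcc(
    paths: Iterable[str | Path],
    batch_map: Mapping[str, str] | None = None,
) -> RawCountMatrix:
    """Read a collection of RCC files into one count matrix, one sample each.

    Sample ids come from the Sample_Attributes ``ID`` field (file stem as
    fallback); batch ids from ``batch_map`` (keyed by file name or sample id)
    or else the Lane_Attributes ``CartridgeID``.  Samples are ordered by
    sample id so the result is independent of input file order; genes keep
    their first-appearance order.
    """
    batch_map = dict(batch_map or {})
    per_sample: dict[str, pd.DataFrame] = {}
    batch_of: dict[str, str] = {}
    gene_order: list[str] = []
    gene_meta: dict[str, tuple[str, str]] = {}
    for path in paths:
        path = Path(path)
        sections = _parse_rcc_sections(path.read_text(), path)
        attrs = _kv(sections.get("Sample_Attributes", []))
        lane = _kv(sections.get("Lane_Attributes", []))
        sample_id = attrs.get("ID") or path.stem
        if sample_id in per_sample:
            raise FormatError(f"{path}: duplicate sample id {sample_id!r}")
        summary = _parse_code_summary(sections["Code_Summary"], path)
        if summary["gene"].duplicated().any():
            dupes = sorted(summary.loc[summary["gene"].duplicated(), "gene"])
            raise FormatError(f"{path}: probe symbol appears in two code classes: {dupes}")
        per_sample[sample_id] = summary.set_index("gene")
        batch_of[sample_id] = (
            batch_map.get(path.name)
            or batch_map.get(sample_id)
            or lane.get("CartridgeID")
            or "unassigned"
        )
        for rec in summary.itertuples(index=False):
            if rec.gene not in gene_meta:
                gene_order.append(rec.gene)
                gene_meta[rec.gene] = (rec.code_class, rec.accession)
    if not per_sample:
        raise FormatError("no RCC files given")
    sample_ids = sorted(per_sample)
    counts = pd.DataFrame(
        {s: per_sample[s]["count"].reindex(gene_order) for s in sample_ids},
        index=pd.Index(gene_order, name="gene"),
    )
    if counts.isna().any().any():
        missing = counts.columns[counts.isna().any()].tolist()
        raise FormatError(f"samples missing probes present in other files: {missing}")
    gene_info = pd.DataFrame(
        {
            "code_class": [gene_meta[g][0] for g in gene_order],
            "accession": [gene_meta[g][1] for g in gene_order],
        },
        index=counts.index,
    )
    return RawCountMatrix(counts.astype(np.int64), gene_info, batch_of)


# ---------------------------------------------------------------------------
# CSV count tables


def read_count_table(
    path: str | Path,
    code_class_column: str = "code_class",
    gene_column: str = "gene",
    accession_column: str = "accession",
    batch_of: Mapping[str, str] | None = None,
) -> RawCountMatrix:
    """Read a gene x sample CSV count table.

    Expects one row per probe with a symbol column, a code-class column
    (nCounter dialect spellings accepted), an optional accession column, and
    one column of integer counts per sample.  Batch ids normally come from
    the companion sample sheet; pass ``batch_of`` or use
    :func:`apply_sample_sheet`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    for col in (gene_column, code_class_column):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    meta_cols = {gene_column, code_class_column, accession_column}
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns found")
    counts = {}
    for col in sample_cols:
        try:
            vals = df[col].astype(np.int64)
        except ValueError:
            bad = df.loc[~df[col].str.fullmatch(r"-?\d+"), col].iloc[0]
            raise FormatError(f"{path}: column {col!r}: count {bad!r} is not an integer") from None
        if (vals < 0).any():
            raise FormatError(f"{path}: column {col!r}: negative count")
        counts[col] = vals
    classes = []
    for raw in df[code_class_column]:
        canonical = CODE_CLASS_DIALECT.get(str(raw).strip().lower())
        if canonical is None:
            raise FormatError(
                f"{path}: unknown code class {raw!r}; accepted spellings: "
                f"{sorted(CODE_CLASS_DIALECT)}"
            )
        classes.append(canonical)
    index = pd.Index(df[gene_column], name="gene")
    gene_info = pd.DataFrame(
        {
            "code_class": classes,
            "accession": df[accession_column] if accession_column in df.columns else "",
        },
        index=index,
    )
    matrix = pd.DataFrame(counts)
    matrix.index = index
    return RawCountMatrix(matrix, gene_info, dict(batch_of or {}))


def write_count_table(matrix, path: str | Path, float_values: bool = False) -> None:
    """Write a (raw or normalized) count matrix as a CSV count table."""
    df = matrix.counts if hasattr(matrix, "counts") else matrix.values
    out = pd.concat([matrix.gene_info[["code_class", "accession"]], df], axis=1)
    out.index.name = "gene"
    out.reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Sample sheets


@dataclass(frozen=True)
class TherapyRecord:
    drug: str
    dose: float  # mg/kg/day (oral) or mg/kg per infusion
    start: dt.date
    stop: dt.date | None = None  # open-ended if None

    def __post_init__(self) -> None:
        if self.stop is not None and self.start > self.stop:
            raise FormatError(
                f"therapy {self.drug}: start {self.start} after stop {self.stop}"
            )


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample metadata from the sample sheet."""

    sample_id: str
    subject_id: str
    date: dt.date
    group: str  # patient | healthy_reference
    batch: str
    stimulation: str = "none"  # none | unstimulated_cultured | IFNb_stimulated
    therapy: tuple[TherapyRecord, ...] = ()
    infusion_dates: tuple[dt.date, ...] = ()
    events: tuple[tuple[dt.date, str], ...] = ()
    days_since_last_infusion: int | None = None

    def __post_init__(self) -> None:
        if self.group not in ("patient", "healthy_reference"):
            raise FormatError(f"{self.sample_id}: unknown group {self.group!r}")
        if self.stimulation not in ("none", "unstimulated_cultured", "IFNb_stimulated"):
            raise FormatError(
                f"{self.sample_id}: unknown stimulation {self.stimulation!r}"
            )
        if self.days_since_last_infusion is not None and self.days_since_last_infusion < 0:
            raise FormatError(f"{self.sample_id}: negative days_since_last_infusion")


def _parse_date(text: str, context: str) -> dt.date:
    try:
        return dt.date.fromisoformat(text.strip())
    except ValueError:
        raise FormatError(f"{context}: date {text!r} is not ISO-8601 (YYYY-MM-DD)") from None


def _parse_therapy(cell: str, context: str) -> tuple[TherapyRecord, ...]:
    # "drug|dose|start|stop" records separated by ";"; stop may be empty (ongoing)
    records = []
    for chunk in filter(None, (c.strip() for c in cell.split(";"))):
        parts = chunk.split("|")
        if len(parts) not in (3, 4):
            raise FormatError(
                f"{context}: therapy record {chunk!r} is not drug|dose|start[|stop]"
            )
        drug, dose, start = parts[0], float(parts[1]), _parse_date(parts[2], context)
        stop = None
        if len(parts) == 4 and parts[3].strip():
            stop = _parse_date(parts[3], context)
        records.append(TherapyRecord(drug, dose, start, stop))
    return tuple(records)


def _parse_events(cell: str, context: str) -> tuple[tuple[dt.date, str], ...]:
    events = []
    for chunk in filter(None, (c.strip() for c in cell.split(";"))):
        parts = chunk.split("|", 1)
        if len(parts) != 2:
            raise FormatError(f"{context}: event {chunk!r} is not date|label")
        events.append((_parse_date(parts[0], context), parts[1]))
    return tuple(events)


def read_sample_sheet(path: str | Path) -> list[SampleAnnotation]:
    """Read the CSV sample sheet.

    Required columns: sample_id, subject_id, date, group, batch, stimulation.
    Optional: days_since_last_infusion, therapy (``drug|dose|start|stop``
    records joined by ";"), infusions (";"-joined ISO dates),
    events (``date|label`` joined by ";").
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    required = ["sample_id", "subject_id", "date", "group", "batch", "stimulation"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise FormatError(f"{path}: duplicate sample_id values {dupes}")
    annotations = []
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        ctx = f"{path} row {rownum}"
        group = GROUP_ALIASES.get(row.group.strip().lower())
        if group is None:
            raise FormatError(f"{ctx}: unknown group {row.group!r}")
        stim_raw = getattr(row, "stimulation", "")
        stim = STIMULATION_ALIASES.get(stim_raw.strip().lower())
        if stim is None:
            raise FormatError(f"{ctx}: unknown stimulation {stim_raw!r}")
        days = getattr(row, "days_since_last_infusion", "")
        annotations.append(
            SampleAnnotation(
                sample_id=row.sample_id.strip(),
                subject_id=row.subject_id.strip(),
                date=_parse_date(row.date, ctx),
                group=group,
                batch=row.batch.strip() or "unassigned",
                stimulation=stim,
                therapy=_parse_therapy(getattr(row, "therapy", ""), ctx),
                infusion_dates=tuple(
                    _parse_date(d, ctx)
                    for d in filter(None, (c.strip() for c in getattr(row, "infusions", "").split(";")))
                ),
                events=_parse_events(getattr(row, "events", ""), ctx),
                days_since_last_infusion=int(days) if str(days).strip() else None,
            )
        )
    return annotations


def write_sample_sheet(annotations: Sequence[SampleAnnotation], path: str | Path) -> None:
    rows = []
    for a in annotations:
        rows.append({
            "sample_id": a.sample_id,
            "subject_id": a.subject_id,
            "date": a.date.isoformat(),
            "group": a.group,
            "batch": a.batch,
            "stimulation": a.stimulation,
            "days_since_last_infusion": (
                "" if a.days_since_last_infusion is None else a.days_since_last_infusion
            ),
            "therapy": ";".join(
                f"{t.drug}|{t.dose}|{t.start.isoformat()}|"
                f"{'' if t.stop is None else t.stop.isoformat()}"
                for t in a.therapy
            ),
            "infusions": ";".join(d.isoformat() for d in a.infusion_dates),
            "events": ";".join(f"{d.isoformat()}|{label}" for d, label in a.events),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def annotations_by_id(annotations: Sequence[SampleAnnotation]) -> dict[str, SampleAnnotation]:
    return {a.sample_id: a for a in annotations}


def apply_sample_sheet(matrix: RawCountMatrix, annotations: Sequence[SampleAnnotation]) -> RawCountMatrix:
    """Return a copy of the matrix with batch ids taken from the sample sheet."""
    by_id = annotations_by_id(annotations)
    batch_of = dict(matrix.batch_of)
    for s in matrix.samples:
        if s in by_id:
            batch_of[s] = by_id[s].batch
    return RawCountMatrix(matrix.counts, matrix.gene_info, batch_of)


# ---------------------------------------------------------------------------
# Score tables


def write_score_table(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a score table CSV with the documented stable column order."""
    out = scores.copy()
    for col in SCORE_TABLE_COLUMNS:
        if col not in out.columns:
            out[col] = ""
    out[SCORE_TABLE_COLUMNS].to_csv(path, index=False)


def read_score_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SCORE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: score table missing columns {missing}")
    return df
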