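"""Reading, validation and filtering of CNV cohorts and gene annotations.

Coordinate conventions
----------------------
All in-memory intervals are **0-based half-open** ``[start, stop)`` so that
``length == stop - start``.  CNV TSV input is declared 1-based inclusive
(the convention of most CNV call tables) and is shifted on read; BED input
is already half-open and taken as-is; gene TSV input is 1-based inclusive.

A cohort is a set of CNV calls plus a per-sample table (label and optional
sex).  Samples whose CNVs are all filtered away stay in the sample table:
they still contribute to the denominators of the burden statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

logger = logging.getLogger(__name__)

VALID_CHROMS = {str(c) for c in range(1, 23)} | {"X", "Y"}

CNV_COLUMNS = ["sample_id", "chrom", "start", "stop", "dosage", "label", "sex"]
REQUIRED_CNV_COLUMNS = ["sample_id", "chrom", "start", "stop", "dosage", "label"]


class Dosage(str, Enum):
    """CNV type: loss (del) or gain (dup)."""

    DEL = "del"
    DUP = "dup"


class Label(str, Enum):
    CASE = "case"
    CONTROL = "control"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


def normalize_chrom(token: str) -> str:
    """Strip a ``chr`` prefix and uppercase X/Y."""
    t = str(token).strip()
    if t.lower().startswith("chr"):
        t = t[3:]
    if t.lower() in ("x", "y"):
        t = t.upper()
    return t


@dataclass(frozen=True, slots=True)
class CNVRecord:
    """One copy-number variant call for one individual.

    ``start``/``stop`` are 0-based half-open; ``length`` is ``stop - start``.
    """

    sample_id: str
    chrom: str
    start: int
    stop: int
    dosage: str  # "del" | "dup"
    label: str  # "case" | "control"
    sex: Optional[str] = None  # "male" | "female" | None

    @property
    def length(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """An annotated gene interval (0-based half-open) with a biotype."""

    gene_id: str
    name: str
    chrom: str
    start: int
    stop: int
    biotype: str = "coding"  # "coding" | "lncRNA"

    @property
    def length(self) -> int:
        return self.stop - self.start


@dataclass
class Cohort:
    """CNV records plus the per-sample table for one case/control study."""

    records: list[CNVRecord]
    samples: dict[str, tuple[str, Optional[str]]]  # sample_id -> (label, sex)
    disease_tag: str = ""
    n_dropped_rows: int = 0

    def __post_init__(self) -> None:
        missing = {r.sample_id for r in self.records} - set(self.samples)
        if missing:
            raise ValueError(f"records reference unknown samples: {sorted(missing)[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_ids(self, label: Optional[str] = None) -> list[str]:
        if label is None:
            return sorted(self.samples)
        return sorted(s for s, (lab, _) in self.samples.items() if lab == label)

    @property
    def n_cases(self) -> int:
        return sum(1 for lab, _ in self.samples.values() if lab == "case")

    @property
    def n_controls(self) -> int:
        return sum(1 for lab, _ in self.samples.values() if lab == "control")


@dataclass(frozen=True)
class CohortSummary:
    """Dataset-level counts and case/control ratios.

    Ratios carry full precision in ``*_ratio`` and a 2-decimal
    *truncated* rendering in ``*_ratio_str`` (matching the usual printed
    style of published cohort tables).  A ratio with a zero denominator is
    ``nan`` / ``"NA"``.
    """

    n_case_cnvs: int
    n_control_cnvs: int
    sum_cnvs: int
    case_control_cnv_ratio: float
    n_patients: int
    n_healthy: int
    sum_individuals: int
    patient_healthy_ratio: float

    @staticmethod
    def _trunc2(x: float) -> str:
        if not math.isfinite(x):
            return "NA"
        return f"{math.floor(x * 100) / 100:.2f}"

    @property
    def case_control_cnv_ratio_str(self) -> str:
        return self._trunc2(self.case_control_cnv_ratio)

    @property
    def patient_healthy_ratio_str(self) -> str:
        return self._trunc2(self.patient_healthy_ratio)


def _parse_cnv_row(
    row: Mapping[str, object], one_based: bool
) -> tuple[Optional[CNVRecord], Optional[str]]:
    """Return (record, None) or (None, reason)."""
    vals = {}
    for col in REQUIRED_CNV_COLUMNS:
        v = row.get(col)
        if v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == "":
            return None, f"missing {col}"
        vals[col] = v
    try:
        start = int(vals["start"])
        stop = int(vals["stop"])
    except (TypeError, ValueError):
        return None, "non-integer coordinates"
    if one_based:
        start -= 1
    if not start < stop:
        return None, "stop <= start"
    chrom = normalize_chrom(str(vals["chrom"]))
    if chrom not in VALID_CHROMS:
        return None, f"unknown chromosome {vals['chrom']!r}"
    dosage = str(vals["dosage"]).strip().lower()
    if dosage not in ("del", "dup"):
        return None, f"unknown dosage token {vals['dosage']!r}"
    label = str(vals["label"]).strip().lower()
    if label not in ("case", "control"):
        return None, f"unknown label token {vals['label']!r}"
    sex_raw = row.get("sex")
    sex: Optional[str] = None
    if sex_raw is not None and not (isinstance(sex_raw, float) and math.isnan(sex_raw)):
        s = str(sex_raw).strip().lower()
        if s in ("male", "m"):
            sex = "male"
        elif s in ("female", "f"):
            sex = "female"
        elif s in ("", "na", "nan", "none", "."):
            sex = None
        else:
            return None, f"unknown sex token {sex_raw!r}"
    return (
        CNVRecord(
            sample_id=str(vals["sample_id"]),
            chrom=chrom,
            start=start,
            stop=stop,
            dosage=dosage,
            label=label,
            sex=sex,
        ),
        None,
    )


def build_cohort(
    records: Iterable[CNVRecord], disease_tag: str = "", n_dropped_rows: int = 0
) -> Cohort:
    """Assemble a Cohort, rejecting records whose sample carries conflicting labels."""
    recs = list(records)
    samples: dict[str, tuple[str, Optional[str]]] = {}
    kept: list[CNVRecord] = []
    dropped = n_dropped_rows
    for r in recs:
        if r.sample_id in samples:
            lab, sex = samples[r.sample_id]
            if lab != r.label:
                logger.warning("sample %s has conflicting labels; row dropped", r.sample_id)
                dropped += 1
                continue
            if sex is None and r.sex is not None:
                samples[r.sample_id] = (lab, r.sex)
        else:
            samples[r.sample_id] = (r.label, r.sex)
        kept.append(r)
    return Cohort(records=kept, samples=samples, disease_tag=disease_tag, n_dropped_rows=dropped)


def read_cnv_table(
    path: str | Path,
    dialect: Optional[Mapping[str, str]] = None,
    disease_tag: str = "",
    one_based: bool = True,
) -> Cohort:
    """Read a CNV TSV into a Cohort.

    Parameters
    ----------
    path
        Tab-separated file with a header; required columns ``sample_id,
        chrom, start, stop, dosage, label`` plus optional ``sex``.
    dialect
        Optional map from the file's column names to the canonical ones,
        e.g. ``{"pid": "sample_id"}``.
    one_based
        Input coordinates are 1-based inclusive (default) and are shifted
        to the internal 0-based half-open convention on read.

    Rows with a missing required field, a malformed interval, or an unknown
    dosage/label token are dropped, counted and logged.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise OSError(f"cannot read CNV table {path}: {exc}") from exc
    if dialect:
        df = df.rename(columns=dict(dialect))
    missing_cols = [c for c in REQUIRED_CNV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    records: list[CNVRecord] = []
    n_dropped = 0
    for row in df.to_dict("records"):
        rec, reason = _parse_cnv_row(row, one_based=one_based)
        if rec is None:
            n_dropped += 1
            logger.info("dropped row (%s): %s", reason, row)
        else:
            records.append(rec)
    cohort = build_cohort(records, disease_tag=disease_tag, n_dropped_rows=n_dropped)
    logger.info(
        "%s: %d records, %d samples, %d rows dropped",
        path.name,
        len(cohort.records),
        cohort.n_samples,
        cohort.n_dropped_rows,
    )
    return cohort


def write_cnv_table(cohort: Cohort, path: str | Path, one_based: bool = True) -> None:
    """Write a cohort back to the CNV TSV dialect read by :func:`read_cnv_table`.

    Samples with no remaining CNVs cannot be represented in a pure record
    table; they are emitted with a sentinel row only if absent (not done —
    round-trips assume every sample has at least one record).
    """
    rows = []
    for r in cohort.records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "chrom": r.chrom,
                "start": r.start + 1 if one_based else r.start,
                "stop": r.stop,
                "dosage": r.dosage,
                "label": r.label,
                "sex": r.sex if r.sex is not None else "NA",
            }
        )
    pd.DataFrame(rows, columns=CNV_COLUMNS).to_csv(path, sep="\t", index=False)


def filter_cnvs(
    cohort: Cohort, min_len_bp: int = 1000, drop_chrY: bool = True
) -> Cohort:
    """Apply the standard CNV quality filters.

    Removes calls strictly shorter than ``min_len_bp`` (default: anything
    below one kilobase) and, when ``drop_chrY``, all chrY calls (too few
    for meaningful burden comparison).  The sample table is preserved even
    for samples left with zero CNVs, so burden denominators are unchanged.
    """
    kept = [
        r
        for r in cohort.records
        if r.length >= min_len_bp and not (drop_chrY and r.chrom == "Y")
    ]
    n_removed = len(cohort.records) - len(kept)
    if n_removed:
        logger.info(
            "filter_cnvs: removed %d of %d records (min_len=%d, drop_chrY=%s)",
            n_removed,
            len(cohort.records),
            min_len_bp,
            drop_chrY,
        )
    return Cohort(
        records=kept,
        samples=dict(cohort.samples),
        disease_tag=cohort.disease_tag,
        n_dropped_rows=cohort.n_dropped_rows,
    )


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Count CNVs and individuals by cohort arm and form case/control ratios."""
    n_case_cnvs = sum(1 for r in cohort.records if r.label == "case")
    n_control_cnvs = len(cohort.records) - n_case_cnvs
    n_patients = cohort.n_cases
    n_healthy = cohort.n_controls
    cnv_ratio = n_case_cnvs / n_control_cnvs if n_control_cnvs else float("nan")
    ind_ratio = n_patients / n_healthy if n_healthy else float("nan")
    return CohortSummary(
        n_case_cnvs=n_case_cnvs,
        n_control_cnvs=n_control_cnvs,
        sum_cnvs=n_case_cnvs + n_control_cnvs,
        case_control_cnv_ratio=cnv_ratio,
        n_patients=n_patients,
        n_healthy=n_healthy,
        sum_individuals=n_patients + n_healthy,
        patient_healthy_ratio=ind_ratio,
    )


def read_gene_annotation(path: str | Path, format: str = "bed") -> list[GeneRecord]:
    """Read a gene annotation into GeneRecords.

    ``format="bed"``: BED4+ columns ``chrom chromStart chromEnd name
    [gene_id biotype]``, 0-based half-open (kept as-is).
    ``format="tsv"``: header columns ``gene_id name chrom start stop
    biotype``, 1-based inclusive (shifted on read).

    Duplicate gene_ids are a fatal error; malformed intervals are dropped
    and logged.
    """
    path = Path(path)
    genes: list[GeneRecord] = []
    if format == "bed":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        for row in df.itertuples(index=False):
            fields = list(row)
            chrom = normalize_chrom(fields[0])
            try:
                start, stop = int(fields[1]), int(fields[2])
            except (TypeError, ValueError):
                logger.warning("malformed BED interval dropped: %s", fields)
                continue
            name = str(fields[3]) if len(fields) > 3 else f"{chrom}:{start}-{stop}"
            gene_id = str(fields[4]) if len(fields) > 4 and pd.notna(fields[4]) else name
            biotype = str(fields[5]) if len(fields) > 5 and pd.notna(fields[5]) else "coding"
            if not start < stop or chrom not in VALID_CHROMS:
                logger.warning("malformed BED interval dropped: %s", fields)
                continue
            genes.append(GeneRecord(gene_id, name, chrom, start, stop, biotype))
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        required = ["gene_id", "name", "chrom", "start", "stop"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing gene columns {missing}")
        for row in df.to_dict("records"):
            chrom = normalize_chrom(str(row["chrom"]))
            try:
                start, stop = int(row["start"]) - 1, int(row["stop"])
            except (TypeError, ValueError):
                logger.warning("malformed gene row dropped: %s", row)
                continue
            if not start < stop or chrom not in VALID_CHROMS:
                logger.warning("malformed gene row dropped: %s", row)
                continue
            genes.append(
                GeneRecord(
                    gene_id=str(row["gene_id"]),
                    name=str(row["name"]),
                    chrom=chrom,
                    start=start,
                    stop=stop,
                    biotype=str(row.get("biotype") or "coding"),
                )
            )
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    ids = [g.gene_id for g in genes]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate gene_ids {dupes[:5]}")
    return genes


def write_gene_annotation(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write genes as BED6-style TSV (0-based half-open)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.stop}\t{g.name}\t{g.gene_id}\t{g.biotype}\n")


def read_gene_set(path: str | Path) -> set[str]:
    """Read a one-gene-per-line text file; ``#`` comments and blanks ignored."""
    members: set[str] = set()
    with open(path) as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token:
                members.add(token)
    return members
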