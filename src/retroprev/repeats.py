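"""Repeat-annotation parsing and classification of potentially active L1/SINE copies.

A "potentially active" element is a recent, intact insertion: an L1 within
±10% of the 6.1 kb family consensus length, or a SINE of 100-400 bp, in either
case with at most 5% sequence divergence from the consensus. Counts of such
elements per genome serve as proxies for ongoing retrotranspositional activity.

Two input dialects are supported:

``rmsk_out``
    The classic RepeatMasker ``.out`` layout: three header lines, then
    whitespace-aligned columns (SW score, %div, %del, %ins, query, begin, end,
    left, strand, repeat name, class/family, ...). Coordinates are 1-based
    inclusive and are normalised to 0-based half-open here.

``bed``
    A BED6+ dialect (as produced by converting ``.out`` files): chrom, start,
    end, name = repeat class/family string, score = percent divergence, strand.
    Coordinates are already 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "RepeatRecord",
    "ActivityCounts",
    "RepeatParseError",
    "classify_superfamily",
    "parse_repeat_annotation",
    "is_active_l1",
    "is_active_sine",
    "count_active",
    "write_repeat_bed",
    "activity_counts_to_frame",
]

L1_CONSENSUS_LENGTH = 6100
L1_LENGTH_TOLERANCE = 0.10
SINE_MIN_LENGTH = 100
SINE_MAX_LENGTH = 400
MAX_DIVERGENCE = 5.0


class RepeatParseError(ValueError):
    pass


@dataclass(frozen=True)
class RepeatRecord:
    """A single annotated repeat interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    superfamily: str  # "L1", "SINE", or "other"
    divergence: float  # percent substitutions from consensus

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise RepeatParseError(
                f"{self.chrom}:{self.start}-{self.end}: end must exceed start"
            )
        if self.divergence < 0:
            raise RepeatParseError(f"negative divergence {self.divergence}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ActivityCounts:
    """Per-species counts of potentially active elements."""

    species_id: str
    n_active_l1: int
    n_active_sine: int

    @property
    def n_combined(self) -> int:
        return self.n_active_l1 + self.n_active_sine


def classify_superfamily(class_family: str) -> str:
    """Map a RepeatMasker class/family string to L1 / SINE / other."""
    if class_family.startswith("LINE/L1"):
        return "L1"
    if class_family.startswith("SINE"):
        return "SINE"
    return "other"


def _parse_bed_row(fields: list[str], lineno: int) -> RepeatRecord:
    if len(fields) < 6:
        raise RepeatParseError(f"line {lineno}: BED repeat row needs >= 6 fields")
    chrom, start, end, name, score, strand = fields[:6]
    return RepeatRecord(
        chrom=chrom,
        start=int(start),
        end=int(end),
        strand="-" if strand in ("-", "C") else "+",
        superfamily=classify_superfamily(name),
        divergence=float(score),
    )


def _parse_out_row(fields: list[str], lineno: int) -> RepeatRecord:
    if len(fields) < 11:
        raise RepeatParseError(f"line {lineno}: .out row needs >= 11 fields")
    # SW score, %div, %del, %ins, query, begin, end, (left), strand, name, class/family
    divergence = float(fields[1])
    chrom = fields[4]
    begin_1based = int(fields[5])
    end_inclusive = int(fields[6])
    strand = fields[8]
    class_family = fields[10]
    return RepeatRecord(
        chrom=chrom,
        start=begin_1based - 1,
        end=end_inclusive,
        strand="-" if strand in ("-", "C") else "+",
        superfamily=classify_superfamily(class_family),
        divergence=divergence,
    )


def parse_repeat_annotation(path: str | Path, dialect: str = "bed") -> list[RepeatRecord]:
    """Parse a repeat annotation file into :class:`RepeatRecord` objects.

    Malformed rows raise :class:`RepeatParseError` with the 1-based line number.
    """
    if dialect not in ("bed", "rmsk_out"):
        raise RepeatParseError(f"unknown repeat-annotation dialect {dialect!r}")
    records: list[RepeatRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if dialect == "rmsk_out" and (
                stripped.startswith("SW") or stripped.startswith("score")
            ):
                continue  # header lines of the .out layout
            if dialect == "bed" and stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split()
            try:
                if dialect == "bed":
                    records.append(_parse_bed_row(fields, lineno))
                else:
                    records.append(_parse_out_row(fields, lineno))
            except RepeatParseError:
                raise
            except (ValueError, IndexError) as exc:
                raise RepeatParseError(f"line {lineno}: malformed row ({exc})") from exc
    return records


def is_active_l1(
    rec: RepeatRecord,
    consensus_length: int = L1_CONSENSUS_LENGTH,
    length_tolerance: float = L1_LENGTH_TOLERANCE,
    max_divergence: float = MAX_DIVERGENCE,
) -> bool:
    """Full-length, recently inserted L1: length within ±10% of the 6.1 kb
    consensus (bounds inclusive) and divergence <= 5%."""
    if rec.superfamily != "L1":
        raise ValueError(f"is_active_l1 called on {rec.superfamily} record")
    lo = (1.0 - length_tolerance) * consensus_length
    hi = (1.0 + length_tolerance) * consensus_length
    return lo <= rec.length <= hi and rec.divergence <= max_divergence


def is_active_sine(
    rec: RepeatRecord,
    min_len: int = SINE_MIN_LENGTH,
    max_len: int = SINE_MAX_LENGTH,
    max_divergence: float = MAX_DIVERGENCE,
) -> bool:
    """Recently inserted SINE: 100-400 bp (inclusive) with divergence <= 5%."""
    if rec.superfamily != "SINE":
        raise ValueError(f"is_active_sine called on {rec.superfamily} record")
    return min_len <= rec.length <= max_len and rec.divergence <= max_divergence


def count_active(
    records: Iterable[RepeatRecord],
    species_id: str,
    **thresholds,
) -> ActivityCounts:
    """Count potentially active L1s and SINEs; combined = L1 + SINE.

    Species with zero full-length L1s still receive their SINE count in the
    combined tally, so recent activity mobilised by unannotated or fragmented
    L1 machinery is not discarded.
    """
    l1_kwargs = {
        k: thresholds[k]
        for k in ("consensus_length", "length_tolerance", "max_divergence")
        if k in thresholds
    }
    sine_kwargs = {
        k: thresholds[k] for k in ("min_len", "max_len", "max_divergence") if k in thresholds
    }
    n_l1 = 0
    n_sine = 0
    for rec in records:
        if rec.superfamily == "L1" and is_active_l1(rec, **l1_kwargs):
            n_l1 += 1
        elif rec.superfamily == "SINE" and is_active_sine(rec, **sine_kwargs):
            n_sine += 1
    return ActivityCounts(species_id=species_id, n_active_l1=n_l1, n_active_sine=n_sine)


def write_repeat_bed(records: Iterable[RepeatRecord], path: str | Path) -> None:
    """Write records in the package's BED6 repeat dialect."""
    class_map = {"L1": "LINE/L1", "SINE": "SINE/generic", "other": "Unknown"}
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{class_map[r.superfamily]}\t"
                f"{r.divergence:.2f}\t{r.strand}\n"
            )


def activity_counts_to_frame(counts: Iterable[ActivityCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_id": c.species_id,
                "n_active_l1": c.n_active_l1,
                "n_active_sine": c.n_active_sine,
                "n_combined": c.n_combined,
            }
            for c in counts
        ]
    )
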