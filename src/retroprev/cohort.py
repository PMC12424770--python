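"""Per-species necropsy cohort: loading, validation, filtering, and sampling weights.

Cancer prevalence in comparative oncology datasets is estimated from necropsy
records: neoplasia prevalence is the fraction of necropsies reporting any tumor
(benign or malignant), malignancy prevalence the fraction reporting a malignant
tumor. Small necropsy counts make these estimates unreliable, so species below a
minimum record count are excluded, as are species with zero recorded neoplasia
or malignancy (cancer occurs in essentially all mammals; such zeros reflect
undersampling, not biology). Retained species are down-weighted in regression by
the inverse square root of their necropsy total.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "CohortValidationError",
    "SpeciesCohortRecord",
    "compute_prevalence",
    "sampling_weight",
    "filter_cohort",
    "load_cohort_table",
    "write_cohort_table",
    "write_exclusion_log",
    "cohort_to_frame",
]

REASON_INSUFFICIENT = "insufficient necropsies"
REASON_ZERO_NEOPLASIA = "zero neoplasia"
REASON_ZERO_MALIGNANCY = "zero malignancy"


class CohortValidationError(ValueError):
    """Raised when a cohort record violates count nesting or prevalence bounds."""


@dataclass
class SpeciesCohortRecord:
    """One species' necropsy tallies, prevalences, longevity, and sampling weight.

    Counts must nest: 0 <= n_malignant <= n_neoplasia <= n_necropsies.
    Prevalences are stored as fractions in [0, 1]; percent display is formatting
    only.  ``longevity`` is maximum longevity in months and may be missing.
    """

    species_id: str
    n_necropsies: int
    n_neoplasia: int
    n_malignant: int
    longevity: Optional[float] = None
    neoplasia_prevalence: float = field(init=False)
    malignancy_prevalence: float = field(init=False)
    weight: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("n_necropsies", "n_neoplasia", "n_malignant"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise CohortValidationError(
                    f"{self.species_id}: {name} must be an integer, got {v!r}"
                )
            if v < 0:
                raise CohortValidationError(f"{self.species_id}: {name} is negative ({v})")
        if not (self.n_malignant <= self.n_neoplasia <= self.n_necropsies):
            raise CohortValidationError(
                f"{self.species_id}: counts must nest "
                f"(malignant {self.n_malignant} <= neoplasia {self.n_neoplasia} "
                f"<= necropsies {self.n_necropsies})"
            )
        if self.longevity is not None and not (self.longevity > 0):
            raise CohortValidationError(
                f"{self.species_id}: longevity must be positive months, got {self.longevity}"
            )
        self.neoplasia_prevalence = compute_prevalence(
            self.n_neoplasia, self.n_necropsies, species=self.species_id
        )
        self.malignancy_prevalence = compute_prevalence(
            self.n_malignant, self.n_necropsies, species=self.species_id
        )
        self.weight = sampling_weight(self.n_necropsies) if self.n_necropsies >= 1 else math.nan


def compute_prevalence(n_tumor: int, n_total: int, species: str = "<unknown>") -> float:
    """Prevalence as tumor count / total necropsies, on the fraction scale.

    Raises :class:`CohortValidationError` (naming the species) for a zero
    denominator or a tumor count exceeding the total.
    """
    if n_total <= 0:
        raise CohortValidationError(f"{species}: no necropsy records (n_total={n_total})")
    if not (0 <= n_tumor <= n_total):
        raise CohortValidationError(
            f"{species}: tumor count {n_tumor} outside [0, {n_total}]"
        )
    return n_tumor / n_total


def sampling_weight(n_necropsies: int) -> float:
    """Regression weight 1/sqrt(n) for a species with ``n_necropsies`` records."""
    if n_necropsies < 1:
        raise CohortValidationError(f"sampling weight needs n >= 1, got {n_necropsies}")
    return 1.0 / math.sqrt(n_necropsies)


def filter_cohort(
    records: Iterable[SpeciesCohortRecord],
    min_records: int = 20,
    require_malignant: bool = True,
) -> tuple[list[SpeciesCohortRecord], list[dict]]:
    """Apply the cohort inclusion rules and return (retained, exclusion log).

    A species is retained iff it has at least ``min_records`` necropsies, at
    least one neoplasia, and (when ``require_malignant``) at least one
    malignancy.  Each excluded species is logged with *all* applicable reasons,
    insufficient-n first, so the log is deterministic.

    ``require_malignant=False`` relaxes the both-zero exclusion to neoplasia
    only, for fitting neoplasia-response models to species that have tumors but
    no recorded malignancy.
    """
    retained: list[SpeciesCohortRecord] = []
    log: list[dict] = []
    for rec in records:
        reasons = []
        if rec.n_necropsies < min_records:
            reasons.append(REASON_INSUFFICIENT)
        if rec.n_neoplasia == 0:
            reasons.append(REASON_ZERO_NEOPLASIA)
        if require_malignant and rec.n_malignant == 0:
            reasons.append(REASON_ZERO_MALIGNANCY)
        if reasons:
            log.append(
                {
                    "species_id": rec.species_id,
                    "n_necropsies": rec.n_necropsies,
                    "reasons": reasons,
                }
            )
        else:
            retained.append(rec)
    if not retained:
        raise CohortValidationError("no species survive cohort filtering")
    return retained, log


def load_cohort_table(path: str | Path) -> list[SpeciesCohortRecord]:
    """Read the UTF-8 tab-delimited cohort table.

    Expected header columns: species_id, n_necropsies, n_neoplasia,
    n_malignant, longevity_months (empty cell = missing longevity).
    """
    df = pd.read_csv(path, sep="\t", dtype={"species_id": str})
    required = {"species_id", "n_necropsies", "n_neoplasia", "n_malignant"}
    missing = required - set(df.columns)
    if missing:
        raise CohortValidationError(f"cohort table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        longevity = getattr(row, "longevity_months", None)
        if longevity is not None and pd.isna(longevity):
            longevity = None
        records.append(
            SpeciesCohortRecord(
                species_id=row.species_id,
                n_necropsies=int(row.n_necropsies),
                n_neoplasia=int(row.n_neoplasia),
                n_malignant=int(row.n_malignant),
                longevity=float(longevity) if longevity is not None else None,
            )
        )
    return records


def cohort_to_frame(records: Iterable[SpeciesCohortRecord]) -> pd.DataFrame:
    rows = [
        {
            "species_id": r.species_id,
            "n_necropsies": r.n_necropsies,
            "n_neoplasia": r.n_neoplasia,
            "n_malignant": r.n_malignant,
            "longevity_months": r.longevity,
            "neoplasia_prevalence": r.neoplasia_prevalence,
            "malignancy_prevalence": r.malignancy_prevalence,
            "weight": r.weight,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def write_cohort_table(records: Iterable[SpeciesCohortRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, sep="\t", index=False)


def write_exclusion_log(log: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(log, indent=2) + "\n")
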