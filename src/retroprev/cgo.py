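"""Cancer-gene-ortholog (CGO) load per species from orthogroup tables.

Human Cancer Gene Census entries are mapped into orthogroups (the OrthoFinder
text layout: ``Orthogroups.tsv`` with comma-separated member lists per species
column, and ``Orthogroups.GeneCount.tsv`` with integer counts). A cancer
gene's contribution to a species is that species' gene count in the orthogroup
containing the gene's query protein; species totals and functional-category
tallies (somatic, germline, oncogene, TSG, fusion) sum those contributions.

Counting is per cancer gene, not per orthogroup: two census genes collapsing
into one orthogroup each contribute the species count. A ``dedupe`` switch
collapses to unique orthogroups for sensitivity analysis. Genes with role
"both" count toward oncogene AND tumor-suppressor tallies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "CancerGeneEntry",
    "CgoProfile",
    "OrthogroupError",
    "parse_orthogroups",
    "count_cgo",
    "load_cancer_genes",
    "profiles_to_frame",
]


class OrthogroupError(ValueError):
    pass


@dataclass(frozen=True)
class CancerGeneEntry:
    symbol: str
    protein_id: str
    somatic: bool
    germline: bool
    role: str  # oncogene | tsg | both | other
    fusion: bool

    def __post_init__(self) -> None:
        if self.role not in ("oncogene", "tsg", "both", "other"):
            raise ValueError(f"{self.symbol}: unknown role {self.role!r}")


@dataclass(frozen=True)
class CgoProfile:
    species_id: str
    total: int
    somatic: int
    germline: int
    oncogene: int
    tsg: int
    fusion: int


def parse_orthogroups(groups_path: str | Path, counts_path: str | Path) -> dict:
    """Parse Orthogroups.tsv + Orthogroups.GeneCount.tsv into one mapping.

    Returns ``{orthogroup_id: {"members": {species: [gene ids]},
    "counts": {species: int}}}``. The two files must agree: same orthogroup
    identifiers, and every count equal to the member-list length; mismatches
    raise :class:`OrthogroupError` listing the offending orthogroups.
    """
    groups = pd.read_csv(groups_path, sep="\t", dtype=str, keep_default_na=False)
    counts = pd.read_csv(counts_path, sep="\t")
    og_col = groups.columns[0]
    og_col_c = counts.columns[0]
    species_cols = [c for c in groups.columns[1:]]
    count_species = [c for c in counts.columns[1:] if c != "Total"]
    if set(species_cols) != set(count_species):
        raise OrthogroupError(
            f"species columns differ between files: {sorted(species_cols)} vs "
            f"{sorted(count_species)}"
        )
    group_ids = list(groups[og_col])
    count_ids = list(counts[og_col_c].astype(str))
    missing = sorted(set(group_ids) ^ set(count_ids))
    if missing:
        raise OrthogroupError(f"orthogroup identifiers mismatch between files: {missing}")

    counts = counts.set_index(og_col_c)
    mapping: dict = {}
    bad: list[str] = []
    for _, row in groups.iterrows():
        og = row[og_col]
        members = {}
        for sp in species_cols:
            cell = row[sp].strip()
            members[sp] = [g.strip() for g in cell.split(",") if g.strip()] if cell else []
        cts = {sp: int(counts.loc[og, sp]) for sp in species_cols}
        if any(cts[sp] != len(members[sp]) for sp in species_cols):
            bad.append(og)
        mapping[og] = {"members": members, "counts": cts}
    if bad:
        raise OrthogroupError(f"gene counts disagree with member lists for: {sorted(bad)}")
    return mapping


def _protein_index(orthogroups: dict, query_species: str) -> dict[str, str]:
    index: dict[str, str] = {}
    for og, rec in orthogroups.items():
        for pid in rec["members"].get(query_species, []):
            index[pid] = og
    return index


def count_cgo(
    entries: Iterable[CancerGeneEntry],
    orthogroups: dict,
    species_id: str,
    query_species: str,
    dedupe: bool = False,
    unresolved_log: Optional[list] = None,
) -> CgoProfile:
    """Tally ortholog counts for one species across cancer genes and categories.

    ``query_species`` is the orthogroup column holding the census proteins
    (normally the human proteome). Entries whose protein is unassigned to any
    orthogroup contribute zero and are appended to ``unresolved_log`` if given.
    With ``dedupe=True`` each orthogroup contributes at most once to each tally
    regardless of how many census genes map into it.
    """
    index = _protein_index(orthogroups, query_species)
    total = somatic = germline = oncogene = tsg = fusion = 0
    seen: dict[str, set] = {k: set() for k in ("total", "somatic", "germline", "onc", "tsg", "fus")}
    for entry in entries:
        og = index.get(entry.protein_id)
        if og is None:
            if unresolved_log is not None:
                unresolved_log.append(entry.symbol)
            continue
        contribution = orthogroups[og]["counts"].get(species_id, 0)

        def add(bucket: str, flag: bool) -> int:
            if not flag:
                return 0
            if dedupe:
                if og in seen[bucket]:
                    return 0
                seen[bucket].add(og)
            return contribution

        total += add("total", True)
        somatic += add("somatic", entry.somatic)
        germline += add("germline", entry.germline)
        oncogene += add("onc", entry.role in ("oncogene", "both"))
        tsg += add("tsg", entry.role in ("tsg", "both"))
        fusion += add("fus", entry.fusion)
    return CgoProfile(
        species_id=species_id,
        total=total,
        somatic=somatic,
        germline=germline,
        oncogene=oncogene,
        tsg=tsg,
        fusion=fusion,
    )


def load_cancer_genes(path: str | Path) -> list[CancerGeneEntry]:
    """Read the cancer-gene metadata TSV (symbol, protein_id, somatic,
    germline, role, fusion), mirroring Cancer Gene Census export fields."""
    df = pd.read_csv(path, sep="\t", dtype=str)

    def as_bool(v: str) -> bool:
        return str(v).strip().lower() in ("1", "true", "yes", "y")

    return [
        CancerGeneEntry(
            symbol=row.symbol,
            protein_id=row.protein_id,
            somatic=as_bool(row.somatic),
            germline=as_bool(row.germline),
            role=str(row.role).strip().lower(),
            fusion=as_bool(row.fusion),
        )
        for row in df.itertuples(index=False)
    ]


def profiles_to_frame(profiles: Iterable[CgoProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_id": p.species_id,
                "cgo_total": p.total,
                "cgo_somatic": p.somatic,
                "cgo_germline": p.germline,
                "cgo_oncogene": p.oncogene,
                "cgo_tsg": p.tsg,
                "cgo_fusion": p.fusion,
            }
            for p in profiles
        ]
    )
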