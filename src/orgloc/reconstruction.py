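"""Metabolic pathway presence/localization matrices and community filters.

Enzyme-evidence tables (one row per homolog found — or not — in a species)
are combined with consensus localization calls into a species x enzyme
matrix whose cells record both a presence status and the predicted
compartment.  Homologs whose only hits are prokaryotic are treated as
contaminants of the (meta)transcriptome and count as absent.  Pathway
completeness is all-or-nothing: one missing enzyme (e.g. carbamate kinase
in the arginine deiminase pathway) renders the pathway incomplete.

Community tables of 16S-derived lineage relative abundances are filtered
at a 1% threshold — lineages below it likely represent contaminants such
as sample bleeding during sequencing — and compared between cultures for
shared lineages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = [
    "STATUS_ORDER",
    "PathwayDefinition",
    "flag_contaminants",
    "build_matrix",
    "pathway_completeness",
    "filter_community",
    "shared_lineages",
]

#: Cell statuses from strongest to weakest evidence.  When a cell has
#: several paralogs the strongest status wins and all localizations are
#: reported as a set.
STATUS_ORDER = (
    "present_consistent",
    "present_unassigned",
    "present_truncated",
    "contaminant_only",
    "absent",
)
_STATUS_RANK = {s: i for i, s in enumerate(STATUS_ORDER)}
_PRESENT = {"present_consistent", "present_unassigned", "present_truncated"}


@dataclass
class PathwayDefinition:
    """An ordered enzyme list with optional expected compartments."""

    pathway_id: str
    enzymes: tuple[str, ...]
    expected_compartment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.enzymes = tuple(self.enzymes)
        if not self.enzymes:
            raise ValueError(f"{self.pathway_id}: enzyme list must be non-empty")
        if len(set(self.enzymes)) != len(self.enzymes):
            raise ValueError(f"{self.pathway_id}: duplicate enzymes in pathway")
        unknown = set(self.expected_compartment) - set(self.enzymes)
        if unknown:
            raise ValueError(
                f"{self.pathway_id}: expected_compartment for enzymes not in "
                f"the pathway: {sorted(unknown)}"
            )


def flag_contaminants(evidence: pd.DataFrame) -> pd.DataFrame:
    """Mark (species, enzyme) cells whose only homologs are prokaryotic.

    Adds/overwrites a boolean ``contaminant_only`` column.  A cell with at
    least one eukaryotic-hit paralog keeps its evidence; only cells where
    every found homolog best-hits a prokaryote are downgraded (they count
    as absent in pathway logic).
    """
    out = evidence.copy()
    found = out.loc[out["homolog_found"]]
    any_euk = (
        found.assign(euk=found["best_hit_taxonomy"] != "prokaryote")
        .groupby(["species", "enzyme_id"])["euk"]
        .any()
    )
    flags = []
    for row in out.itertuples(index=False):
        if not row.homolog_found:
            flags.append(False)
            continue
        flags.append(not bool(any_euk.loc[(row.species, row.enzyme_id)]))
    out["contaminant_only"] = flags
    return out


def _paralog_status(row, consensus_map: dict[str, tuple[str, str]],
                    expected: str | None) -> tuple[str, str]:
    """(status, localization) for one evidence row."""
    if not row.homolog_found:
        return "absent", "unknown"
    if row.best_hit_taxonomy == "prokaryote":
        # a prokaryote-best-hit paralog never contributes a localization;
        # the cell is downgraded only when no other paralog remains
        return "contaminant_only", "unknown"
    pid = getattr(row, "protein_id", "") or ""
    assigned, rule = consensus_map.get(pid, ("unassigned", "none"))
    if rule == "truncated":
        return "present_truncated", "unknown"
    if assigned == "unassigned":
        return "present_unassigned", "unknown"
    if expected is None or assigned == expected:
        return "present_consistent", assigned
    # localization predicted but contradicting the expectation: report the
    # prediction, do not count the cell as consistent
    return "present_unassigned", assigned


def build_matrix(
    evidence: pd.DataFrame,
    pathways: list[PathwayDefinition],
    consensus: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the species x enzyme presence/localization matrix.

    ``evidence`` may contain several rows (paralogs) per (species, enzyme);
    each paralog is scored separately, the cell takes the strongest status
    and reports the set of predicted localizations.  Paralogs whose best
    hit is prokaryotic are scored as contaminants, so a mixed cell keeps
    only its eukaryotic evidence.  ``consensus`` links
    evidence rows to localization calls via ``protein_id``.  Evidence for
    enzymes not in any pathway is ignored.  Pairs without evidence are
    absent.  Output rows are sorted by (species, pathway, enzyme) so the
    matrix is independent of evidence row order.
    """
    consensus_map: dict[str, tuple[str, str]] = {}
    if consensus is not None:
        consensus_map = {
            r.protein_id: (r.assigned, r.rule_fired)
            for r in consensus.itertuples(index=False)
        }
    enzyme_to_pathway: dict[str, str] = {}
    expected: dict[str, str | None] = {}
    for pw in pathways:
        for enz in pw.enzymes:
            enzyme_to_pathway[enz] = pw.pathway_id
            expected[enz] = pw.expected_compartment.get(enz)

    cells: dict[tuple[str, str], list[tuple[str, str]]] = {}
    species_seen: set[str] = set()
    for row in evidence.itertuples(index=False):
        species_seen.add(row.species)
        if row.enzyme_id not in enzyme_to_pathway:
            continue
        status = _paralog_status(row, consensus_map, expected[row.enzyme_id])
        cells.setdefault((row.species, row.enzyme_id), []).append(status)

    rows = []
    for species in sorted(species_seen):
        for pw in pathways:
            for enz in pw.enzymes:
                paralogs = cells.get((species, enz), [])
                if paralogs:
                    status = min(paralogs, key=lambda s: _STATUS_RANK[s[0]])[0]
                    locs = sorted(
                        {loc for _, loc in paralogs if loc != "unknown"}
                    )
                else:
                    status, locs = "absent", []
                rows.append(
                    {
                        "species": species,
                        "pathway_id": pw.pathway_id,
                        "enzyme_id": enz,
                        "status": status,
                        "localization": ",".join(locs) if locs else "unknown",
                        "n_paralogs": len(paralogs),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["species", "pathway_id", "enzyme_id", "status",
                 "localization", "n_paralogs"],
    )


def pathway_completeness(
    matrix: pd.DataFrame,
    pathway: PathwayDefinition,
    species: str,
) -> tuple[float, bool, list[str]]:
    """(fraction present, complete?, missing enzymes) for one pathway.

    Contaminant-only cells count as absent.  A pathway is complete only
    when every enzyme is present — the all-or-nothing rule under which a
    single missing enzyme (carbamate kinase, say) voids the pathway.
    """
    sub = matrix.loc[
        (matrix["species"] == species)
        & (matrix["pathway_id"] == pathway.pathway_id)
    ]
    present = {
        r.enzyme_id for r in sub.itertuples(index=False)
        if r.status in _PRESENT
    }
    missing = [e for e in pathway.enzymes if e not in present]
    fraction = len(present & set(pathway.enzymes)) / len(pathway.enzymes)
    return fraction, not missing, missing


def _culture_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("lineage", "oxygen_preference")]


def filter_community(
    table: pd.DataFrame,
    threshold: float = 0.01,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the relative-abundance contaminant filter per culture.

    A lineage is retained for a culture when its relative abundance there
    is at least the threshold (abundance exactly at the threshold is kept:
    only lineages strictly below it are discarded).  Returns a boolean
    retention table (lineage x culture) and retained counts per culture.
    """
    cultures = _culture_columns(table)
    retained = pd.DataFrame({"lineage": table["lineage"]})
    counts = {}
    for culture in cultures:
        keep = table[culture] >= threshold
        retained[culture] = keep.to_numpy()
        counts[culture] = int(keep.sum())
    return retained, counts


def shared_lineages(
    table: pd.DataFrame,
    cultures: tuple[str, str],
    threshold: float = 0.01,
    oxygen_preference: Iterable[str] | None = None,
) -> set[str]:
    """Lineages retained (post-filter) in both cultures.

    Optionally restricted to lineages whose ``oxygen_preference`` tag is in
    the given set (e.g. anaerobic/microaerophilic only).
    """
    retained, _ = filter_community(table, threshold)
    a, b = cultures
    mask = retained[a] & retained[b]
    shared = set(retained.loc[mask, "lineage"])
    if oxygen_preference is not None:
        allowed = set(oxygen_preference)
        tags = dict(zip(table["lineage"], table.get("oxygen_preference", "")))
        shared = {ln for ln in shared if tags.get(ln) in allowed}
    return shared
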