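"""Conservative consensus localization calling.

A protein is assigned to an organellar class (plastid, mitochondrion, or
secretory) only when every selected predictor agrees on it — unanimity
trades recall for precision, so a substantial fraction of genuinely
organellar proteins is expected to stay unassigned while cross-organelle
misassignment becomes very unlikely.  Membrane and peroxisome are visible
to only one multi-class predictor; they are assigned when that tool calls
them and every other selected tool says "other".  Proteins with a
truncated N-terminus are never assigned: their targeting information is
missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_io import ProteinRecord

__all__ = ["ConsensusConfig", "ConsensusCall", "consensus_call",
           "batch_consensus"]

MULTICLASS_ONLY_CLASSES = frozenset({"membrane", "peroxisome"})


@dataclass
class ConsensusConfig:
    """Which tools vote, and which one may call membrane/peroxisome."""

    selected_tools: tuple[str, ...]
    multiclass_tool: str
    organellar_classes: frozenset[str] = frozenset(
        {"plastid", "mitochondrion", "secretory"}
    )

    def __post_init__(self) -> None:
        self.selected_tools = tuple(self.selected_tools)
        self.organellar_classes = frozenset(self.organellar_classes)
        if self.multiclass_tool not in self.selected_tools:
            raise ValueError(
                f"multiclass tool {self.multiclass_tool!r} is not among the "
                f"selected tools {self.selected_tools}"
            )
        if self.organellar_classes & MULTICLASS_ONLY_CLASSES:
            raise ValueError(
                "organellar_classes must not include membrane/peroxisome"
            )


@dataclass
class ConsensusCall:
    protein_id: str
    assigned: str  # canonical class or "unassigned"
    rule_fired: str  # unanimity | multiclass_only | truncated | none
    supporting_tools: list[str] = field(default_factory=list)
    override_note: str = ""  # free text for manual N-terminus inspections


def consensus_call(
    protein_id: str,
    calls: dict[str, str],
    cfg: ConsensusConfig,
    is_partial: bool = False,
) -> ConsensusCall:
    """Consensus assignment for one protein from its per-tool calls.

    ``calls`` maps tool_id -> canonical class and must contain exactly one
    entry per selected tool.  Rules, in order: a partial N-terminus is
    never assigned; unanimity on an organellar class assigns it; membrane/
    peroxisome from the multiclass tool is accepted when all other tools
    say "other"; everything else stays unassigned.
    """
    missing = [t for t in cfg.selected_tools if t not in calls]
    if missing:
        raise ValueError(f"{protein_id}: missing call(s) from tool(s) {missing}")
    if is_partial:
        return ConsensusCall(protein_id, "unassigned", "truncated")
    votes = [calls[t] for t in cfg.selected_tools]
    first = votes[0]
    if first in cfg.organellar_classes and all(v == first for v in votes):
        return ConsensusCall(
            protein_id, first, "unanimity", list(cfg.selected_tools)
        )
    multi_vote = calls[cfg.multiclass_tool]
    others = [t for t in cfg.selected_tools if t != cfg.multiclass_tool]
    if multi_vote in MULTICLASS_ONLY_CLASSES and all(
        calls[t] == "other" for t in others
    ):
        return ConsensusCall(
            protein_id, multi_vote, "multiclass_only", [cfg.multiclass_tool]
        )
    return ConsensusCall(protein_id, "unassigned", "none")


def batch_consensus(
    calls: pd.DataFrame,
    cfg: ConsensusConfig,
    records: list[ProteinRecord] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Consensus-call every protein in a calls table.

    ``records`` supplies the is_partial flags; proteins without a record
    are treated as complete.  Returns one row per protein (sorted by
    protein id, so the output is independent of input row order) and a
    per-class summary count series.
    """
    partial = {}
    if records is not None:
        partial = {r.id: r.is_partial for r in records}
    relevant = calls.loc[calls["tool_id"].isin(cfg.selected_tools)]
    out_rows = []
    for pid, group in relevant.groupby("protein_id", sort=True):
        if group["tool_id"].duplicated().any():
            raise ValueError(f"{pid}: duplicate tool calls")
        per_tool = dict(zip(group["tool_id"], group["canonical"]))
        call = consensus_call(pid, per_tool, cfg, partial.get(pid, False))
        out_rows.append(
            {
                "protein_id": call.protein_id,
                "assigned": call.assigned,
                "rule_fired": call.rule_fired,
                "supporting_tools": ",".join(call.supporting_tools),
            }
        )
    out = pd.DataFrame(
        out_rows,
        columns=["protein_id", "assigned", "rule_fired", "supporting_tools"],
    )
    summary = (
        out["assigned"].value_counts().sort_index()
        if len(out)
        else pd.Series(dtype=int)
    )
    return out, summary
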