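"""Domain types and file I/O for the localization pipeline.

The pipeline works with a small set of tabular and sequence inputs: protein
sequences (FASTA), a gold-standard localization table, per-tool prediction
call tables, per-tool vocabulary maps, enzyme-evidence tables, community
abundance tables, and two-column spectra.  Everything tabular moves through
pandas DataFrames validated against named schemas; sequences are held as
:class:`ProteinRecord` objects.

Localization classes form a closed vocabulary of seven values
(:data:`CANONICAL_CLASSES`).  ``unassigned`` is an output-only value: it can
never appear as a gold-standard label.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CANONICAL_CLASSES",
    "GOLD_CLASSES",
    "AMINO_ACIDS",
    "ProteinRecord",
    "VocabularyMap",
    "read_fasta",
    "write_fasta",
    "map_labels",
    "read_table",
    "write_table",
    "SCHEMAS",
]

#: Closed localization vocabulary.  ``unassigned`` is produced only by the
#: consensus caller and is never a valid gold-standard label.
CANONICAL_CLASSES = (
    "plastid",
    "mitochondrion",
    "secretory",
    "membrane",
    "peroxisome",
    "other",
    "unassigned",
)

#: Classes a gold-standard label may take.
GOLD_CLASSES = tuple(c for c in CANONICAL_CLASSES if c != "unassigned")

#: The 20 standard residues plus X for unknown.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_LETTERS = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an N-terminus completeness flag.

    ``is_partial`` marks transcripts truncated at the N-terminus; such
    sequences carry no usable targeting information and are excluded from
    presequence feature cohorts and never consensus-assigned.
    """

    id: str
    sequence: str
    description: str = ""
    is_partial: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        seq = self.sequence.upper()
        for pos, letter in enumerate(seq, start=1):
            if letter not in ALLOWED_LETTERS:
                raise ValueError(
                    f"{self.id}: illegal residue {letter!r} at position {pos}"
                )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


def _infer_partial(sequence: str, description: str) -> bool:
    # Policy: a transcript is N-terminally incomplete when it does not start
    # with Met, or when the assembler marked it "partial" in the description.
    if not sequence.upper().startswith("M"):
        return True
    return "partial" in description.lower().split()


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased.  ``is_partial`` is set when the first residue
    is not M or the description contains a ``partial`` token.  Raises
    ``ValueError`` on an empty file, a duplicate id, or an illegal residue
    (the error names the record and position).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        desc = rec.description[len(rec.id):].strip()
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=seq,
                description=desc,
                is_partial=_infer_partial(seq, desc),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as unwrapped FASTA (one sequence line per record)."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=None)
        writer.write_file(seqs)


@dataclass
class VocabularyMap:
    """Per-tool mapping from native predictor labels to canonical classes.

    Each predictor emits its own label vocabulary (e.g. ``cTP``, ``mTP``,
    ``SP`` for a transit-peptide predictor); this map reconciles them onto
    the shared seven-class vocabulary.  Many-to-one mappings are allowed.
    """

    pairs: dict[tuple[str, str], str] = field(default_factory=dict)

    def add(self, tool_id: str, native_label: str, canonical: str) -> None:
        if canonical not in CANONICAL_CLASSES:
            raise ValueError(f"unknown canonical class {canonical!r}")
        self.pairs[(tool_id, native_label)] = canonical

    def lookup(self, tool_id: str, native_label: str) -> str:
        try:
            return self.pairs[(tool_id, native_label)]
        except KeyError:
            raise KeyError(
                f"no vocabulary entry for tool {tool_id!r}, "
                f"native label {native_label!r}"
            ) from None

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "VocabularyMap":
        vmap = cls()
        for row in frame.itertuples(index=False):
            vmap.add(row.tool_id, row.native_label, row.canonical)
        return vmap

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"tool_id": t, "native_label": n, "canonical": c}
            for (t, n), c in sorted(self.pairs.items())
        ]
        return pd.DataFrame(rows, columns=["tool_id", "native_label", "canonical"])

    @classmethod
    def identity(cls, tool_ids: Iterable[str]) -> "VocabularyMap":
        """Identity map for tools that already emit canonical class names."""
        vmap = cls()
        for tool in tool_ids:
            for cls_name in CANONICAL_CLASSES:
                vmap.add(tool, cls_name, cls_name)
        return vmap


def map_labels(calls: pd.DataFrame, vmap: VocabularyMap) -> pd.DataFrame:
    """Fill the ``canonical`` column of a calls table from a vocabulary map.

    Input row order is preserved.  Raises ``KeyError`` naming the tool and
    label on the first unmapped (tool_id, native_label) pair.
    """
    out = calls.copy()
    out["canonical"] = [
        vmap.lookup(t, n) for t, n in zip(out["tool_id"], out["native_label"])
    ]
    return out


# ---------------------------------------------------------------------------
# Tabular schemas


def _check_classes(frame: pd.DataFrame, column: str, allowed: Sequence[str]) -> None:
    bad = set(frame[column]) - set(allowed)
    if bad:
        raise ValueError(f"invalid value(s) in column {column!r}: {sorted(bad)}")


def _validate_labels(frame: pd.DataFrame) -> pd.DataFrame:
    _check_classes(frame, "true_class", GOLD_CLASSES)
    return frame


def _validate_calls(frame: pd.DataFrame) -> pd.DataFrame:
    if "canonical" in frame.columns:
        _check_classes(frame, "canonical", CANONICAL_CLASSES)
    if "score" in frame.columns:
        scores = frame["score"].dropna()
        if ((scores < 0) | (scores > 1)).any():
            raise ValueError("call scores must lie in [0, 1]")
    return frame


def _validate_vocabulary(frame: pd.DataFrame) -> pd.DataFrame:
    _check_classes(frame, "canonical", CANONICAL_CLASSES)
    return frame


def _validate_evidence(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    if frame["homolog_found"].dtype != bool:
        frame["homolog_found"] = (
            frame["homolog_found"].astype(str).str.lower().map(
                {"true": True, "false": False}
            )
        )
        if frame["homolog_found"].isna().any():
            raise ValueError("homolog_found must be true/false")
    _check_classes(frame, "best_hit_taxonomy", ("eukaryote", "prokaryote", "unknown"))
    return frame


def _validate_abundance(frame: pd.DataFrame) -> pd.DataFrame:
    value_cols = [
        c for c in frame.columns if c not in ("lineage", "oxygen_preference")
    ]
    if not value_cols:
        raise ValueError("abundance table needs at least one culture column")
    for col in value_cols:
        values = pd.to_numeric(frame[col], errors="raise")
        if (values < 0).any():
            raise ValueError(f"negative abundance in culture column {col!r}")
        frame[col] = values
    return frame


def _validate_spectrum(frame: pd.DataFrame) -> pd.DataFrame:
    wn = pd.to_numeric(frame["wavenumber"], errors="raise")
    if not wn.is_monotonic_increasing or wn.duplicated().any():
        raise ValueError("wavenumber axis must be strictly increasing")
    frame["wavenumber"] = wn
    frame["intensity"] = pd.to_numeric(frame["intensity"], errors="raise")
    return frame


@dataclass(frozen=True)
class TableSchema:
    name: str
    required: tuple[str, ...]
    optional: tuple[str, ...] = ()
    key: tuple[str, ...] = ()
    free_columns: bool = False
    validator: object = None


SCHEMAS: dict[str, TableSchema] = {
    "labels": TableSchema(
        "labels", ("protein_id", "true_class"), key=("protein_id",),
        validator=_validate_labels,
    ),
    "calls": TableSchema(
        "calls", ("protein_id", "tool_id", "native_label"),
        optional=("canonical", "score"), key=("protein_id", "tool_id"),
        validator=_validate_calls,
    ),
    "vocabulary": TableSchema(
        "vocabulary", ("tool_id", "native_label", "canonical"),
        key=("tool_id", "native_label"), validator=_validate_vocabulary,
    ),
    "consensus": TableSchema(
        "consensus", ("protein_id", "assigned", "rule_fired"),
        optional=("supporting_tools", "override_note"), key=("protein_id",),
    ),
    "evidence": TableSchema(
        "evidence",
        ("species", "enzyme_id", "homolog_found", "best_hit_taxonomy"),
        optional=("protein_id", "n_paralogs", "status"),
        validator=_validate_evidence,
    ),
    "abundance": TableSchema(
        "abundance", ("lineage",), key=("lineage",), free_columns=True,
        validator=_validate_abundance,
    ),
    "spectrum": TableSchema(
        "spectrum", ("wavenumber", "intensity"), validator=_validate_spectrum,
    ),
}


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and validate a TSV file against a named schema.

    Raises ``ValueError`` naming any missing required column, any duplicate
    key, or any value that violates the schema's constraints.
    """
    schema = SCHEMAS[schema_name]
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return validate_table(frame, schema_name, source=str(path))


def validate_table(
    frame: pd.DataFrame, schema_name: str, source: str = "<frame>"
) -> pd.DataFrame:
    schema = SCHEMAS[schema_name]
    missing = [c for c in schema.required if c not in frame.columns]
    if missing:
        raise ValueError(f"{source}: missing column(s) {missing} for schema "
                         f"{schema_name!r}")
    if not schema.free_columns:
        known = set(schema.required) | set(schema.optional)
        extra = [c for c in frame.columns if c not in known]
        if extra:
            raise ValueError(f"{source}: unexpected column(s) {extra} for "
                             f"schema {schema_name!r}")
    frame = frame.copy()
    if "score" in frame.columns:
        frame["score"] = pd.to_numeric(
            frame["score"].replace("", None), errors="raise"
        )
    if "n_paralogs" in frame.columns:
        frame["n_paralogs"] = pd.to_numeric(
            frame["n_paralogs"].replace("", "0"), errors="raise"
        ).astype(int)
    if schema.key:
        dup = frame.duplicated(subset=list(schema.key))
        if dup.any():
            first = frame.loc[dup, list(schema.key)].iloc[0].tolist()
            raise ValueError(
                f"{source}: duplicate key {tuple(first)} on {schema.key}"
            )
    if schema.validator is not None:
        frame = schema.validator(frame)
    return frame


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a table as tab-separated UTF-8 with a header and no index."""
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8")
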