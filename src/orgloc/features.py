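"""Transit-peptide validation features.

Predicted chloroplast transit peptides (cTP) and mitochondrial transit
peptides (mTP) have distinctive N-terminal architecture: cTPs are
relatively uncharged at the very N-terminus and most positively charged in
the central part, while mTPs are most positively charged from the start.
Both classes show a high prevalence of "GLK" sites — short stretches rich
in F/G/L/K, putative interaction sites for the chloroplast protein import
(Toc) machinery — within the first ~40 residues of plastid proteins and
the first ~20 of mitochondrial ones.  This module computes the features
that make those expectations checkable on any cohort of sequences:
positional charge profiles, region charge summaries, GLK-site scans, and
position-specific residue enrichment (log2 observed/background).

Residue positions are 1-based throughout.  Sequences flagged as
N-terminally partial are excluded from cohort statistics by default, since
a truncated N-terminus carries no targeting information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import AMINO_ACIDS, ALLOWED_LETTERS, ProteinRecord

__all__ = [
    "CHARGE",
    "MotifGrammar",
    "MotifScanResult",
    "residue_charge",
    "positional_charge_profile",
    "region_charge_summary",
    "scan_glk_sites",
    "glk_prevalence",
    "sentinel_enrichment",
]

# Charge convention at assumed physiological pH: K/R positive, D/E negative,
# H (and the unknown residue X) neutral.
CHARGE = {letter: 0 for letter in ALLOWED_LETTERS}
CHARGE.update({"K": 1, "R": 1, "D": -1, "E": -1})


def residue_charge(residue: str, charge_table: dict[str, int] | None = None) -> int:
    """Integer charge of one residue letter (+1 K/R, -1 D/E, else 0)."""
    table = charge_table or CHARGE
    try:
        return table[residue.upper()]
    except KeyError:
        raise ValueError(f"illegal residue letter {residue!r}") from None


def _cohort(records: list[ProteinRecord], include_partial: bool) -> list[ProteinRecord]:
    if include_partial:
        return list(records)
    return [r for r in records if not r.is_partial]


def positional_charge_profile(
    records: list[ProteinRecord],
    max_position: int,
    include_partial: bool = False,
) -> pd.DataFrame:
    """Mean residue charge at each position 1..max_position across a cohort.

    Sequences shorter than a position drop out of that position's mean, so
    ``n_contributing`` is non-increasing.  Returns a frame with columns
    ``position``, ``mean_charge``, ``n_contributing``.
    """
    if max_position < 1:
        raise ValueError("max_position must be >= 1")
    cohort = _cohort(records, include_partial)
    if not cohort:
        raise ValueError("no sequences in cohort")
    sums = np.zeros(max_position)
    counts = np.zeros(max_position, dtype=int)
    for rec in cohort:
        upto = min(len(rec.sequence), max_position)
        charges = np.fromiter(
            (CHARGE[c] for c in rec.sequence[:upto]), dtype=int, count=upto
        )
        sums[:upto] += charges
        counts[:upto] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "position": np.arange(1, max_position + 1),
            "mean_charge": means,
            "n_contributing": counts,
        }
    )


def region_charge_summary(
    records: list[ProteinRecord],
    first_k: int,
    central: tuple[int, int],
    include_partial: bool = False,
) -> tuple[float, float]:
    """Mean charge over the first ``first_k`` residues and a central window.

    Each region mean is computed per sequence (only sequences long enough to
    cover the whole region contribute) and then averaged over sequences.
    """
    lo, hi = central
    if first_k < 1 or lo < 1 or hi < lo:
        raise ValueError("invalid region windows")
    cohort = _cohort(records, include_partial)

    def region_mean(start: int, end: int) -> float:
        values = [
            np.mean([CHARGE[c] for c in rec.sequence[start - 1:end]])
            for rec in cohort
            if len(rec.sequence) >= end
        ]
        if not values:
            raise ValueError(
                f"no sequence covers region ({start}, {end})"
            )
        return float(np.mean(values))

    return region_mean(1, first_k), region_mean(lo, hi)


@dataclass(frozen=True)
class MotifGrammar:
    """GLK-site grammar: a fixed-length subwindow is a site when it contains
    at least ``min_distinct`` distinct letters from ``alphabet``.

    The exact site definition varies between studies, so every piece is
    configurable; the default (length-4 window, >=3 distinct of F/G/L/K)
    is a reasonable reading of the published FGLK-site concept.
    """

    site_length: int = 4
    alphabet: frozenset[str] = frozenset("FGLK")
    min_distinct: int = 3


@dataclass
class MotifScanResult:
    protein_id: str
    window: tuple[int, int]  # 1-based inclusive, as scanned (after clipping)
    site_start_positions: list[int] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.site_start_positions)


def scan_glk_sites(
    record: ProteinRecord,
    window: tuple[int, int],
    grammar: MotifGrammar | None = None,
) -> MotifScanResult:
    """Scan an N-terminal window for GLK sites.

    A site is a ``grammar.site_length``-residue subwindow whose start lies
    inside ``window`` (1-based inclusive) and which contains at least
    ``grammar.min_distinct`` distinct letters from the grammar alphabet.
    Overlapping sites are all reported.  A window extending past the
    sequence end is clipped with a warning.
    """
    grammar = grammar or MotifGrammar()
    start, end = window
    if start < 1 or end < start:
        raise ValueError(f"invalid scan window {window}")
    seq = record.sequence
    if end > len(seq):
        warnings.warn(
            f"{record.id}: scan window {window} clipped to sequence "
            f"length {len(seq)}",
            stacklevel=2,
        )
        end = len(seq)
    positions = []
    last_start = min(end, len(seq) - grammar.site_length + 1)
    for pos in range(start, last_start + 1):
        sub = seq[pos - 1: pos - 1 + grammar.site_length]
        distinct = set(sub) & grammar.alphabet
        if len(distinct) >= grammar.min_distinct:
            positions.append(pos)
    return MotifScanResult(record.id, (start, end), positions)


def glk_prevalence(
    records: list[ProteinRecord],
    window: tuple[int, int],
    grammar: MotifGrammar | None = None,
    include_partial: bool = False,
) -> float:
    """Fraction of cohort sequences with at least one GLK site in window."""
    cohort = _cohort(records, include_partial)
    if not cohort:
        raise ValueError("no sequences in cohort")
    hits = sum(
        1 for rec in cohort if scan_glk_sites(rec, window, grammar).count > 0
    )
    return hits / len(cohort)


def sentinel_enrichment(
    records: list[ProteinRecord],
    background_frequencies: dict[str, float] | np.ndarray,
    k: int,
    pseudocount: float = 0.5,
    include_partial: bool = False,
) -> pd.DataFrame:
    """Position x residue log2 enrichment over background for positions 1..k.

    enrichment[p][a] = log2(((count(a at p) + psi) / (n_p + 20 psi)) /
    background[a]) where n_p counts sequences of length >= p and psi is the
    pseudocount.  Lets any sentinel-residue pattern (e.g. early Ala/Ser in
    cTPs, Arg in mTPs) be read off directly.  Returns a frame indexed by
    position with one column per residue.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if isinstance(background_frequencies, dict):
        background = np.array(
            [background_frequencies[a] for a in AMINO_ACIDS], dtype=float
        )
    else:
        background = np.asarray(background_frequencies, dtype=float)
    if background.shape != (20,):
        raise ValueError("background must cover the 20 residues")
    if abs(background.sum() - 1.0) > 1e-6:
        raise ValueError("background frequencies must sum to 1")
    cohort = _cohort(records, include_partial)
    if not cohort:
        raise ValueError("no sequences in cohort")

    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    counts = np.zeros((k, 20))
    n_at = np.zeros(k)
    for rec in cohort:
        upto = min(len(rec.sequence), k)
        n_at[:upto] += 1
        for pos in range(upto):
            letter = rec.sequence[pos]
            if letter in aa_index:  # X carries no information
                counts[pos, aa_index[letter]] += 1
    zero_bg = {a for a in AMINO_ACIDS if background[aa_index[a]] == 0}
    if zero_bg:
        # a zero background makes the log-odds infinite for that residue
        raise ValueError(
            f"background frequency is zero for residue(s) "
            f"{sorted(zero_bg)}; add a pseudocount to the background"
        )
    freqs = (counts + pseudocount) / (n_at[:, None] + 20 * pseudocount)
    with np.errstate(divide="ignore"):
        enrichment = np.log2(freqs / background[None, :])
    frame = pd.DataFrame(
        enrichment, index=pd.RangeIndex(1, k + 1, name="position"),
        columns=list(AMINO_ACIDS),
    )
    return frame
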