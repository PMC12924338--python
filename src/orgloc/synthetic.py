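"""Synthetic data with the statistical structure the pipeline assumes.

Four generators cover every input the analysis touches:

* labeled proteomes whose presequences carry the charge architecture of real
  targeting peptides — chloroplast transit peptides (cTP) uncharged at the
  N-terminus and most positively charged in the central part, mitochondrial
  transit peptides (mTP) positively charged from the very start — plus
  optionally planted FGLK sites, the putative Toc-interaction motifs;
* mock predictor call tables drawn from per-tool confusion matrices
  (row-stochastic true-class -> emitted-class models);
* two-culture 16S community abundance tables with planted sub-1% noise
  lineages and a configurable shared lineage subset;
* two-peak Raman spectra (CH2 deformation at 1440 cm^-1, C=C stretch at
  1656 cm^-1) over a linear baseline with Gaussian noise.

All generators are deterministic for a fixed seed; substreams are derived
from one global seed via ``numpy.random.SeedSequence.spawn`` so the
components stay independent yet reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import AMINO_ACIDS, GOLD_CLASSES, ProteinRecord
from .spectra import Spectrum

__all__ = [
    "ProteomeConfig",
    "ToolErrorModel",
    "SpectrumConfig",
    "generate_labeled_proteome",
    "generate_tool_calls",
    "generate_spectrum",
    "generate_community_table",
]

_AA = np.array(list(AMINO_ACIDS))
_KR = np.isin(_AA, ["K", "R"])
_MOTIF = np.isin(_AA, list("FGLK"))


def _default_background() -> np.ndarray:
    freqs = np.where(_MOTIF, 0.02, (1.0 - 4 * 0.02) / 16)
    return freqs


@dataclass
class ProteomeConfig:
    """Parameters of the labeled-proteome generator.

    Counts are per localization class.  Presequence composition is sampled
    from ``background_frequencies`` (order ACDEFGHIKLMNPQRSTVWY) with K/R
    probability multiplied by the stated boost inside the charged region:
    the middle third of the cTP for plastid proteins, the first 10 residues
    of the mTP for mitochondrial proteins.  Outside charged regions, the
    first 10 cTP residues have K/R suppressed (divided by the boost) so the
    cTP N-terminus stays relatively uncharged.  One literal ``FGLK`` 4-mer
    is planted with the per-class probability inside the class window
    (first 40 residues for plastid, first 20 for mitochondrion); background
    occurrences are not suppressed.

    The default background downweights the motif alphabet F/G/L/K (0.02
    each, the 16 other residues uniform at 0.0575) so spontaneous GLK-like
    4-mers stay rare and the planted-site probabilities remain
    interpretable as site prevalences.
    """

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {
            "plastid": 100, "mitochondrion": 100, "secretory": 100, "other": 100,
        }
    )
    ctp_length_range: tuple[int, int] = (40, 70)
    mtp_length_range: tuple[int, int] = (20, 60)
    mature_length_range: tuple[int, int] = (120, 300)
    background_frequencies: np.ndarray = field(
        default_factory=lambda: _default_background()
    )
    ctp_center_KR_boost: float = 3.0
    mtp_start_KR_boost: float = 3.0
    glk_insert_prob_plastid: float = 0.8
    glk_insert_prob_mito: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        self.background_frequencies = np.asarray(
            self.background_frequencies, dtype=float
        )
        if self.background_frequencies.shape != (20,):
            raise ValueError("background_frequencies must have length 20")
        if abs(self.background_frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("background_frequencies must sum to 1")
        if (self.background_frequencies < 0).any():
            raise ValueError("background_frequencies must be non-negative")
        for name, count in self.n_per_class.items():
            if name not in GOLD_CLASSES:
                raise ValueError(f"unknown class {name!r}")
            if count < 0:
                raise ValueError("class counts must be >= 0")
        for prob in (self.glk_insert_prob_plastid, self.glk_insert_prob_mito):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("GLK insert probabilities must lie in [0, 1]")
        for lo, hi in (self.ctp_length_range, self.mtp_length_range,
                       self.mature_length_range):
            if lo < 4 or hi < lo:
                raise ValueError("length ranges must satisfy 4 <= lo <= hi")


@dataclass
class ToolErrorModel:
    """Row-stochastic confusion model (true class -> emitted class)."""

    tool_id: str
    confusion: pd.DataFrame  # rows: true class, columns: emitted class

    def __post_init__(self) -> None:
        rows = np.asarray(self.confusion, dtype=float)
        if (rows < 0).any():
            raise ValueError(f"{self.tool_id}: confusion entries must be >= 0")
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.tool_id}: confusion rows must sum to 1")

    @classmethod
    def diagonal(
        cls,
        tool_id: str,
        accuracy: float,
        classes: tuple[str, ...] = ("plastid", "mitochondrion", "secretory", "other"),
        emit_classes: tuple[str, ...] | None = None,
    ) -> "ToolErrorModel":
        """Model with ``accuracy`` on the diagonal and errors spread evenly."""
        emit = list(emit_classes or classes)
        mat = pd.DataFrame(0.0, index=list(classes), columns=emit)
        for c in classes:
            others = [e for e in emit if e != c]
            mat.loc[c, c] = accuracy
            if others:
                mat.loc[c, others] = (1.0 - accuracy) / len(others)
            else:
                mat.loc[c, c] = 1.0
        return cls(tool_id, mat)

    @classmethod
    def uniform(
        cls,
        tool_id: str,
        classes: tuple[str, ...] = ("plastid", "mitochondrion", "secretory", "other"),
    ) -> "ToolErrorModel":
        """Random-guessing model: every row uniform over the classes."""
        mat = pd.DataFrame(
            1.0 / len(classes), index=list(classes), columns=list(classes)
        )
        return cls(tool_id, mat)


@dataclass
class SpectrumConfig:
    """Parameters of the two-peak Raman spectrum generator.

    ``true_ratio`` is the height of the C=C band (1656 cm^-1) relative to
    the CH2 band (1440 cm^-1), i.e. the unsaturation ratio the downstream
    statistic should recover.  The default 1.07 mirrors a monounsaturated
    triacylglycerol signature.
    """

    peak_centers: tuple[float, float] = (1656.0, 1440.0)
    peak_widths: tuple[float, float] = (12.0, 14.0)
    true_ratio: float = 1.07
    baseline_slope: float = 0.0
    baseline_intercept: float = 0.0
    noise_sd: float = 0.0
    axis_start: float = 1300.0
    axis_stop: float = 1800.0
    axis_step: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_ratio <= 0:
            raise ValueError("true_ratio must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = sorted((self.axis_start, self.axis_stop))
        for center in self.peak_centers:
            if not lo <= center <= hi:
                raise ValueError(
                    f"peak center {center} outside axis [{lo}, {hi}]"
                )


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


def _sample(rng: np.random.Generator, weights: np.ndarray, size: int) -> np.ndarray:
    probs = weights / weights.sum()
    return rng.choice(_AA, size=size, p=probs)


def _boosted(background: np.ndarray, boost: float) -> np.ndarray:
    weights = background.copy()
    weights[_KR] *= boost
    return weights


def _plant_fglk(rng: np.random.Generator, residues: np.ndarray, window_end: int) -> None:
    # overwrite a random 4-mer whose start lies within the class window
    limit = min(window_end, len(residues) - 3)
    start = rng.integers(0, limit)
    residues[start:start + 4] = list("FGLK")


def _make_plastid(rng: np.random.Generator, cfg: ProteomeConfig) -> str:
    tp_len = int(rng.integers(*cfg.ctp_length_range, endpoint=True))
    mature_len = int(rng.integers(*cfg.mature_length_range, endpoint=True))
    bg = cfg.background_frequencies
    third = tp_len // 3
    # N-terminal stretch: K/R suppressed; middle third: K/R boosted.
    # Regions are placed so that, counting the initiator Met as position 1,
    # the uncharged stretch covers full-sequence positions 1-10.
    head = _sample(rng, _boosted(bg, 1.0 / cfg.ctp_center_KR_boost),
                   min(9, third))
    mid_start = len(head)
    pre_mid = _sample(rng, bg, max(0, third - mid_start))
    center = _sample(rng, _boosted(bg, cfg.ctp_center_KR_boost), third)
    tail = _sample(rng, bg, tp_len - len(head) - len(pre_mid) - len(center))
    tp = np.concatenate([head, pre_mid, center, tail])
    if rng.random() < cfg.glk_insert_prob_plastid:
        _plant_fglk(rng, tp, window_end=min(39, tp_len))  # window: first 40 incl M
    mature = _sample(rng, bg, mature_len)
    return "M" + "".join(tp) + "".join(mature)


def _make_mito(rng: np.random.Generator, cfg: ProteomeConfig) -> str:
    tp_len = int(rng.integers(*cfg.mtp_length_range, endpoint=True))
    mature_len = int(rng.integers(*cfg.mature_length_range, endpoint=True))
    bg = cfg.background_frequencies
    # charged start covers full-sequence positions 1-10 (position 1 is M)
    start = _sample(rng, _boosted(bg, cfg.mtp_start_KR_boost), min(9, tp_len))
    rest = _sample(rng, bg, tp_len - len(start))
    tp = np.concatenate([start, rest])
    if rng.random() < cfg.glk_insert_prob_mito:
        _plant_fglk(rng, tp, window_end=min(19, tp_len))
    mature = _sample(rng, bg, mature_len)
    return "M" + "".join(tp) + "".join(mature)


def _make_secretory(rng: np.random.Generator, cfg: ProteomeConfig) -> str:
    # minimal signal peptide: uncharged hydrophobic stretch after the Met
    leader_len = int(rng.integers(15, 25, endpoint=True))
    leader = rng.choice(list("ALVF"), size=leader_len)
    mature_len = int(rng.integers(*cfg.mature_length_range, endpoint=True))
    mature = _sample(rng, cfg.background_frequencies, mature_len)
    return "M" + "".join(leader) + "".join(mature)


def _make_other(rng: np.random.Generator, cfg: ProteomeConfig) -> str:
    mature_len = int(rng.integers(*cfg.mature_length_range, endpoint=True))
    mature = _sample(rng, cfg.background_frequencies, mature_len)
    return "M" + "".join(mature)


_MAKERS = {
    "plastid": _make_plastid,
    "mitochondrion": _make_mito,
    "secretory": _make_secretory,
    "other": _make_other,
}


def generate_labeled_proteome(
    cfg: ProteomeConfig,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate a labeled synthetic proteome.

    Returns the protein records and a gold-standard labels table
    (``protein_id``, ``true_class``).  Class counts equal the config counts
    exactly; output is reproducible for a fixed ``cfg.seed``.
    """
    (rng,) = _spawn(cfg.seed, 1)
    records: list[ProteinRecord] = []
    labels: list[dict[str, str]] = []
    counter = 0
    for cls_name in ("plastid", "mitochondrion", "secretory", "other"):
        maker = _MAKERS[cls_name]
        for _ in range(cfg.n_per_class.get(cls_name, 0)):
            counter += 1
            pid = f"syn{counter:05d}"
            seq = maker(rng, cfg)
            records.append(
                ProteinRecord(id=pid, sequence=seq,
                              description=f"synthetic {cls_name}")
            )
            labels.append({"protein_id": pid, "true_class": cls_name})
    label_frame = pd.DataFrame(labels, columns=["protein_id", "true_class"])
    return records, label_frame


def generate_tool_calls(
    labels: pd.DataFrame,
    models: list[ToolErrorModel],
    seed: int = 0,
) -> pd.DataFrame:
    """Draw one call per protein x tool from each tool's confusion rows.

    Emitted classes are independent across proteins and tools.  The output
    calls table carries the emitted class both as ``native_label`` and as
    ``canonical`` (synthetic tools speak the canonical vocabulary).
    """
    rngs = _spawn(seed, max(len(models), 1))
    frames = []
    for model, rng in zip(models, rngs):
        missing = set(labels["true_class"]) - set(model.confusion.index)
        if missing:
            raise ValueError(
                f"{model.tool_id}: no confusion row for class(es) "
                f"{sorted(missing)}"
            )
        emit_classes = np.array(model.confusion.columns)
        emitted = np.empty(len(labels), dtype=object)
        for cls_name, group in labels.groupby("true_class", sort=True):
            probs = model.confusion.loc[cls_name].to_numpy(dtype=float)
            idx = rng.choice(len(emit_classes), size=len(group), p=probs)
            emitted[labels.index.get_indexer(group.index)] = emit_classes[idx]
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": labels["protein_id"].to_numpy(),
                    "tool_id": model.tool_id,
                    "native_label": emitted,
                    "canonical": emitted,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["protein_id", "tool_id", "native_label", "canonical"]
        )
    return pd.concat(frames, ignore_index=True)


def generate_spectrum(cfg: SpectrumConfig) -> Spectrum:
    """Generate a two-peak spectrum: baseline + Gaussians + noise.

    The CH2 band (second peak center) has height 1; the C=C band (first
    peak center) has height ``cfg.true_ratio``.
    """
    (rng,) = _spawn(cfg.seed, 1)
    axis = np.arange(cfg.axis_start, cfg.axis_stop + cfg.axis_step / 2,
                     cfg.axis_step)
    c_cc, c_ch2 = cfg.peak_centers
    w_cc, w_ch2 = cfg.peak_widths
    intensity = (
        cfg.baseline_intercept
        + cfg.baseline_slope * axis
        + cfg.true_ratio * np.exp(-0.5 * ((axis - c_cc) / w_cc) ** 2)
        + np.exp(-0.5 * ((axis - c_ch2) / w_ch2) ** 2)
    )
    if cfg.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, cfg.noise_sd, size=axis.shape)
    return Spectrum(wavenumber=axis, intensity=intensity)


def generate_community_table(
    n_lineages: int = 18,
    n_noise: int = 5,
    n_shared: int = 7,
    seed: int = 0,
    cultures: tuple[str, str] = ("culture_A", "culture_B"),
) -> pd.DataFrame:
    """Generate a two-culture 16S relative-abundance table.

    Each culture contains ``n_lineages`` lineages of which ``n_noise`` are
    forced below 1% relative abundance (sequencing contaminants, e.g.
    sample bleeding).  ``n_shared`` of the retained lineages are common to
    both cultures and tagged anaerobic/microaerophilic; culture-specific
    retained lineages are tagged aerobic.  Defaults emulate two co-isolated
    algal cultures each carrying 13 genuine prokaryotic lineages with 7
    shared between them.  Column sums are exactly 1 per culture.
    """
    if n_lineages < 1:
        raise ValueError("n_lineages must be >= 1")
    n_retained = n_lineages - n_noise
    if n_noise < 0 or n_retained < 0:
        raise ValueError("need 0 <= n_noise <= n_lineages")
    if not 0 <= n_shared <= n_retained:
        raise ValueError("need 0 <= n_shared <= n_lineages - n_noise")
    (rng,) = _spawn(seed, 1)

    shared = [f"shared{i + 1:02d}" for i in range(n_shared)]
    n_own = n_retained - n_shared
    rows: dict[str, dict[str, float]] = {}
    oxygen: dict[str, str] = {}
    for name in shared:
        oxygen[name] = "anaerobic_or_microaerophilic"
    for culture in cultures:
        own = [f"{culture}_only{i + 1:02d}" for i in range(n_own)]
        noise = [f"{culture}_noise{i + 1:02d}" for i in range(n_noise)]
        for name in own:
            oxygen[name] = "aerobic"
        for name in noise:
            oxygen[name] = "unknown"
        # noise mass: each strictly below the 1% threshold after normalization
        noise_ab = rng.uniform(0.001, 0.008, size=n_noise)
        retained_names = shared + own
        # floor of 2% per retained lineage guarantees every retained lineage
        # clears the 1% threshold; the remainder is spread by a Dirichlet draw
        floor = 0.02
        remainder = 1.0 - noise_ab.sum() - floor * len(retained_names)
        if remainder <= 0:
            raise ValueError("too many lineages for the abundance floors")
        dirichlet = rng.dirichlet(np.full(len(retained_names), 2.0))
        retained_ab = floor + remainder * dirichlet
        for name, ab in zip(retained_names, retained_ab):
            rows.setdefault(name, {})[culture] = ab
        for name, ab in zip(noise, noise_ab):
            rows.setdefault(name, {})[culture] = ab

    lineages = sorted(rows)
    frame = pd.DataFrame(
        {
            "lineage": lineages,
            **{
                culture: [rows[ln].get(culture, 0.0) for ln in lineages]
                for culture in cultures
            },
            "oxygen_preference": [oxygen[ln] for ln in lineages],
        }
    )
    for culture in cultures:
        frame[culture] = frame[culture] / frame[culture].sum()
    return frame
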