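"""Raman band-intensity statistics for lipid unsaturation.

The unsaturation ratio I(1656)/I(1440) compares the C=C stretching band
(1656 cm^-1) with the CH2 deformation band (1440 cm^-1) and proxies the
double-bond content of stored triacylglycerols: a ratio near 1 reflects a
monounsaturated fatty-acid profile.  Band intensity is, by default, the
local maximum height within +/-10 cm^-1 of the band center after removal
of a straight baseline anchored in two flat flanking windows; an
integrated-area mode is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "BandDefinition",
    "baseline_correct",
    "unsaturation_ratio",
    "cohort_ratio_summary",
]


@dataclass
class Spectrum:
    """A single spectrum: strictly increasing wavenumber axis + intensity."""

    wavenumber: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber.shape != self.intensity.shape:
            raise ValueError("wavenumber and intensity must have equal length")
        if self.wavenumber.size < 2:
            raise ValueError("spectrum needs at least two points")
        if not (np.diff(self.wavenumber) > 0).all():
            raise ValueError("wavenumber axis must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavenumber": self.wavenumber, "intensity": self.intensity}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Spectrum":
        return cls(frame["wavenumber"].to_numpy(),
                   frame["intensity"].to_numpy())


@dataclass
class BandDefinition:
    """The two band centers, search half-width, and baseline anchors."""

    centers: tuple[float, float] = (1656.0, 1440.0)
    half_width: float = 10.0
    #: (low, high) wavenumber ranges flanking both bands used to anchor the
    #: baseline line; chosen outside both band search windows.
    anchor_low: tuple[float, float] = (1300.0, 1350.0)
    anchor_high: tuple[float, float] = (1750.0, 1800.0)
    mode: str = "height"  # or "area"

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")
        if self.mode not in ("height", "area"):
            raise ValueError("mode must be 'height' or 'area'")
        for lo, hi in (self.anchor_low, self.anchor_high):
            if hi <= lo:
                raise ValueError("anchor windows must have lo < hi")
        for center in self.centers:
            for lo, hi in (self.anchor_low, self.anchor_high):
                if lo <= center <= hi:
                    raise ValueError(
                        f"anchor window ({lo}, {hi}) overlaps band center "
                        f"{center}"
                    )


def _window_mask(axis: np.ndarray, lo: float, hi: float) -> np.ndarray:
    mask = (axis >= lo) & (axis <= hi)
    if not mask.any():
        raise ValueError(f"window ({lo}, {hi}) contains no axis points")
    return mask


def baseline_correct(spectrum: Spectrum, bands: BandDefinition) -> Spectrum:
    """Subtract the straight line through the two anchor-window means.

    The line passes through (mean wavenumber, mean intensity) of each anchor
    window, so a purely linear ramp maps to the zero spectrum.
    """
    axis, inten = spectrum.wavenumber, spectrum.intensity
    lo_mask = _window_mask(axis, *bands.anchor_low)
    hi_mask = _window_mask(axis, *bands.anchor_high)
    x0, y0 = axis[lo_mask].mean(), inten[lo_mask].mean()
    x1, y1 = axis[hi_mask].mean(), inten[hi_mask].mean()
    slope = (y1 - y0) / (x1 - x0)
    baseline = y0 + slope * (axis - x0)
    return Spectrum(axis, inten - baseline)


def _band_intensity(spectrum: Spectrum, center: float, bands: BandDefinition) -> float:
    mask = _window_mask(
        spectrum.wavenumber, center - bands.half_width, center + bands.half_width
    )
    if bands.mode == "height":
        return float(spectrum.intensity[mask].max())
    return float(
        np.trapezoid(spectrum.intensity[mask], spectrum.wavenumber[mask])
    )


def unsaturation_ratio(
    spectrum: Spectrum,
    bands: BandDefinition | None = None,
    correct_baseline: bool = True,
) -> float:
    """I(C=C)/I(CH2) band-intensity ratio of one spectrum.

    Raises ``ValueError`` when the CH2 band intensity is non-positive
    (no band found, the ratio would be meaningless).
    """
    bands = bands or BandDefinition()
    if correct_baseline:
        spectrum = baseline_correct(spectrum, bands)
    numerator = _band_intensity(spectrum, bands.centers[0], bands)
    denominator = _band_intensity(spectrum, bands.centers[1], bands)
    if denominator <= 0:
        raise ValueError(
            f"non-positive CH2 band intensity ({denominator:.4g}); "
            "cannot form the unsaturation ratio"
        )
    return numerator / denominator


def cohort_ratio_summary(
    spectra: list[Spectrum],
    bands: BandDefinition | None = None,
) -> tuple[float, float, int]:
    """Mean, sample standard deviation (n-1), and n of per-spectrum ratios."""
    if not spectra:
        raise ValueError("cohort must contain at least one spectrum")
    ratios = np.array([unsaturation_ratio(s, bands) for s in spectra])
    sd = float(ratios.std(ddof=1)) if len(ratios) > 1 else float("nan")
    return float(ratios.mean()), sd, len(ratios)
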