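"""Smoothing, uTFMP construction, and zone segmentation.

The urinary total fluorescent metabolome profile (uTFMP) is the smoothed
synchronous fluorescence profile of one urine sample over 250-550 nm. Raw
scans are Savitzky-Golay smoothed (window 11 points, cubic), and a profile
is built either from a single dilution or as the per-wavelength maximum over
a dilution series, which captures each fluorophore at its least-quenched
dilution. Zones Z1a..Z7 partition 250-500 nm by fluorophore family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .grid import SynchronousSpectrum, WavelengthGrid

Construction = Literal["single_dilution", "max_over_dilutions"]


@dataclass(frozen=True)
class SmoothingConfig:
    window_length: int = 11
    poly_order: int = 3

    def __post_init__(self) -> None:
        if self.window_length % 2 != 1:
            raise ValueError("smoothing window must be odd")
        if self.poly_order >= self.window_length:
            raise ValueError("polynomial order must be below window length")


#: Zone bounds on the excitation axis, half-open [start, end). Parent ranges
#: Z1 (250-300) and Z4 (345-380) are split at their midpoints; the sub-zone
#: boundaries are a project convention, configurable via ZoneScheme.
DEFAULT_ZONES: tuple[tuple[str, float, float], ...] = (
    ("Z1a", 250.0, 275.0),
    ("Z1b", 275.0, 300.0),
    ("Z2", 300.0, 325.0),
    ("Z3", 325.0, 345.0),
    ("Z4a", 345.0, 362.5),
    ("Z4b", 362.5, 380.0),
    ("Z5", 380.0, 410.0),
    ("Z6", 410.0, 450.0),
    ("Z7", 450.0, 500.0),
)

ZONE_NAMES = tuple(name for name, _, _ in DEFAULT_ZONES)


@dataclass(frozen=True)
class ZoneScheme:
    """Ordered half-open wavelength intervals naming the fluorescent zones."""

    zones: tuple[tuple[str, float, float], ...] = DEFAULT_ZONES

    def __post_init__(self) -> None:
        names = [z[0] for z in self.zones]
        if set(names) != set(ZONE_NAMES) or len(names) != len(ZONE_NAMES):
            raise ValueError(f"zone names must be exactly {ZONE_NAMES}")
        prev_end = None
        for name, start, end in self.zones:
            if not (start < end):
                raise ValueError(f"zone {name}: empty or reversed interval [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"zone {name}: overlaps previous zone")
            prev_end = end
        lo, hi = self.zones[0][1], self.zones[-1][2]
        if lo < 250.0 - 1e-9 or hi > 500.0 + 1e-9:
            raise ValueError("zone scheme must lie within 250-500 nm")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(z[0] for z in self.zones)

    def bounds(self, name: str) -> tuple[float, float]:
        for n, start, end in self.zones:
            if n == name:
                return start, end
        raise KeyError(name)


@dataclass
class Utfmp:
    """A smoothed, standardized fluorescence profile for one sample."""

    sample_id: str
    grid: WavelengthGrid
    intensities: np.ndarray
    construction: Construction = "single_dilution"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.grid),):
            raise ValueError("profile length does not match grid")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("profile contains non-finite values")


def savgol_smooth(spectrum: SynchronousSpectrum, cfg: SmoothingConfig = SmoothingConfig()) -> SynchronousSpectrum:
    """Savitzky-Golay smooth a spectrum on its own grid.

    Local least-squares polynomial of ``cfg.poly_order`` over a centered
    window of ``cfg.window_length`` points; edges are handled by evaluating
    the polynomial fitted to the terminal window (scipy ``mode='interp'``),
    so the filter is exact on polynomials up to the fitted order everywhere.
    """
    if len(spectrum.intensities) < cfg.window_length:
        raise ValueError("spectrum shorter than smoothing window")
    smoothed = savgol_filter(
        spectrum.intensities, cfg.window_length, cfg.poly_order, mode="interp"
    )
    return SynchronousSpectrum(
        sample_id=spectrum.sample_id,
        grid=spectrum.grid,
        intensities=smoothed,
        delta_lambda_nm=spectrum.delta_lambda_nm,
        dilution_factor=spectrum.dilution_factor,
    )


def build_utfmp(
    series: Sequence[SynchronousSpectrum],
    cfg: SmoothingConfig = SmoothingConfig(),
    construction: Construction = "max_over_dilutions",
    dilution_factor: float = 1.0,
) -> Utfmp:
    """Build one sample's uTFMP from its dilution series.

    Smoothing is applied per dilution first. ``max_over_dilutions`` takes
    the per-wavelength maximum across the series; ``single_dilution``
    returns the spectrum at ``dilution_factor``.
    """
    if not series:
        raise ValueError("empty dilution series")
    ids = {s.sample_id for s in series}
    if len(ids) != 1:
        raise ValueError(f"mixed sample ids in series: {sorted(ids)}")
    smoothed = [savgol_smooth(s, cfg) for s in series]
    if construction == "single_dilution":
        matches = [s for s in smoothed if s.dilution_factor == dilution_factor]
        if not matches:
            raise KeyError(
                f"sample {series[0].sample_id!r}: no spectrum at dilution {dilution_factor}"
            )
        profile = matches[0].intensities
    elif construction == "max_over_dilutions":
        profile = np.max([s.intensities for s in smoothed], axis=0)
    else:
        raise ValueError(f"unknown construction {construction!r}")
    return Utfmp(
        sample_id=series[0].sample_id,
        grid=series[0].grid,
        intensities=np.clip(profile, 0.0, None),
        construction=construction,
    )


def segment_zones(profile: Utfmp, scheme: ZoneScheme = ZoneScheme()) -> dict[str, np.ndarray]:
    """Map zone name -> intensity sub-vector of grid points in [start, end)."""
    out: dict[str, np.ndarray] = {}
    for name, start, end in scheme.zones:
        sl = profile.grid.index_range(start, end)
        sub = profile.intensities[sl]
        if sub.size == 0:
            raise ValueError(f"zone {name}: no grid points in [{start}, {end})")
        out[name] = sub
    return out
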