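"""Wavelength grid and spectral containers for synchronous fluorescence scans.

A synchronous scan moves the excitation and emission monochromators together
with a fixed offset (here 30 nm) and records one intensity per excitation
wavelength, so a whole sample is a single vector on a fixed grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

DELTA_LAMBDA_NM = 30.0

GROUPS = ("control", "benign", "malignant")

STRIP_PARAMETERS = (
    "leukocytes",
    "nitrite",
    "pH",
    "specific_gravity",
    "protein",
    "glucose",
    "ketones",
    "urobilinogen",
    "bilirubin",
    "blood",
)


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform excitation-wavelength grid, default 250-550 nm at 0.5 nm."""

    start_nm: float = 250.0
    end_nm: float = 550.0
    step_nm: float = 0.5

    def __post_init__(self) -> None:
        if not self.start_nm < self.end_nm:
            raise ValueError("grid start must be below end")
        if self.step_nm <= 0:
            raise ValueError("grid step must be positive")
        n_steps = (self.end_nm - self.start_nm) / self.step_nm
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("grid span must be an integer number of steps")

    def __len__(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(len(self))

    def index_range(self, start_nm: float, end_nm: float) -> slice:
        """Slice of grid indices with start_nm <= wavelength < end_nm."""
        wl = self.wavelengths
        lo = int(np.searchsorted(wl, start_nm - 1e-9, side="left"))
        hi = int(np.searchsorted(wl, end_nm - 1e-9, side="left"))
        return slice(lo, hi)


@dataclass
class SynchronousSpectrum:
    """One sample's synchronous fluorescence scan.

    Intensities are in arbitrary fluorescence units, one per grid point.
    ``dilution_factor`` is 1 for the undiluted aliquot, 3 for a 1:3
    dilution, and so on.
    """

    sample_id: str
    grid: WavelengthGrid
    intensities: np.ndarray
    delta_lambda_nm: float = DELTA_LAMBDA_NM
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.grid),):
            raise ValueError(
                f"spectrum {self.sample_id!r}: expected {len(self.grid)} "
                f"intensities, got {self.intensities.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"spectrum {self.sample_id!r}: non-finite intensity")
        if self.dilution_factor <= 0:
            raise ValueError("dilution factor must be positive")


@dataclass
class SampleMetadata:
    """Clinical covariates for one sample."""

    sample_id: str
    group: str
    age_years: Optional[float] = None
    strip: Optional[Mapping[str, object]] = field(default=None)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"sample {self.sample_id!r}: group {self.group!r} not in {GROUPS}"
            )
        if self.age_years is not None and not (18 <= self.age_years <= 100):
            raise ValueError(
                f"sample {self.sample_id!r}: age {self.age_years} outside 18-100"
            )
        if self.strip is not None and "pH" in self.strip:
            ph = float(self.strip["pH"])
            if not (4.5 <= ph <= 9.0):
                raise ValueError(
                    f"sample {self.sample_id!r}: strip pH {ph} outside 4.5-9"
                )
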