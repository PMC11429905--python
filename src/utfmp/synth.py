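"""Seedable synthetic cohorts of synchronous urine fluorescence spectra.

Real cohorts of this kind are not publicly deposited, so every downstream
stage is exercised on a generative stand-in: each sample is a sum of
Gaussian fluorophore bands on the 250-550 nm excitation grid, with
group-specific amplitude multipliers and center shifts encoding the
qualitative disease effects (indole-region depression in malignancy, a
malignant-only 3-hydroxyanthranilic-acid band, a red-shifted NADH-like
band, kynurenine/xanthopterin depression with flavin elevation), log-normal
between-subject variability, and intensity-proportional noise.

Band positions, widths and effect sizes are calibration choices, not
measured values: they are set so the large-sample Z6/Z7 control-vs-malignant
AUC falls in 0.75-0.85, and benign effects sit between control and
malignant. See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .grid import GROUPS, SampleMetadata, SynchronousSpectrum, WavelengthGrid


@dataclass(frozen=True)
class FluorophoreBand:
    """One Gaussian emission band of a urinary fluorophore family."""

    name: str
    center_nm: float
    width_nm: float  # Gaussian sigma
    amplitude: float  # arbitrary fluorescence units

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError(f"band {self.name}: width must be positive")
        if not (250.0 <= self.center_nm <= 550.0):
            raise ValueError(f"band {self.name}: center outside 250-550 nm")
        if self.amplitude < 0:
            raise ValueError(f"band {self.name}: amplitude must be nonnegative")


#: Default bands, one or two per fluorescent zone; centers near zone midpoints.
DEFAULT_BANDS: tuple[FluorophoreBand, ...] = (
    FluorophoreBand("indoles_a", 270.0, 9.0, 350.0),
    FluorophoreBand("indoles_b", 290.0, 9.0, 300.0),
    FluorophoreBand("5-HIAA", 312.0, 8.0, 200.0),
    FluorophoreBand("3-HAA", 335.0, 7.0, 80.0),
    FluorophoreBand("NADH-like", 360.0, 9.0, 150.0),
    FluorophoreBand("xanthurenic", 395.0, 10.0, 120.0),
    FluorophoreBand("kynurenine/xanthopterin", 430.0, 11.0, 100.0),
    FluorophoreBand("flavins", 470.0, 12.0, 90.0),
)

#: Per-band amplitude multipliers by group (control, benign, malignant).
DEFAULT_MULTIPLIERS: Mapping[str, tuple[float, float, float]] = {
    "indoles_a": (1.0, 0.85, 0.60),
    "indoles_b": (1.0, 0.85, 0.60),
    "5-HIAA": (1.0, 0.72, 0.65),
    "3-HAA": (0.0, 0.0, 1.0),  # malignant-only band
    "NADH-like": (1.0, 1.40, 1.50),
    "xanthurenic": (1.0, 1.0, 1.0),  # no group difference
    "kynurenine/xanthopterin": (1.0, 0.92, 0.85),
    "flavins": (1.0, 1.09, 1.20),
}

#: Per-band center shifts in nm by group; the NADH-like band red-shifts in
#: malignant samples.
DEFAULT_SHIFTS: Mapping[str, tuple[float, float, float]] = {
    "NADH-like": (0.0, 0.0, 6.0),
}


@dataclass(frozen=True)
class GroupEffectProfile:
    """Group-wise effect model plus nuisance variation for the generator.

    Between-subject variability splits into a global urine-concentration
    factor shared by all bands (sigma_log_global, cancels in zone ratios)
    and a band-specific factor (sigma_log_band); total per-band log-sd is
    sqrt(sigma_log_global^2 + sigma_log_band^2) ~= 0.3 by default.
    """

    bands: tuple[FluorophoreBand, ...] = DEFAULT_BANDS
    multipliers: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MULTIPLIERS)
    )
    center_shifts_nm: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SHIFTS)
    )
    sigma_log_global: float = 0.22
    sigma_log_band: float = 0.204
    noise_floor: float = 1.5
    noise_frac: float = 0.02
    baseline: float = 5.0

    def __post_init__(self) -> None:
        for name, mults in self.multipliers.items():
            if any(m < 0 for m in mults):
                raise ValueError(f"band {name}: negative multiplier")
        if min(self.sigma_log_global, self.sigma_log_band, self.noise_floor, self.noise_frac) < 0:
            raise ValueError("variability and noise scales must be nonnegative")

    def multiplier(self, band: str, group: str) -> float:
        return self.multipliers.get(band, (1.0, 1.0, 1.0))[GROUPS.index(group)]

    def shift(self, band: str, group: str) -> float:
        return self.center_shifts_nm.get(band, (0.0, 0.0, 0.0))[GROUPS.index(group)]


def null_effect_profile(**overrides) -> GroupEffectProfile:
    """Effect-free profile: equal multipliers and no shifts, so the three
    groups are exchangeable (downstream classifiers should sit at AUC 0.5)."""
    mults = {name: (m[0], m[0], m[0]) for name, m in DEFAULT_MULTIPLIERS.items()}
    # the malignant-only band is dropped entirely under the null
    mults["3-HAA"] = (0.0, 0.0, 0.0)
    return GroupEffectProfile(multipliers=mults, center_shifts_nm={}, **overrides)


#: Urinalysis strip positivity rates (positive count / group n) and pH means,
#: matching the descriptive statistics of the emulated study population.
DEFAULT_STRIP_RATES: Mapping[str, Mapping[str, float]] = {
    "control": {
        "leukocytes": 4 / 96, "nitrite": 0.0, "protein": 36 / 96, "glucose": 0.0,
        "ketones": 5 / 96, "urobilinogen": 0.0, "bilirubin": 7 / 96, "blood": 8 / 96,
    },
    "benign": {
        "leukocytes": 8 / 23, "nitrite": 0.0, "protein": 11 / 23, "glucose": 0.0,
        "ketones": 8 / 23, "urobilinogen": 7 / 23, "bilirubin": 12 / 23, "blood": 1 / 23,
    },
    "malignant": {
        "leukocytes": 61 / 77, "nitrite": 0.0, "protein": 28 / 77, "glucose": 3 / 77,
        "ketones": 26 / 77, "urobilinogen": 26 / 77, "bilirubin": 38 / 77, "blood": 32 / 77,
    },
}

DEFAULT_PH_MEANS: Mapping[str, float] = {"control": 6.06, "benign": 6.43, "malignant": 5.69}
DEFAULT_PH_SD = 0.45

#: Study-design group sizes and age ranges.
DEFAULT_COUNTS = {"control": 96, "benign": 23, "malignant": 77}
_AGE_RANGES = {"control": (25, 75), "benign": (30, 80), "malignant": (40, 85)}


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one synthetic cohort deterministically."""

    n_control: int = DEFAULT_COUNTS["control"]
    n_benign: int = DEFAULT_COUNTS["benign"]
    n_malignant: int = DEFAULT_COUNTS["malignant"]
    seed: int = 0
    effect: GroupEffectProfile = GroupEffectProfile()
    grid: WavelengthGrid = WavelengthGrid()
    dilution_factors: tuple[float, ...] = ()  # empty: undiluted spectra only
    strip_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(r) for g, r in DEFAULT_STRIP_RATES.items()}
    )
    ph_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PH_MEANS))
    quench_strength: float = 2.0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_benign, self.n_malignant) < 0:
            raise ValueError("group counts must be nonnegative")
        factors = self.dilution_factors
        if factors and (min(factors) < 1 or list(factors) != sorted(set(factors))):
            raise ValueError("dilution factors must be >= 1 and strictly increasing")

    @property
    def counts(self) -> dict[str, int]:
        return {
            "control": self.n_control,
            "benign": self.n_benign,
            "malignant": self.n_malignant,
        }


def _gaussian(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def geometric_dilution_factors(ratio: int = 3, n_steps: int = 7) -> tuple[float, ...]:
    """1:3 geometric dilution series, undiluted to 729x (~1000-fold)."""
    return tuple(float(ratio**k) for k in range(n_steps))


def generate_cohort(spec: CohortSpec) -> tuple[list[SynchronousSpectrum], list[SampleMetadata]]:
    """Generate spectra and metadata for a three-group cohort.

    Deterministic given ``spec.seed``. Each sample's undiluted spectrum is
    baseline + sum of group-modulated Gaussian bands times log-normal
    subject factors, plus heteroscedastic Gaussian noise, clipped at 0.
    If ``spec.dilution_factors`` is nonempty, a quenched dilution series is
    appended per sample (see :func:`generate_dilution_series`).
    """
    if spec.n_control + spec.n_benign + spec.n_malignant == 0:
        raise ValueError("empty cohort: all group counts are zero")
    rng = np.random.default_rng(spec.seed)
    wl = spec.grid.wavelengths
    eff = spec.effect
    spectra: list[SynchronousSpectrum] = []
    metadata: list[SampleMetadata] = []
    for group in GROUPS:
        n = spec.counts[group]
        strips = generate_strip_covariates(
            group, n, seed=int(rng.integers(2**31)),
            rates=spec.strip_rates, ph_means=spec.ph_means,
        )
        lo, hi = _AGE_RANGES[group]
        for i in range(n):
            sample_id = f"{group[:3].upper()}{i + 1:03d}"
            global_factor = float(np.exp(rng.normal(0.0, eff.sigma_log_global)))
            signal = np.full_like(wl, eff.baseline)
            for band in eff.bands:
                mult = eff.multiplier(band.name, group)
                if mult == 0.0:
                    continue
                subject_factor = float(np.exp(rng.normal(0.0, eff.sigma_log_band)))
                center = band.center_nm + eff.shift(band.name, group)
                signal = signal + (
                    band.amplitude * mult * global_factor * subject_factor
                    * _gaussian(wl, center, band.width_nm)
                )
            noise_sd = eff.noise_floor + eff.noise_frac * signal
            observed = np.clip(signal + rng.normal(0.0, 1.0, wl.size) * noise_sd, 0.0, None)
            base = SynchronousSpectrum(
                sample_id=sample_id, grid=spec.grid, intensities=observed
            )
            if spec.dilution_factors:
                spectra.extend(
                    generate_dilution_series(
                        base, spec.dilution_factors, spec.quench_strength
                    )
                )
            else:
                spectra.append(base)
            metadata.append(
                SampleMetadata(
                    sample_id=sample_id,
                    group=group,
                    age_years=float(rng.uniform(lo, hi)),
                    strip=strips[i],
                )
            )
    return spectra, metadata


def generate_dilution_series(
    spectrum: SynchronousSpectrum,
    factors: Sequence[float],
    quench_strength: float = 2.0,
    seed: int | None = None,
    noise_scale: float = 0.0,
) -> list[SynchronousSpectrum]:
    """Quenched dilution series from one undiluted spectrum.

    At relative concentration c = 1/factor the observed signal follows the
    inner-filter form S(c) proportional to c * exp(-q*c), anchored so factor 1
    reproduces the input spectrum:

        S_f = S_1 * (1/f) * exp(q * (1 - 1/f))

    With q = 0 intensity scales exactly as 1/f; with q > 1 the per-wavelength
    maximum sits at an interior concentration c = 1/q, i.e. moderately
    diluted urine fluoresces more than raw urine, which is the rationale for
    measuring a dilution series at all.
    """
    if any(f < 1 for f in factors):
        raise ValueError("dilution factors must be >= 1")
    if quench_strength < 0:
        raise ValueError("quench strength must be nonnegative")
    rng = np.random.default_rng(seed)
    out = []
    for f in factors:
        c = 1.0 / f
        scale = c * np.exp(quench_strength * (1.0 - c))
        intens = spectrum.intensities * scale
        if noise_scale > 0:
            intens = np.clip(intens + rng.normal(0.0, noise_scale, intens.size), 0.0, None)
        out.append(replace(spectrum, intensities=intens, dilution_factor=float(f)))
    return out


def generate_strip_covariates(
    group: str,
    n: int,
    seed: int | None = None,
    rates: Mapping[str, Mapping[str, float]] | None = None,
    ph_means: Mapping[str, float] | None = None,
    ph_sd: float = DEFAULT_PH_SD,
) -> list[dict[str, object]]:
    """Semiquantitative urinalysis records: Bernoulli positivity per strip
    parameter at the group's rate, pH drawn around the group mean."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if n < 0:
        raise ValueError("n must be nonnegative")
    rates = rates or DEFAULT_STRIP_RATES
    ph_means = ph_means or DEFAULT_PH_MEANS
    rng = np.random.default_rng(seed)
    group_rates = rates[group]
    records = []
    for _ in range(n):
        rec: dict[str, object] = {
            param: int(rng.random() < p) for param, p in group_rates.items()
        }
        rec["pH"] = float(np.clip(rng.normal(ph_means[group], ph_sd), 4.5, 9.0))
        records.append(rec)
    return records
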