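"""Zone summaries, ratio markers, ternary peak codes, and feature tables.

Each profile is reduced either to 20 zone-level features (9 zone summaries,
9 peak codes, the Z4a/Z5 and Z6/Z7 ratios) or kept as the full 601-point
profile ("uTFMP" representation) for the classifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import SampleMetadata
from .preprocess import Utfmp, ZoneScheme, segment_zones

logger = logging.getLogger(__name__)

SummaryStat = Literal["max", "mean", "integral"]
PeakMode = Literal["zone_rise", "consecutive_step"]
Representation = Literal["zones", "utfmp"]

RATIO_COLUMNS = ("Z4a_over_Z5", "Z6_over_Z7")


@dataclass(frozen=True)
class PeakRule:
    """Ternary coding of within-zone spectral rise.

    Code 2 (peak) for a characteristic increase >= ``peak_threshold``
    fluorescence units, 1 (slight inclination) for an increase in
    [``flat_threshold``, ``peak_threshold``), 0 otherwise. The printed
    bands "5-10" and ">=15" leave [10, 15) unassigned; the inclination
    band is widened to [5, 15) so the coding is total.

    ``zone_rise`` measures the largest rise from any preceding point in the
    zone (a >=15-unit jump between points 0.5 nm apart on smoothed data is
    physically implausible); ``consecutive_step`` takes the literal maximum
    first difference.
    """

    peak_threshold: float = 15.0
    flat_threshold: float = 5.0
    mode: PeakMode = "zone_rise"

    def __post_init__(self) -> None:
        if not (0 < self.flat_threshold < self.peak_threshold):
            raise ValueError("need 0 < flat_threshold < peak_threshold")


def peak_code(slice_values: np.ndarray | Sequence[float], rule: PeakRule = PeakRule()) -> int:
    """Assign the ternary peak code to one zone's intensity slice."""
    values = np.asarray(slice_values, dtype=float)
    if values.size < 2:
        raise ValueError("zone slice must contain at least 2 points")
    if rule.mode == "consecutive_step":
        rise = float(np.max(np.diff(values)))
    elif rule.mode == "zone_rise":
        running_min = np.minimum.accumulate(values)[:-1]
        rise = float(np.max(values[1:] - running_min))
    else:
        raise ValueError(f"unknown peak mode {rule.mode!r}")
    if rise >= rule.peak_threshold:
        return 2
    if rise >= rule.flat_threshold:
        return 1
    return 0


def zone_summary(
    profile: Utfmp,
    scheme: ZoneScheme = ZoneScheme(),
    stat: SummaryStat = "max",
) -> dict[str, float]:
    """One summary value per zone: peak height (max), mean, or per-nm integral."""
    segments = segment_zones(profile, scheme)
    step = profile.grid.step_nm
    out: dict[str, float] = {}
    for name, values in segments.items():
        if stat == "max":
            out[name] = float(np.max(values))
        elif stat == "mean":
            out[name] = float(np.mean(values))
        elif stat == "integral":
            out[name] = float(np.trapezoid(values, dx=step))
        else:
            raise ValueError(f"unknown summary stat {stat!r}")
    return out


def ratio_markers(features: Mapping[str, float], epsilon: float = 1e-9) -> dict[str, float]:
    """The Z4a/Z5 and Z6/Z7 spectral-marker ratios from zone summaries."""
    for zone in ("Z4a", "Z5", "Z6", "Z7"):
        if zone not in features:
            raise KeyError(f"zone summary {zone} missing")
        if features[zone] < 0:
            raise ValueError(f"zone summary {zone} is negative")
    denominators = {"Z5": features["Z5"], "Z7": features["Z7"]}
    for zone, value in denominators.items():
        if value < epsilon:
            logger.warning("ratio denominator %s=%g below guard %g", zone, value, epsilon)
    return {
        "Z4a_over_Z5": features["Z4a"] / max(features["Z5"], epsilon),
        "Z6_over_Z7": features["Z6"] / max(features["Z7"], epsilon),
    }


def build_feature_table(
    profiles: Iterable[Utfmp],
    metadata: Iterable[SampleMetadata],
    representation: Representation = "zones",
    scheme: ZoneScheme = ZoneScheme(),
    stat: SummaryStat = "max",
    rule: PeakRule = PeakRule(),
) -> pd.DataFrame:
    """Per-sample feature matrix with a ``group`` column, sorted by sample id.

    ``zones``: 9 zone summaries + 9 peak codes + 2 ratios per sample.
    ``utfmp``: the full profile, one column per grid wavelength.
    """
    meta_by_id = {m.sample_id: m for m in metadata}
    rows = []
    for profile in sorted(profiles, key=lambda p: p.sample_id):
        meta = meta_by_id.get(profile.sample_id)
        if meta is None:
            raise KeyError(f"no metadata for sample {profile.sample_id!r}")
        if representation == "zones":
            summaries = zone_summary(profile, scheme, stat)
            codes = {
                f"peak_{name}": peak_code(values, rule)
                for name, values in segment_zones(profile, scheme).items()
            }
            row = {**summaries, **codes, **ratio_markers(summaries)}
        elif representation == "utfmp":
            row = {
                f"wl_{wl:g}": v
                for wl, v in zip(profile.grid.wavelengths, profile.intensities)
            }
        else:
            raise ValueError(f"unknown representation {representation!r}")
        row["group"] = meta.group
        rows.append(pd.Series(row, name=profile.sample_id))
    if not rows:
        raise ValueError("no profiles to tabulate")
    table = pd.DataFrame(rows)
    table.index.name = "sample_id"
    return table


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a feature table into (X, group labels)."""
    X = table.drop(columns="group").to_numpy(dtype=float)
    y = table["group"].to_numpy()
    return X, y
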