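"""One-command orchestration: cohort -> preprocessing -> features ->
statistics -> classifiers, with a reproducible report bundle.

Every stage's output is persisted as CSV under the output directory, and a
JSON manifest records the full configuration, seeds, package versions and
output file hashes, so a run can be reproduced bit-for-bit from the
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import defaultdict
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import PeakRule, Representation, build_feature_table
from .grid import GROUPS, STRIP_PARAMETERS, SampleMetadata, SynchronousSpectrum, WavelengthGrid
from .io import read_metadata, read_spectra, write_feature_table, write_metadata, write_spectra
from .models import CvSpec, SplitSpec, default_model_specs, fit_plsda, run_suite, suite_summary
from .preprocess import SmoothingConfig, ZoneScheme, build_utfmp
from .stats import marker_roc_table, test_group_differences
from .synth import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)

#: Repetition profiles: "desk" keeps a full run on one CPU in minutes,
#: "paper" is the faithful 100-repetition protocol.
PROFILES = {"desk": 10, "paper": 100}


@dataclass
class RunConfig:
    seed: int = 2024
    outdir: str = "results/run"
    spectra_path: str | None = None  # load these instead of simulating
    metadata_path: str | None = None
    cohort: CohortSpec | None = None  # simulation spec; defaults from seed
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    scheme: ZoneScheme = field(default_factory=ZoneScheme)
    rule: PeakRule = field(default_factory=PeakRule)
    representations: tuple[Representation, ...] = ("zones", "utfmp")
    profile: str = "desk"
    n_folds: int = 10
    n_plsda_components: int = 2
    stages: tuple[str, ...] = ("descriptive", "stats", "plsda", "classify")

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"profile must be one of {sorted(PROFILES)}")
        if not self.stages:
            raise ValueError("no stages enabled")


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (flat keys mirroring RunConfig)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    for key in ("seed", "outdir", "spectra_path", "metadata_path", "profile",
                "n_folds", "n_plsda_components"):
        if key in raw:
            kwargs[key] = raw[key]
    if "smoothing" in raw:
        kwargs["smoothing"] = SmoothingConfig(**raw["smoothing"])
    if "zones" in raw:
        kwargs["scheme"] = ZoneScheme(tuple((z["name"], z["start"], z["end"]) for z in raw["zones"]))
    if "peak_rule" in raw:
        kwargs["rule"] = PeakRule(**raw["peak_rule"])
    if "representations" in raw:
        kwargs["representations"] = tuple(raw["representations"])
    if "stages" in raw:
        kwargs["stages"] = tuple(raw["stages"])
    if "cohort" in raw:
        kwargs["cohort"] = CohortSpec(**raw["cohort"])
    return RunConfig(**kwargs)


def tabulate_strip(metadata: Iterable[SampleMetadata]) -> pd.DataFrame:
    """Per-group positive counts per strip parameter, plus mean pH."""
    records = [m for m in metadata if m.strip]
    if not records:
        logger.warning("no strip data present; returning empty table")
        return pd.DataFrame()
    rows = {}
    for param in STRIP_PARAMETERS:
        if param == "pH":
            continue
        if not any(param in m.strip for m in records):
            continue
        rows[param] = {
            g: int(sum(bool(m.strip.get(param, 0)) for m in records if m.group == g))
            for g in GROUPS
        }
    have_ph = [m for m in records if "pH" in m.strip]
    table = pd.DataFrame(rows).T
    if have_ph:
        table.loc["mean_pH"] = {
            g: float(np.mean([m.strip["pH"] for m in have_ph if m.group == g] or [np.nan]))
            for g in GROUPS
        }
    else:
        logger.warning("pH missing from strip data; pH row omitted")
    table.index.name = "parameter"
    return table


def profiles_from_spectra(
    spectra: Sequence[SynchronousSpectrum],
    smoothing: SmoothingConfig,
    construction: str = "max_over_dilutions",
):
    """Group spectra by sample id and build one uTFMP per sample."""
    by_sample: dict[str, list[SynchronousSpectrum]] = defaultdict(list)
    for s in spectra:
        by_sample[s.sample_id].append(s)
    return [
        build_utfmp(series, smoothing, construction=construction)
        for series in by_sample.values()
    ]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class ReportBundle:
    outdir: Path
    group_counts: dict[str, int]
    strip_table: pd.DataFrame
    zone_tests: pd.DataFrame
    roc_summary: pd.DataFrame
    plsda_summary: pd.DataFrame
    classifier_summary: pd.DataFrame
    confusions: pd.DataFrame
    manifest: dict


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every enabled stage and write the report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.spectra_path and config.metadata_path:
        spectra = read_spectra(config.spectra_path)
        metadata = read_metadata(config.metadata_path)
        source = {"spectra": str(config.spectra_path), "metadata": str(config.metadata_path)}
    else:
        cohort = config.cohort or CohortSpec(seed=config.seed)
        spectra, metadata = generate_cohort(cohort)
        write_spectra(spectra, outdir / "spectra.csv")
        write_metadata(metadata, outdir / "metadata.csv")
        source = {"simulated": True, "cohort_seed": cohort.seed,
                  "counts": cohort.counts}

    group_counts = {g: sum(1 for m in metadata if m.group == g) for g in GROUPS}
    logger.info("cohort: %s", group_counts)

    strip_table = pd.DataFrame()
    if "descriptive" in config.stages:
        strip_table = tabulate_strip(metadata)
        if not strip_table.empty:
            strip_table.to_csv(outdir / "strip_counts.csv")

    profiles = profiles_from_spectra(spectra, config.smoothing)
    tables = {
        rep: build_feature_table(
            profiles, metadata, representation=rep,
            scheme=config.scheme, rule=config.rule,
        )
        for rep in config.representations
    }
    for rep, table in tables.items():
        write_feature_table(table, outdir / f"features_{rep}.csv")

    zone_tests = pd.DataFrame()
    roc_summary = pd.DataFrame()
    if "stats" in config.stages and "zones" in tables:
        ztab = tables["zones"]
        test_rows = []
        for variable in [*config.scheme.names, "Z4a_over_Z5", "Z6_over_Z7"]:
            res = test_group_differences(ztab, variable)
            row = {
                "variable": variable,
                "test": res.global_test,
                "p_global": res.global_p,
            }
            for comp in res.pairwise:
                row[f"p_{comp.pair[0]}_vs_{comp.pair[1]}"] = comp.p_adjusted
            for g in GROUPS:
                row[f"median_{g}"] = res.medians.get(g, np.nan)
                row[f"iqr_{g}"] = res.iqrs.get(g, np.nan)
            test_rows.append(row)
        zone_tests = pd.DataFrame(test_rows)
        zone_tests.to_csv(outdir / "zone_tests.csv", index=False)
        roc_summary = pd.concat(
            [marker_roc_table(ztab, g) for g in ("benign", "malignant") if group_counts[g] > 0],
            ignore_index=True,
        )
        roc_summary.to_csv(outdir / "marker_roc.csv", index=False)

    plsda_rows = []
    if "plsda" in config.stages and "zones" in tables:
        ztab = tables["zones"]
        for positive in ("malignant", "benign"):
            if group_counts[positive] < 7:  # too few for a stratified 70:30 + CV
                continue
            sub = ztab[ztab["group"].isin(["control", positive])]
            train, test = stratified_split_table(sub, config.seed)
            res = fit_plsda(
                train, test, n_components=config.n_plsda_components,
                positive_group=positive, seed=config.seed,
            )
            plsda_rows.append(
                {
                    "comparison": f"control_vs_{positive}",
                    "r2": res.r2,
                    "q2": res.q2,
                    "accuracy": res.accuracy,
                    "auc": res.auc,
                    **{f"{cls}_{k}": v for cls, d in res.report.items() for k, v in d.items()},
                }
            )
    plsda_summary = pd.DataFrame(plsda_rows)
    if not plsda_summary.empty:
        plsda_summary.to_csv(outdir / "plsda.csv", index=False)

    classifier_summary = pd.DataFrame()
    confusions = pd.DataFrame()
    if "classify" in config.stages:
        cv = CvSpec(n_folds=config.n_folds, n_repetitions=PROFILES[config.profile], seed=config.seed)
        split = SplitSpec(seed=config.seed)
        all_reports = []
        for rep, table in tables.items():
            all_reports.extend(run_suite(table, default_model_specs(), cv, split, representation=rep))
        classifier_summary = suite_summary(all_reports)
        classifier_summary.to_csv(outdir / "classifier_metrics.csv", index=False)
        confusions = pd.DataFrame(
            [
                {
                    "model": r.model,
                    "representation": r.representation,
                    "partition": part,
                    **conf,
                }
                for r in all_reports
                for part, conf in (("cv_pooled", r.cv_pooled_confusion), ("test", r.test_confusion))
            ]
        )
        confusions.to_csv(outdir / "confusion_matrices.csv", index=False)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "profile": config.profile,
        "n_repetitions": PROFILES[config.profile],
        "source": source,
        "config": {
            "smoothing": asdict(config.smoothing),
            "zones": list(config.scheme.zones),
            "peak_rule": {"peak_threshold": config.rule.peak_threshold,
                          "flat_threshold": config.rule.flat_threshold,
                          "mode": config.rule.mode},
            "representations": list(config.representations),
            "n_folds": config.n_folds,
            "n_plsda_components": config.n_plsda_components,
            "stages": list(config.stages),
        },
        "versions": _library_versions(),
        "outputs": {
            p.name: _sha256(p) for p in sorted(outdir.glob("*.csv"))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ReportBundle(
        outdir=outdir,
        group_counts=group_counts,
        strip_table=strip_table,
        zone_tests=zone_tests,
        roc_summary=roc_summary,
        plsda_summary=plsda_summary,
        classifier_summary=classifier_summary,
        confusions=confusions,
        manifest=manifest,
    )


def stratified_split_table(table: pd.DataFrame, seed: int):
    from .models import SplitSpec, stratified_split

    return stratified_split(table, SplitSpec(seed=seed))


def _library_versions() -> dict[str, str]:
    import sklearn
    import scipy

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }
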