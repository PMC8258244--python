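"""Config-driven orchestration of the full analysis grid.

``run_analysis`` walks exposures x outcomes x instrument sets x methods,
writing one TSV per report table plus leave-one-out, clustering,
meta-analysis and a JSON run-manifest.  Failures are isolated per grid
cell: one outcome with too few instruments must not abort the rest of the
grid.  Reruns with identical config and seeds are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import math
import pandas as pd
import yaml

from . import io as sio
from .clustering import assignment_table, fit_clusters
from .estimators import (MrResult, egger, f_statistic, ivw, leave_one_out,
                         max_likelihood, mvmr, significance_label,
                         wald_ratios, weighted_median)
from .exceptions import ConfigError, SummrError
from .harmonize import apply_exclusions, build_set
from .meta import MetaInput, meta_fixed

log = logging.getLogger(__name__)

PRIMARY_METHODS = ("ivw", "egger")
ALL_METHODS = ("ivw", "ml", "median", "egger")

#: instrument-set labels
SET_FULL = "full"
SET_NO_PALINDROMIC = "no_palindromic"
SET_CURATED = "curated"


@dataclass
class StudyConfig:
    label: str
    path: str
    column_map: dict | None = None
    instruments: str | None = None
    primary_only: bool = False


@dataclass
class AnalysisConfig:
    exposures: list[StudyConfig]
    outcomes: list[StudyConfig]
    covariates: list[StudyConfig] = field(default_factory=list)
    exclusions: str | None = None
    methods: tuple[str, ...] = ALL_METHODS
    palindromic_mode: str = "frequency-align"
    ambiguity_threshold: float = 0.42
    n_boot: int = 1000
    seed: int = 0
    kmax: int = 5
    clust_threshold: float = 0.8
    clust_min_size: int = 4
    suggestive: float = 0.05
    significant: float = 0.01
    meta_groups: dict[str, list[str]] = field(default_factory=dict)
    run_clustering: bool = True
    run_loo: bool = True

    def __post_init__(self) -> None:
        if not self.exposures or not self.outcomes:
            raise ConfigError("config needs at least one exposure and one outcome")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ConfigError(f"unknown methods: {sorted(unknown)}")
        if not (self.significant <= self.suggestive):
            raise ConfigError("significance thresholds out of order")
        for study in self.exposures + self.outcomes + self.covariates:
            if not Path(study.path).exists():
                raise ConfigError(f"study file not found: {study.path}")
            if study.instruments and not Path(study.instruments).exists():
                raise ConfigError(f"instrument file not found: {study.instruments}")
        if self.exclusions and not Path(self.exclusions).exists():
            raise ConfigError(f"exclusion file not found: {self.exclusions}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent

        def study(d):
            d = dict(d)
            d["path"] = str((base / d["path"]))
            if d.get("instruments"):
                d["instruments"] = str(base / d["instruments"])
            return StudyConfig(**d)

        kwargs = dict(raw)
        kwargs["exposures"] = [study(d) for d in raw.get("exposures", [])]
        kwargs["outcomes"] = [study(d) for d in raw.get("outcomes", [])]
        kwargs["covariates"] = [study(d) for d in raw.get("covariates", [])]
        if raw.get("exclusions"):
            kwargs["exclusions"] = str(base / raw["exclusions"])
        if "methods" in raw:
            kwargs["methods"] = tuple(raw["methods"])
        return cls(**kwargs)


def _run_method(name: str, hset, config: AnalysisConfig) -> MrResult:
    if name == "ivw":
        return ivw(hset)
    if name == "ml":
        return max_likelihood(hset)
    if name == "median":
        return weighted_median(hset, n_boot=config.n_boot, seed=config.seed)
    if name == "egger":
        return egger(hset)
    raise ConfigError(f"unknown method {name!r}")


def _result_row(exposure, outcome, set_label, res: MrResult) -> dict:
    return {
        "exposure": exposure, "outcome": outcome, "instrument_set": set_label,
        "method": res.method, "n_snp": res.n_snp, "or": res.odds_ratio,
        "ci_low": res.or_ci[0], "ci_high": res.or_ci[1],
        "pvalue": res.pvalue, "intercept_pvalue": res.intercept_pvalue,
    }


def run_analysis(config: AnalysisConfig, out_dir: str | Path) -> Path:
    """Execute the whole grid, writing result TSVs + manifest to out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failures: list[dict] = []
    manifest: dict = {"seed": config.seed, "inputs": {}, "reads": {},
                      "matches": {}}

    def record_failure(**cell):
        failures.append(cell)
        log.warning("grid cell failed: %s", cell)

    def read_study(study: StudyConfig):
        records = sio.read_gwas(study.path, study.column_map)
        manifest["inputs"][study.label] = sio.file_sha256(study.path)
        manifest["reads"][study.label] = {
            "n_records": len(records), "n_dropped": records.n_dropped,
            "n_duplicates": records.n_duplicates}
        return records

    exclusions = sio.read_exclusions(config.exclusions) if config.exclusions else None
    covariate_records = {c.label: read_study(c) for c in config.covariates}

    main_rows, curated_rows, mvmr_rows, primary_rows, meta_rows = [], [], [], [], []
    loo_frames, cluster_frames, scatter_frames, strength_rows = [], [], [], []
    ivw_by_cell: dict[tuple[str, str, str], MrResult] = {}

    for exposure in config.exposures:
        exp_records = read_study(exposure)
        ivs = (sio.read_instruments(exposure.instruments)
               if exposure.instruments else None)
        methods = PRIMARY_METHODS if exposure.primary_only else config.methods
        for outcome in config.outcomes:
            out_records = read_study(outcome)
            try:
                full = build_set(exp_records, out_records, ivs,
                                 mode=config.palindromic_mode,
                                 ambiguity_threshold=config.ambiguity_threshold)
            except SummrError as exc:
                record_failure(exposure=exposure.label, outcome=outcome.label,
                               stage="harmonize", error=str(exc))
                continue
            if ivs is not None:
                manifest["matches"][f"{exposure.label}:{outcome.label}"] = \
                    f"{full.n_total}/{len(ivs)}"
            sets = {SET_FULL: full}
            try:
                sets[SET_NO_PALINDROMIC] = build_set(
                    exp_records, out_records, ivs, mode="drop-palindromic")
            except SummrError as exc:
                record_failure(exposure=exposure.label, outcome=outcome.label,
                               stage="palindromic-set", error=str(exc))
            if exclusions is not None:
                sets[SET_CURATED] = apply_exclusions(full, exclusions)

            _, overall_f = f_statistic(full)
            strength_rows.append({"exposure": exposure.label,
                                  "outcome": outcome.label,
                                  "n_snp": full.n_active,
                                  "overall_f": overall_f})

            for set_label, hset in sets.items():
                if exposure.primary_only:
                    rows = primary_rows
                elif set_label == SET_CURATED:
                    rows = curated_rows
                else:
                    rows = main_rows
                for name in methods:
                    try:
                        res = _run_method(name, hset, config)
                    except SummrError as exc:
                        record_failure(exposure=exposure.label,
                                       outcome=outcome.label,
                                       set=set_label, method=name,
                                       error=str(exc))
                        continue
                    rows.append(_result_row(exposure.label, outcome.label,
                                            set_label, res))
                    if name == "ivw":
                        ivw_by_cell[(exposure.label, outcome.label,
                                     set_label)] = res

            if not exposure.primary_only:
                if config.run_loo and full.n_active >= 3:
                    try:
                        loo = leave_one_out(full)
                        loo.insert(0, "outcome", outcome.label)
                        loo.insert(0, "exposure", exposure.label)
                        loo_frames.append(loo)
                    except SummrError as exc:
                        record_failure(exposure=exposure.label,
                                       outcome=outcome.label,
                                       stage="leave-one-out", error=str(exc))
                for cov in config.covariates:
                    try:
                        cov_effects = _covariate_frame(
                            covariate_records[cov.label], cov.label)
                        res = mvmr(full, cov_effects)
                        mvmr_rows.append({
                            "exposure": exposure.label,
                            "outcome": outcome.label, "covariate": cov.label,
                            "n_snp": res.n_snp,
                            "or": math.exp(res.theta[0]),
                            "ci_low": math.exp(res.theta[0] - 1.959964 * res.se[0]),
                            "ci_high": math.exp(res.theta[0] + 1.959964 * res.se[0]),
                            "pvalue": res.pvalue[0]})
                    except SummrError as exc:
                        record_failure(exposure=exposure.label,
                                       outcome=outcome.label,
                                       stage=f"mvmr:{cov.label}",
                                       error=str(exc))
                if config.run_clustering:
                    try:
                        ratios = wald_ratios(full)
                        solution = fit_clusters(
                            ratios, K_max=config.kmax,
                            threshold=config.clust_threshold,
                            min_size=config.clust_min_size, seed=config.seed)
                        table = assignment_table(solution)
                        table.insert(0, "outcome", outcome.label)
                        table.insert(0, "exposure", exposure.label)
                        cluster_frames.append(table)
                        scatter = full.active[["rsid", "gamma", "Gamma"]].copy()
                        scatter = scatter.merge(
                            solution.assignments[["rsid", "cluster"]], on="rsid")
                        scatter.insert(0, "outcome", outcome.label)
                        scatter.insert(0, "exposure", exposure.label)
                        scatter_frames.append(scatter)
                    except SummrError as exc:
                        record_failure(exposure=exposure.label,
                                       outcome=outcome.label,
                                       stage="clustering", error=str(exc))

    # cross-disease meta per configured group, per instrument set
    for group, members in config.meta_groups.items():
        for exposure in config.exposures:
            for set_label in (SET_FULL, SET_CURATED):
                inputs = []
                for m in members:
                    res = ivw_by_cell.get((exposure.label, m, set_label))
                    if res is not None:
                        inputs.append(MetaInput(m, res.theta, res.se))
                if len(inputs) >= 2:
                    res = meta_fixed(inputs)
                    row = _result_row(exposure.label, group, set_label, res)
                    row["n_studies"] = len(inputs)
                    meta_rows.append(row)

    def write(rows_or_frames, name, concat=False):
        if concat:
            if not rows_or_frames:
                return
            frame = pd.concat(rows_or_frames, ignore_index=True)
        else:
            if not rows_or_frames:
                return
            frame = pd.DataFrame(rows_or_frames)
        frame.to_csv(out / name, sep="\t", index=False, float_format="%.6g")

    write(main_rows, "estimates_main.tsv")            # Table-1-style
    write(curated_rows, "estimates_curated.tsv")      # Table-2-style
    write(mvmr_rows, "estimates_mvmr.tsv")            # Table-3-style
    write(primary_rows, "estimates_primary.tsv")      # Table-4-style
    write(meta_rows, "meta.tsv")
    write(strength_rows, "instrument_strength.tsv")
    write(loo_frames, "leave_one_out.tsv", concat=True)
    write(cluster_frames, "clusters.tsv", concat=True)
    write(scatter_frames, "cluster_scatter.tsv", concat=True)
    if failures:
        write(failures, "failures.tsv")
        log.warning("run finished with %d failed grid cells", len(failures))
    manifest["n_failures"] = len(failures)
    manifest["thresholds"] = {"suggestive": config.suggestive,
                              "significant": config.significant}
    sio.write_manifest(out / "manifest.json", manifest)
    return out


def _covariate_frame(records, label: str) -> pd.DataFrame:
    return pd.DataFrame({label: {r.rsid: r.beta for r in records}})


def render_report(run_dir: str | Path, suggestive: float = 0.05,
                  significant: float = 0.01) -> Path:
    """Render the run directory as a markdown report with significance
    stars (** below the corrected threshold, * below the suggestive one).

    An incomplete run produces a partial report with warnings rather than
    an error.
    """
    run_dir = Path(run_dir)
    lines = ["# Summary-data MR report", ""]
    warnings = []

    def table_section(name, title):
        path = run_dir / name
        if not path.exists():
            warnings.append(f"missing {name}")
            return
        frame = pd.read_csv(path, sep="\t")
        lines.append(f"## {title}")
        lines.append("")
        if "pvalue" in frame.columns:
            frame["significance"] = frame["pvalue"].map(
                lambda p: significance_label(p, suggestive, significant))
        lines.append("```")
        lines.append(frame.to_string(index=False))
        lines.append("```")
        lines.append("")

    table_section("estimates_main.tsv", "Main estimates (per instrument set)")
    table_section("estimates_curated.tsv", "Confounder-curated estimates")
    table_section("estimates_mvmr.tsv", "Multivariable MR")
    table_section("estimates_primary.tsv", "Primary-only exposures")
    table_section("meta.tsv", "Cross-disease meta-analysis")
    table_section("instrument_strength.tsv", "Instrument strength")

    clusters = run_dir / "clusters.tsv"
    if clusters.exists():
        frame = pd.read_csv(clusters, sep="\t")
        counts = (frame[~frame["cluster"].isin(["null", "junk", "unassigned"])]
                  .groupby(["exposure", "outcome", "cluster"]).size())
        lines.append("## Causal-effect clusters")
        lines.append("")
        if len(counts):
            lines.append("```")
            lines.append(counts.rename("n_variants").reset_index()
                         .to_string(index=False))
            lines.append("```")
        else:
            lines.append("No substantive clusters assigned.")
        lines.append("")
    else:
        warnings.append("missing clusters.tsv")

    if warnings:
        lines.insert(2, "**Warnings:** " + "; ".join(warnings))
        lines.insert(3, "")
    report = run_dir / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
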