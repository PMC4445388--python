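"""End-to-end orchestration of the analysis with reproducible configuration.

``reproduce`` runs the full sequence — factor-structure determination, the
Model A/B/C fits with fit indices, the nested comparisons, and the robustness
variants — on either the packaged summary fixture or a raw cohort file, and
returns a machine-readable :class:`AnalysisReport`.  ``render_report`` writes
the report as JSON plus TSV tables and a plain-text summary.  Every stochastic
stage draws its sub-seed deterministically from the master seed, so two runs
with the same configuration produce byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from edusem import summary_data
from edusem.factor_structure import correlation_eigenvalues, efa, parallel_analysis
from edusem.sem_engine import compare, fit_fiml, fit_indices, fit_ml
from edusem.sem_engine.fit import FitResult
from edusem.study_models import (
    backward_eliminate,
    build,
    build_residualized_suite,
    is_nested,
    residualize_cohort,
    without_residual_covariances,
)
from edusem.synthetic_cohort import (
    CohortMatrix,
    GeneratorConfig,
    generate_cohort,
    impose_missingness,
    read_cohort,
    table1_missingness,
)

__all__ = ["RunConfig", "AnalysisReport", "reproduce", "render_report"]

REPORT_SCHEMA_VERSION = "1"

FIT_TABLE_COLUMNS = ("model", "df", "chi_square", "aic", "rmsea", "cfi", "tli")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run."""

    source: str = "fixture"            # "fixture" or a cohort TSV path
    n_policy: str = "total"
    alpha: float = 0.05
    parallel_iterations: int = 1000
    parallel_percentile: float = 95.0
    efa_factors: tuple[int, ...] = (2, 3, 4)
    models: tuple[str, ...] = ("model_a", "model_b", "model_c")
    variants: tuple[str, ...] = ("no_residuals", "reinstated", "residualized")
    run_elimination: bool = True
    master_seed: int = 0
    comparison_tolerance: float = 1e-6

    def validate(self) -> None:
        if not self.models:
            raise ValueError("config lists no models to fit")
        unknown = set(self.models) - {"model_a", "model_b", "model_c", "model_c_full"}
        if unknown:
            raise ValueError(f"unknown models in config: {sorted(unknown)}")
        unknown_v = set(self.variants) - {"no_residuals", "reinstated", "residualized"}
        if unknown_v:
            raise ValueError(f"unknown variants in config: {sorted(unknown_v)}")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")


def _subseed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0] % (2**31))


@dataclass
class AnalysisReport:
    """Everything one run produced, traceable stage by stage."""

    schema_version: str
    provenance: dict
    factor_structure: dict = field(default_factory=dict)
    fit_table: list[dict] = field(default_factory=list)
    estimates: dict[str, list[dict]] = field(default_factory=dict)
    comparisons: list[dict] = field(default_factory=list)
    elimination: dict = field(default_factory=dict)
    robustness: dict = field(default_factory=dict)
    errors: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=False, default=float)


def _fit_row(fit: FitResult) -> dict:
    ix = fit_indices(fit)
    row = {"model": fit.model, "df": fit.df, "chi_square": round(fit.chi_square, 6),
           "aic": round(fit.aic, 6)}
    row.update({k: (None if np.isnan(v) else round(v, 6)) for k, v in ix.as_dict().items() if k != "aic"})
    return {c: row[c] for c in FIT_TABLE_COLUMNS}


def _estimate_rows(fit: FitResult) -> list[dict]:
    rows = []
    for label in fit.ram.free_labels:
        rows.append(
            {
                "label": label,
                "estimate": round(fit.estimates[label], 8),
                "se": None if np.isnan(fit.se[label]) else round(fit.se[label], 8),
                "std": round(fit.std_estimates[label], 8) if label in fit.std_estimates else None,
            }
        )
    return rows


def _comparison_row(res) -> dict:
    return {
        "restricted": res.restricted,
        "full": res.full,
        "delta_chi_square": round(res.delta_chi_square, 6),
        "delta_df": res.delta_df,
        "p_value": float(f"{res.p_value:.6g}"),
        "delta_aic": round(res.delta_aic, 6),
    }


def _aic_ranking(fits: dict[str, FitResult]) -> list[str]:
    return sorted(fits, key=lambda m: fits[m].aic)


def reproduce(config: RunConfig) -> AnalysisReport:
    """Run the full analysis described by `config`.

    Stage failures are recorded in ``report.errors`` (the report is still
    returned); the CLI maps a non-empty error list to a nonzero exit status.
    """
    config.validate()
    sm = summary_data.load_table1_fixture()
    report = AnalysisReport(
        schema_version=REPORT_SCHEMA_VERSION,
        provenance={
            "config": asdict(config),
            "package_version": __import__("edusem").__version__,
            "subseeds": {"parallel": _subseed(config.master_seed, 1),
                         "cohort": _subseed(config.master_seed, 2),
                         "fits": _subseed(config.master_seed, 3)},
        },
    )
    seed_fits = report.provenance["subseeds"]["fits"]

    cohort: CohortMatrix | None = None
    if config.source == "fixture":
        moments = summary_data.to_covariance(sm, n_policy=config.n_policy)
        method = "ml"
    else:
        cohort = read_cohort(config.source, sm.variables)
        method = "fiml"

    def fit_any(spec):
        if method == "ml":
            return fit_ml(moments, spec, seed=seed_fits)
        return fit_fiml(cohort, spec, seed=seed_fits)

    # --- factor structure -------------------------------------------------
    try:
        if cohort is None:
            subtest_corr = sm.subtest_corr()
            n_fs = sm.n_total
        else:
            sub = cohort.data[list(sm.variables.subtests)].dropna()
            subtest_corr = np.corrcoef(sub.to_numpy(), rowvar=False)
            n_fs = len(sub)
        spectrum = correlation_eigenvalues(subtest_corr)
        pa = parallel_analysis(
            spectrum,
            n=n_fs,
            iterations=config.parallel_iterations,
            percentile=config.parallel_percentile,
            seed=report.provenance["subseeds"]["parallel"],
        )
        efa_block = {}
        for k in config.efa_factors:
            sol = efa(subtest_corr, n_fs, k, sm.variables.subtests)
            efa_block[str(k)] = {
                "members": [sorted(m) for m in sol.factor_members()],
                "pattern": np.round(sol.pattern, 6).tolist(),
                "phi": np.round(sol.phi, 6).tolist(),
                "heywood": sol.heywood,
            }
        report.factor_structure = {
            "eigenvalues": np.round(spectrum.eigenvalues, 6).tolist(),
            "parallel_analysis": {k: (np.round(v, 6).tolist() if isinstance(v, list) else v)
                                  for k, v in pa.to_dict().items()},
            "efa": efa_block,
        }
    except Exception as err:  # noqa: BLE001 — stage-level error record
        report.errors.append({"stage": "factor_structure", "error": str(err)})

    # --- model fits and comparisons --------------------------------------
    fits: dict[str, FitResult] = {}
    try:
        for name in config.models:
            fits[name] = fit_any(build(name))
            report.fit_table.append(_fit_row(fits[name]))
            report.estimates[name] = _estimate_rows(fits[name])
        pairs = [("model_a", "model_b"), ("model_a", "model_c"), ("model_b", "model_c")]
        for restricted, full in pairs:
            if restricted in fits and full in fits:
                report.comparisons.append(
                    _comparison_row(compare(fits[restricted], fits[full], tol=config.comparison_tolerance))
                )
        report.robustness["main_aic_ranking"] = _aic_ranking(fits)
    except Exception as err:  # noqa: BLE001
        report.errors.append({"stage": "model_fits", "error": str(err)})

    # --- backward elimination ---------------------------------------------
    if config.run_elimination:
        try:
            _, trace, _ = backward_eliminate(
                moments if cohort is None else cohort,
                alpha=config.alpha,
                method=method,
                seed=seed_fits,
            )
            report.elimination = {
                "alpha": trace.alpha,
                "dropped": list(trace.dropped),
                "surviving": list(trace.surviving),
                "steps": trace.steps,
                "converged": trace.converged,
            }
        except Exception as err:  # noqa: BLE001
            report.errors.append({"stage": "elimination", "error": str(err)})

    # --- robustness variants ----------------------------------------------
    if "no_residuals" in config.variants:
        try:
            nr = {n: fit_any(without_residual_covariances(build(n))) for n in config.models}
            report.robustness["no_residuals"] = {
                "fit_table": [_fit_row(f) for f in nr.values()],
                "aic_ranking": [m for m in _aic_ranking(nr)],
            }
        except Exception as err:  # noqa: BLE001
            report.errors.append({"stage": "no_residuals", "error": str(err)})
    if "reinstated" in config.variants:
        try:
            re_fits = {n: fits.get(n) or fit_any(build(n)) for n in ("model_a", "model_b")}
            re_fits["model_c_full"] = fit_any(build("model_c_full"))
            report.robustness["reinstated"] = {
                "fit_table": [_fit_row(f) for f in re_fits.values()],
                "aic_ranking": _aic_ranking(re_fits),
            }
        except Exception as err:  # noqa: BLE001
            report.errors.append({"stage": "reinstated", "error": str(err)})
    if "residualized" in config.variants:
        try:
            if cohort is None:
                base = generate_cohort(
                    sm, GeneratorConfig(n=sm.n_total, seed=report.provenance["subseeds"]["cohort"])
                )
                base = impose_missingness(base, table1_missingness(sm),
                                          seed=report.provenance["subseeds"]["cohort"])
            else:
                base = cohort
            resid = residualize_cohort(base)
            rfits = {n: fit_fiml(resid, spec, seed=seed_fits)
                     for n, spec in build_residualized_suite().items()}
            report.robustness["residualized"] = {
                "fit_table": [_fit_row(f) for f in rfits.values()],
                "aic_ranking": _aic_ranking(rfits),
            }
        except Exception as err:  # noqa: BLE001
            report.errors.append({"stage": "residualized", "error": str(err)})

    # structural sanity: every comparison we report is on nested specs
    try:
        for restricted, full in (("model_a", "model_b"),):
            if restricted in config.models and full in config.models:
                assert is_nested(build(restricted), build(full))
    except AssertionError:
        report.errors.append({"stage": "nesting_check", "error": "catalogue nesting violated"})

    return report


def render_report(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    """Write JSON, TSV tables and a plain-text summary; idempotent."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    p = out / "report.json"
    p.write_text(report.to_json() + "\n")
    written.append(p)

    if report.fit_table:
        p = out / "fit_table.tsv"
        pd.DataFrame(report.fit_table, columns=FIT_TABLE_COLUMNS).to_csv(p, sep="\t", index=False)
        written.append(p)
    if report.comparisons:
        p = out / "comparisons.tsv"
        pd.DataFrame(report.comparisons).to_csv(p, sep="\t", index=False)
        written.append(p)
    for model, rows in report.estimates.items():
        p = out / f"estimates_{model}.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        written.append(p)

    lines = [f"analysis report (schema {report.schema_version})", ""]
    if report.factor_structure:
        pa = report.factor_structure.get("parallel_analysis", {})
        lines.append(
            f"parallel analysis: retained {pa.get('retained')} factor(s) "
            f"({pa.get('iterations')} iterations, {pa.get('percentile')}th percentile)"
        )
        ev = report.factor_structure.get("eigenvalues", [])
        if ev:
            lines.append(f"first eigenvalue of the subtest matrix: {ev[0]:.3f}")
    for row in report.fit_table:
        lines.append(
            f"{row['model']}: chi2({row['df']}) = {row['chi_square']:.2f}, AIC = {row['aic']:.2f}, "
            f"RMSEA = {row['rmsea']:.3f}, CFI = {row['cfi']:.3f}, TLI = {row['tli']:.3f}"
        )
    for cmp_row in report.comparisons:
        lines.append(
            f"{cmp_row['full']} vs {cmp_row['restricted']}: "
            f"d-chi2({cmp_row['delta_df']}) = {cmp_row['delta_chi_square']:.2f}, "
            f"p = {cmp_row['p_value']:.4g}, d-AIC = {cmp_row['delta_aic']:.2f}"
        )
    ranking = report.robustness.get("main_aic_ranking")
    if ranking:
        lines.append("AIC ranking (best first): " + " < ".join(ranking))
    if report.errors:
        lines.append("ERRORS:")
        lines += [f"  {e['stage']}: {e['error']}" for e in report.errors]
    p = out / "summary.txt"
    p.write_text("\n".join(lines) + "\n")
    written.append(p)
    return written
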