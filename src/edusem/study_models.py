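"""The study's model catalogue and model-search procedures.

Three theoretical structures link years of education to cognition at age ~70,
always controlling for age-11 intelligence (which predicts both education and
later-life g):

* Model A — education relates to the subtests only through the general factor
  g (education -> g, no direct education -> subtest paths);
* Model B — education -> g plus direct paths to Logical Memory and
  Digit-Symbol Substitution;
* Model C — no education -> g path; direct education paths to seven subtests
  (all but Spatial Span, Digit Span Backwards and Letter-Number Sequencing),
  arrived at by backward elimination from a model with paths to all ten.

All models share one g factor over the ten subtests (variance fixed at 1) and
five residual covariances identified in the measurement model: Matrix
Reasoning~~Block Design, Logical Memory~~Verbal Paired Associates,
Digit-Symbol~~Symbol Search, Digit Span Backwards~~Letter-Number Sequencing,
and the (negative) age-70 MHT~~Spatial Span.

The module also builds the alternative factor structures considered when
choosing the measurement model (correlated 2/3/4-factor, hierarchical,
bifactor) and the robustness variants (residual covariances removed, dropped
paths reinstated, subtests residualised on age-11 IQ).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from edusem.sem_engine import Covariance, ModelSpec, Path, compile_ram
from edusem.sem_engine.fit import FitResult, drop_test, fit_fiml, fit_ml
from edusem.summary_data import STUDY_VARIABLES
from edusem.synthetic_cohort import CohortMatrix

__all__ = [
    "RESIDUAL_COVARIANCE_PAIRS",
    "MODEL_C_DIRECT_TARGETS",
    "FACTOR_MEMBERSHIPS",
    "catalog_names",
    "build",
    "build_alt_factor",
    "without_residual_covariances",
    "backward_eliminate",
    "EliminationTrace",
    "residualize_cohort",
    "build_residualized_suite",
    "is_nested",
]

SUBTESTS = STUDY_VARIABLES.subtests
EARLY_IQ = STUDY_VARIABLES.early_iq
EDUCATION = STUDY_VARIABLES.education

RESIDUAL_COVARIANCE_PAIRS: tuple[tuple[str, str], ...] = (
    ("matrix_reasoning", "block_design"),
    ("logical_memory", "verbal_paired_assoc"),
    ("digit_symbol", "symbol_search"),
    ("digit_span_backwards", "letter_number_seq"),
    ("age70_mht", "spatial_span"),
)

# the seven subtests keeping a direct education path in Model C
MODEL_C_DIRECT_TARGETS: tuple[str, ...] = tuple(
    s for s in SUBTESTS if s not in ("spatial_span", "digit_span_backwards", "letter_number_seq")
)

# EFA-derived factor compositions used by the alternative measurement models
FACTOR_MEMBERSHIPS: dict[int, dict[str, tuple[str, ...]]] = {
    2: {
        "timed": ("symbol_search", "block_design", "digit_symbol", "spatial_span"),
        "nontimed": ("logical_memory", "matrix_reasoning", "verbal_paired_assoc",
                     "letter_number_seq", "digit_span_backwards", "age70_mht"),
    },
    3: {
        "speed": ("symbol_search", "digit_symbol"),
        "verbal_memory": ("logical_memory", "verbal_paired_assoc"),
        "fluid": ("matrix_reasoning", "block_design", "letter_number_seq",
                  "digit_span_backwards", "spatial_span", "age70_mht"),
    },
    4: {
        "speed": ("symbol_search", "digit_symbol"),
        "verbal_memory": ("logical_memory", "verbal_paired_assoc"),
        "reasoning": ("matrix_reasoning", "block_design", "age70_mht"),
        "working_memory": ("letter_number_seq", "digit_span_backwards", "spatial_span"),
    },
}


def _g_measurement(observed_subtests: tuple[str, ...], residuals: bool) -> tuple[tuple[Path, ...], tuple[Covariance, ...]]:
    loadings = tuple(Path("g", s) for s in observed_subtests)
    covs = [Covariance("g", "g", free=False, value=1.0)]
    if residuals:
        covs += [Covariance(a, b) for a, b in RESIDUAL_COVARIANCE_PAIRS]
    return loadings, tuple(covs)


def _structural(edu_to_g: bool, edu_targets: tuple[str, ...]) -> tuple[Path, ...]:
    paths = [Path(EARLY_IQ, EDUCATION), Path(EARLY_IQ, "g")]
    if edu_to_g:
        paths.append(Path(EDUCATION, "g"))
    paths += [Path(EDUCATION, s) for s in edu_targets]
    return tuple(paths)


def catalog_names() -> tuple[str, ...]:
    return ("one_factor", "baseline_g", "model_a", "model_b", "model_c", "model_c_full")


def build(name: str, residuals: bool = True) -> ModelSpec:
    """Build a catalogue model by name.

    ``one_factor`` and ``baseline_g`` are measurement-only CFAs of the ten
    subtests (without / with the five residual covariances); the others add
    the age-11 IQ and education structural paths.  ``residuals=False`` removes
    the five residual covariances (robustness variant).
    """
    if name not in catalog_names():
        raise KeyError(f"unknown model {name!r}; catalogue: {catalog_names()}")
    if name in ("one_factor", "baseline_g"):
        loadings, covs = _g_measurement(SUBTESTS, residuals=(name == "baseline_g") and residuals)
        return ModelSpec(name=name, observed=SUBTESTS, latent=("g",), paths=loadings, covariances=covs)
    loadings, covs = _g_measurement(SUBTESTS, residuals=residuals)
    structural = {
        "model_a": _structural(True, ()),
        "model_b": _structural(True, ("logical_memory", "digit_symbol")),
        "model_c": _structural(False, MODEL_C_DIRECT_TARGETS),
        "model_c_full": _structural(False, SUBTESTS),
    }[name]
    return ModelSpec(
        name=name if residuals else f"{name}_no_residuals",
        observed=STUDY_VARIABLES.names,
        latent=("g",),
        paths=loadings + structural,
        covariances=covs,
    )


def without_residual_covariances(spec: ModelSpec) -> ModelSpec:
    """Robustness variant: drop the five residual covariances."""
    pairs = {frozenset(p) for p in RESIDUAL_COVARIANCE_PAIRS}
    covs = tuple(c for c in spec.covariances if frozenset((c.a, c.b)) not in pairs)
    return replace(spec, covariances=covs, name=f"{spec.name}_no_residuals")


def build_alt_factor(name: str) -> ModelSpec:
    """Alternative measurement structures for the ten subtests.

    ``correlated_k{2,3,4}``: k factors (variances fixed at 1, correlations
    free) instead of g.  ``hierarchical``: the four factors with g as a
    second-order factor (first indicator loading per factor fixed at 1 for
    scale).  ``bifactor``: g over all ten subtests plus the four group factors
    orthogonal to g and to each other; two-indicator group factors get
    equated loadings for identification.
    """
    if name.startswith("correlated_k"):
        k = int(name.removeprefix("correlated_k"))
        members = FACTOR_MEMBERSHIPS[k]
        factors = tuple(members)
        paths = tuple(Path(f, s) for f in factors for s in members[f])
        covs = [Covariance(f, f, free=False, value=1.0) for f in factors]
        covs += [Covariance(a, b) for i, a in enumerate(factors) for b in factors[i + 1:]]
        return ModelSpec(name=name, observed=SUBTESTS, latent=factors, paths=paths, covariances=tuple(covs))
    if name == "hierarchical":
        members = FACTOR_MEMBERSHIPS[4]
        factors = tuple(members)
        paths = []
        for f in factors:
            first, *rest = members[f]
            paths.append(Path(f, first, free=False, value=1.0))
            paths += [Path(f, s) for s in rest]
        paths += [Path("g", f) for f in factors]
        covs = (Covariance("g", "g", free=False, value=1.0),)
        return ModelSpec(name=name, observed=SUBTESTS, latent=factors + ("g",), paths=tuple(paths), covariances=covs)
    if name == "bifactor":
        members = FACTOR_MEMBERSHIPS[4]
        factors = tuple(members)
        paths = [Path("g", s) for s in SUBTESTS]
        for f in factors:
            if len(members[f]) == 2:
                paths += [Path(f, s, label=f"lambda_{f}") for s in members[f]]
            else:
                paths += [Path(f, s) for s in members[f]]
        covs = tuple(Covariance(x, x, free=False, value=1.0) for x in ("g",) + factors)
        return ModelSpec(name=name, observed=SUBTESTS, latent=("g",) + factors, paths=tuple(paths), covariances=covs)
    raise KeyError(f"unknown alternative factor model {name!r}")


def is_nested(restricted: ModelSpec, full: ModelSpec) -> bool:
    """Structural nesting: restricted's free parameters are a subset of full's,
    mapped onto identical cells, and its extra constraints are zeros in full."""
    r, f = compile_ram(restricted), compile_ram(full)
    if r.names != f.names or r.observed != f.observed:
        return False
    for label in r.free_labels:
        if label not in f.free_labels or r.cells[label] != f.cells[label]:
            return False
    # cells fixed in restricted must be either identically fixed or free-at-large in full
    free_cells_f = {cell for cells in f.cells.values() for cell in cells}
    for mat, M_r, M_f in (("A", r.A0, f.A0), ("S", r.S0, f.S0)):
        diff = np.argwhere(M_r != M_f)
        for i, j in diff:
            if ("A", i, j) not in free_cells_f and ("S", i, j) not in free_cells_f and ("S", j, i) not in free_cells_f:
                return False
    return True


@dataclass
class EliminationTrace:
    """Record of a backward-elimination pass over candidate paths."""

    alpha: float
    steps: list[dict] = field(default_factory=list)   # label, p_before, delta_chi_square, delta_df
    surviving: tuple[str, ...] = ()
    converged: bool = True

    @property
    def dropped(self) -> tuple[str, ...]:
        return tuple(s["label"] for s in self.steps)


def backward_eliminate(
    data,
    spec: ModelSpec | None = None,
    alpha: float = 0.05,
    method: str = "ml",
    seed: int = 0,
) -> tuple[ModelSpec, EliminationTrace, FitResult]:
    """Backward elimination of education -> subtest paths.

    Starting from ``model_c_full`` (paths from education to all ten subtests,
    none to g), repeatedly refit and drop the single candidate path with the
    largest likelihood-ratio p-value >= alpha, until every remaining candidate
    is significant.  Returns the final spec, the trace, and the final fit.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    spec = spec or build("model_c_full")
    fitter = {"ml": fit_ml, "fiml": fit_fiml}[method]
    fit = fitter(data, spec, seed=seed)
    trace = EliminationTrace(alpha=alpha)
    candidates = [p.default_label() for p in spec.paths if p.source == EDUCATION and p.free and p.target != "g"]
    while candidates:
        if not fit.converged:
            trace.converged = False
            break
        tests = {}
        for label in candidates:
            try:
                tests[label] = drop_test(fit, label, seed=seed)
            except ValueError:
                trace.converged = False
        if not tests:
            break
        worst = max(tests, key=lambda lab: tests[lab].p_value)
        if tests[worst].p_value < alpha:
            break
        cmp_res = tests[worst]
        trace.steps.append(
            {
                "label": worst,
                "p_before": cmp_res.p_value,
                "delta_chi_square": cmp_res.delta_chi_square,
                "delta_df": cmp_res.delta_df,
            }
        )
        spec = replace(spec.fix_parameter(worst, 0.0), name=spec.name)
        fit = fitter(data, spec, seed=seed)
        candidates.remove(worst)
    trace.surviving = tuple(candidates)
    final_spec = replace(spec, name=f"model_c_eliminated_a{alpha:g}")
    return replace(fit.spec, name=final_spec.name) if fit.spec else final_spec, trace, fit


def find_residual_covariances(data, n_steps: int = 5, method: str = "ml", seed: int = 0) -> tuple[str, ...]:
    """Sequential modification-index search for residual covariances.

    Starting from the plain one-factor model of the ten subtests, repeatedly
    free the subtest pair with the largest modification index and refit,
    ``n_steps`` times — the usual MI-guided respecification loop.  On the
    printed summary matrix five steps recover the five residual covariances
    used throughout the study.
    """
    from edusem.sem_engine.fit import modification_indices

    spec = build("one_factor")
    fitter = {"ml": fit_ml, "fiml": fit_fiml}[method]
    freed: list[str] = []
    candidates = [Covariance(a, b) for i, a in enumerate(SUBTESTS) for b in SUBTESTS[i + 1:]]
    for _ in range(n_steps):
        fit = fitter(data, spec, seed=seed)
        remaining = [c for c in candidates if c.default_label() not in freed]
        mis = modification_indices(fit, remaining)
        top = max(mis, key=mis.get)
        freed.append(top)
        a, b = top.split("~~")
        spec = spec.add(Covariance(a, b))
    return tuple(freed)


def residualize_cohort(cohort: CohortMatrix) -> CohortMatrix:
    """Replace each age-70 subtest with its residual from a simple regression
    on age-11 IQ (complete pairs); education and age-11 IQ are untouched.

    Rows missing either member of a pair keep a missing residual.  Residuals
    have zero sample correlation with age-11 IQ by construction.
    """
    df = cohort.data.copy()
    x = df[EARLY_IQ]
    for s in SUBTESTS:
        y = df[s]
        ok = x.notna() & y.notna()
        if ok.sum() < 3:
            raise ValueError(f"insufficient complete pairs to residualize {s!r}")
        slope, intercept = np.polyfit(x[ok], y[ok], 1)
        res = y - (intercept + slope * x)
        df[s] = res.where(ok, np.nan)
    prov = dict(cohort.provenance)
    prov["residualized_on"] = EARLY_IQ
    return CohortMatrix(data=df, variables=cohort.variables, provenance=prov)


def build_residualized_suite() -> dict[str, ModelSpec]:
    """Models A/B/C for residualised subtests: age-11 IQ keeps only its path
    to education (its association with the subtests is removed by the
    preprocessing), everything else as in the main models."""
    out = {}
    for name in ("model_a", "model_b", "model_c"):
        spec = build(name)
        paths = tuple(p for p in spec.paths if not (p.source == EARLY_IQ and p.target == "g"))
        out[name] = replace(spec, paths=paths, name=f"{name}_residualized")
    return out
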