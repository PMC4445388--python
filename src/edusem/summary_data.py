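"""Printed summary statistics for the study cohort: container, validation, fixture.

The analysis rests on a 12-variable summary — an age-11 Moray House Test (MHT)
intelligence score, self-reported years of full-time education, and ten cognitive
tests taken at age ~70 — published as a Pearson correlation matrix with means,
SDs and per-variable observed counts for a cohort of n = 1,091.  This module
loads that table from a packaged TSV fixture, validates it, and converts it to
the covariance form the ML fitting routines consume.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "VariableSet",
    "SummaryMoments",
    "MomentInput",
    "ValidationReport",
    "STUDY_VARIABLES",
    "PRINTED_LABELS",
    "load_table1_fixture",
    "to_covariance",
    "validate",
]

# Short ASCII keys -> printed labels.  Order matches the published table.
PRINTED_LABELS: dict[str, str] = {
    "age11_mht": "Age ~11 MHT",
    "education": "Education (years)",
    "logical_memory": "Logical Memory",
    "digit_symbol": "Digit-Symbol Substitution",
    "matrix_reasoning": "Matrix Reasoning",
    "block_design": "Block Design",
    "verbal_paired_assoc": "Verbal Paired Associates",
    "symbol_search": "Symbol Search",
    "letter_number_seq": "Letter-Number Sequencing",
    "digit_span_backwards": "Digit Span Backwards",
    "spatial_span": "Spatial Span",
    "age70_mht": "Age ~70 MHT",
}


@dataclass(frozen=True)
class VariableSet:
    """Ordered variable identifiers with their roles in the models.

    Roles are ``early_iq`` (the age-11 intelligence score), ``education``
    (years of schooling) and ``subtest`` (the ten age-70 cognitive tests).
    """

    names: tuple[str, ...]
    roles: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("variable names must be unique")
        if set(self.roles) != set(self.names):
            raise ValueError("roles must cover exactly the variable names")
        counts = {r: sum(1 for v in self.roles.values() if v == r) for r in set(self.roles.values())}
        if counts.get("early_iq", 0) != 1 or counts.get("education", 0) != 1:
            raise ValueError("need exactly one early_iq and one education variable")

    @property
    def early_iq(self) -> str:
        return next(n for n in self.names if self.roles[n] == "early_iq")

    @property
    def education(self) -> str:
        return next(n for n in self.names if self.roles[n] == "education")

    @property
    def subtests(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if self.roles[n] == "subtest")


STUDY_VARIABLES = VariableSet(
    names=tuple(PRINTED_LABELS),
    roles={
        "age11_mht": "early_iq",
        "education": "education",
        **{k: "subtest" for k in PRINTED_LABELS if k not in ("age11_mht", "education")},
    },
)


@dataclass(frozen=True)
class SummaryMoments:
    """Correlation matrix plus univariate moments for a named variable set."""

    variables: VariableSet
    corr: np.ndarray          # p x p, unit diagonal
    sd: np.ndarray            # length p, test-score units
    mean: np.ndarray          # length p
    n_obs: np.ndarray         # length p, observed counts
    n_total: int

    @property
    def p(self) -> int:
        return len(self.variables.names)

    def index(self, name: str) -> int:
        return self.variables.names.index(name)

    def r(self, a: str, b: str) -> float:
        return float(self.corr[self.index(a), self.index(b)])

    def subtest_corr(self) -> np.ndarray:
        """Correlation submatrix of the ten age-70 subtests."""
        idx = [self.index(n) for n in self.variables.subtests]
        return self.corr[np.ix_(idx, idx)]


@dataclass(frozen=True)
class MomentInput:
    """Sample moments handed to the ML discrepancy: covariance S, means, n."""

    variables: VariableSet
    cov: np.ndarray
    mean: np.ndarray | None
    n_eff: int


@dataclass
class ValidationReport:
    symmetric: bool
    unit_diagonal: bool
    bounds_ok: bool
    sd_positive: bool
    counts_ok: bool
    min_eigenvalue: float
    positive_definite: bool
    problems: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.problems

    def to_json(self) -> str:
        return json.dumps(
            {
                "symmetric": self.symmetric,
                "unit_diagonal": self.unit_diagonal,
                "bounds_ok": self.bounds_ok,
                "sd_positive": self.sd_positive,
                "counts_ok": self.counts_ok,
                "min_eigenvalue": self.min_eigenvalue,
                "positive_definite": self.positive_definite,
                "problems": self.problems,
            },
            indent=2,
        )


def _parse_count(text: str) -> int:
    # printed tables use comma thousands separators ("1,091")
    return int(text.replace(",", ""))


def load_table1_fixture() -> SummaryMoments:
    """Load the packaged summary table (lower-triangle correlations, M/SD/n).

    Raises ``ValueError`` naming the missing cell if the fixture is incomplete.
    """
    ref = resources.files("edusem").joinpath("data/table1.tsv")
    lines = ref.read_text().strip().splitlines()
    header = lines[0].split("\t")
    names = header[1 : header.index("mean")]
    if tuple(names) != STUDY_VARIABLES.names:
        raise ValueError("fixture variable set does not match the study variables")
    p = len(names)
    corr = np.full((p, p), np.nan)
    mean = np.full(p, np.nan)
    sd = np.full(p, np.nan)
    n_obs = np.zeros(p, dtype=int)
    for line in lines[1:]:
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ValueError(f"fixture row for {cells[0]!r} has {len(cells)} cells, expected {len(header)}")
        i = names.index(cells[0])
        for j in range(i + 1):
            cell = cells[1 + j]
            if cell == "":
                raise ValueError(f"fixture missing correlation ({names[i]}, {names[j]})")
            corr[i, j] = corr[j, i] = float(cell)
        mean[i] = float(cells[1 + p])
        sd[i] = float(cells[2 + p])
        n_obs[i] = _parse_count(cells[3 + p])
    for i in range(p):
        for j in range(p):
            if np.isnan(corr[i, j]):
                raise ValueError(f"fixture missing correlation ({names[i]}, {names[j]})")
        if np.isnan(mean[i]) or np.isnan(sd[i]):
            raise ValueError(f"fixture missing mean/sd for {names[i]}")
    return SummaryMoments(
        variables=STUDY_VARIABLES,
        corr=corr,
        sd=sd,
        mean=mean,
        n_obs=n_obs,
        n_total=int(n_obs.max()),
    )


def validate(sm: SummaryMoments) -> ValidationReport:
    """Report-only checks: symmetry, bounds, minimum eigenvalue, PD flag."""
    problems: list[str] = []
    symmetric = bool(np.allclose(sm.corr, sm.corr.T, atol=1e-12))
    unit_diag = bool(np.allclose(np.diag(sm.corr), 1.0, atol=1e-12))
    bounds_ok = bool(np.all(np.abs(sm.corr) <= 1.0 + 1e-12))
    sd_positive = bool(np.all(sm.sd > 0))
    counts_ok = bool(np.all((sm.n_obs > 0) & (sm.n_obs <= sm.n_total)))
    if not symmetric:
        problems.append("correlation matrix not symmetric")
    if not unit_diag:
        problems.append("correlation diagonal not 1")
    if not bounds_ok:
        problems.append("|r| > 1 present")
    if not sd_positive:
        problems.append("non-positive sd")
    if not counts_ok:
        problems.append("observed counts outside (0, n_total]")
    min_eig = float(np.linalg.eigvalsh((sm.corr + sm.corr.T) / 2.0).min()) if symmetric else float("nan")
    pd_flag = bool(symmetric and min_eig > 0)
    if symmetric and not pd_flag:
        problems.append(f"matrix not positive definite (min eigenvalue {min_eig:.3e})")
    return ValidationReport(
        symmetric=symmetric,
        unit_diagonal=unit_diag,
        bounds_ok=bounds_ok,
        sd_positive=sd_positive,
        counts_ok=counts_ok,
        min_eigenvalue=min_eig,
        positive_definite=pd_flag,
        problems=problems,
    )


def _repair_pd(mat: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Clip eigenvalues at `floor`; preserves printed values to ~3 decimals."""
    w, v = np.linalg.eigh((mat + mat.T) / 2.0)
    if w.min() > 0:
        return mat
    warnings.warn(f"covariance not PD (min eigenvalue {w.min():.3e}); clipping at {floor}")
    w = np.clip(w, floor, None)
    return v @ np.diag(w) @ v.T


def to_covariance(
    sm: SummaryMoments,
    n_policy: str = "total",
    on_non_pd: str = "repair",
) -> MomentInput:
    """Rescale the correlation matrix to covariance form.

    ``cov[i, j] = corr[i, j] * sd[i] * sd[j]``.  The effective sample size fed
    to the fitter follows ``n_policy``: ``total`` (the cohort n, default),
    ``min`` (minimum per-variable observed count) or ``mean`` (rounded mean
    count).  A numerically non-PD result (possible with 2-decimal printed
    correlations) is eigenvalue-clipped when ``on_non_pd='repair'``, or raises
    when ``on_non_pd='fail'``.
    """
    cov = sm.corr * np.outer(sm.sd, sm.sd)
    min_eig = np.linalg.eigvalsh((cov + cov.T) / 2.0).min()
    if min_eig <= 0:
        if on_non_pd == "fail":
            raise ValueError(f"covariance not positive definite (min eigenvalue {min_eig:.3e})")
        cov = _repair_pd(cov)
    if n_policy == "total":
        n_eff = sm.n_total
    elif n_policy == "min":
        n_eff = int(sm.n_obs.min())
    elif n_policy == "mean":
        n_eff = int(round(sm.n_obs.mean()))
    else:
        raise ValueError(f"unknown n_policy {n_policy!r}")
    return MomentInput(variables=sm.variables, cov=cov, mean=sm.mean.copy(), n_eff=n_eff)
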