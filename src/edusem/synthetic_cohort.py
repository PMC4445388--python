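"""Synthetic raw-score cohorts emulating the study data.

The real cohort (n = 1,091, 12 variables, near-complete data) is
access-restricted, so full-information maximum likelihood and the end-to-end
pipeline are exercised on generated stand-ins: multivariate-normal draws with
the printed moment structure and per-variable missing-completely-at-random
(MCAR) masks matching the printed observed counts.

Two generation modes:

``exact_moments``
    Base draws are centered, whitened with the Cholesky factor of their own
    sample covariance, then recolored to the target; the output's sample mean
    and sample covariance (ddof=1) equal the targets to machine precision, so
    complete-data ML fits to the cohort coincide with summary-based fits.
``sampled``
    Plain iid multivariate-normal draws with the target moments in expectation.

Normality is deliberate: it is the distributional assumption under which the
ML fit statistics are derived, even though real test scores are bounded and
discrete.  An optional post-step rounds scores to integer-like ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from edusem.summary_data import SummaryMoments, VariableSet

__all__ = [
    "CohortMatrix",
    "MissingnessProfile",
    "GeneratorConfig",
    "generate_cohort",
    "impose_missingness",
    "table1_missingness",
    "write_cohort",
    "read_cohort",
]

GENERATOR_VERSION = "1"
MISSING_MARKER = "NA"


@dataclass
class CohortMatrix:
    """An n x p raw-score table (NaN marks missing) plus provenance."""

    data: pd.DataFrame
    variables: VariableSet
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def p(self) -> int:
        return self.data.shape[1]

    def observed_counts(self) -> pd.Series:
        return self.data.notna().sum()


@dataclass(frozen=True)
class MissingnessProfile:
    """Per-variable target observed counts (education is always complete)."""

    observed_counts: dict[str, int]

    def validate(self, n_total: int, variables: VariableSet) -> None:
        for name, count in self.observed_counts.items():
            if name not in variables.names:
                raise ValueError(f"unknown variable {name!r} in missingness profile")
            if not 0 < count <= n_total:
                raise ValueError(f"observed count for {name!r} ({count}) outside (0, {n_total}]")
        edu = variables.education
        if self.observed_counts.get(edu, n_total) != n_total:
            raise ValueError("education must have no missing values")


@dataclass(frozen=True)
class GeneratorConfig:
    n: int = 1091
    seed: int = 0
    mode: str = "exact_moments"  # or "sampled"
    discretize: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("exact_moments", "sampled"):
            raise ValueError(f"unknown mode {self.mode!r}")


def table1_missingness(sm: SummaryMoments) -> MissingnessProfile:
    """Missingness profile reproducing the printed per-variable counts."""
    return MissingnessProfile(
        observed_counts={name: int(c) for name, c in zip(sm.variables.names, sm.n_obs)}
    )


def generate_cohort(moments: SummaryMoments, cfg: GeneratorConfig) -> CohortMatrix:
    """Draw an n x p multivariate-normal cohort with the target moments.

    ``exact_moments`` requires n >= p + 1 so the base draws' sample covariance
    is invertible; the recolored output then matches the target mean vector
    and covariance exactly (ddof=1 convention).
    """
    p = moments.p
    cov = moments.corr * np.outer(moments.sd, moments.sd)
    w = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    if w.min() <= 0:
        raise ValueError(f"target covariance not positive definite (min eigenvalue {w.min():.3e})")
    rng = np.random.default_rng(cfg.seed)
    if cfg.mode == "exact_moments":
        if cfg.n < p + 1:
            raise ValueError(f"exact_moments needs n >= p + 1 = {p + 1}")
        z = rng.standard_normal((cfg.n, p))
        z -= z.mean(axis=0)
        sample_cov = z.T @ z / (cfg.n - 1)
        z = z @ np.linalg.inv(np.linalg.cholesky(sample_cov)).T
        x = z @ np.linalg.cholesky(cov).T + moments.mean
    else:
        x = rng.multivariate_normal(moments.mean, cov, size=cfg.n, method="cholesky")
    if cfg.discretize:
        x = np.round(x)
        # education reported in half-year steps
        j = moments.variables.names.index(moments.variables.education)
        x[:, j] = np.round(x[:, j] * 2) / 2
    df = pd.DataFrame(x, columns=list(moments.variables.names))
    prov = {
        "seed": cfg.seed,
        "mode": cfg.mode,
        "n": cfg.n,
        "discretize": cfg.discretize,
        "generator_version": GENERATOR_VERSION,
    }
    return CohortMatrix(data=df, variables=moments.variables, provenance=prov)


def impose_missingness(cohort: CohortMatrix, profile: MissingnessProfile, seed: int) -> CohortMatrix:
    """Blank entries uniformly at random per variable to hit the target counts.

    MCAR by construction: positions are chosen independently of all values.
    Deterministic under a fixed seed; columns absent from the profile are left
    complete.
    """
    profile.validate(cohort.n, cohort.variables)
    rng = np.random.default_rng(seed)
    df = cohort.data.copy()
    for name in cohort.variables.names:
        target = profile.observed_counts.get(name, cohort.n)
        n_missing = cohort.n - target
        if n_missing:
            rows = rng.choice(cohort.n, size=n_missing, replace=False)
            df.iloc[rows, df.columns.get_loc(name)] = np.nan
    prov = dict(cohort.provenance)
    prov["missingness"] = {"seed": seed, "observed_counts": dict(profile.observed_counts)}
    return CohortMatrix(data=df, variables=cohort.variables, provenance=prov)


def cohort_moments(cohort: CohortMatrix, ddof: int = 0):
    """Sample moments (listwise-complete rows) of a cohort as fitter input.

    ``ddof=0`` gives the normal-theory MLE covariance, under which a
    complete-data FIML fit and a summary ML fit coincide exactly.
    """
    from edusem.summary_data import MomentInput

    x = cohort.data.to_numpy(dtype=float)
    complete = ~np.isnan(x).any(axis=1)
    x = x[complete]
    if len(x) < cohort.p + 1:
        raise ValueError("not enough complete rows to form sample moments")
    return MomentInput(
        variables=cohort.variables,
        cov=np.cov(x, rowvar=False, ddof=ddof),
        mean=x.mean(axis=0),
        n_eff=len(x),
    )


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".provenance.json")


def write_cohort(cohort: CohortMatrix, path: str | Path) -> None:
    """TSV with header and 'NA' missing markers; JSON provenance sidecar."""
    path = Path(path)
    cohort.data.to_csv(path, sep="\t", index=False, na_rep=MISSING_MARKER, float_format="%.10g")
    _sidecar(path).write_text(
        json.dumps({"variables": list(cohort.variables.names), "provenance": cohort.provenance}, indent=2)
    )


def read_cohort(path: str | Path, variables: VariableSet) -> CohortMatrix:
    """Lossless counterpart of :func:`write_cohort`.

    Malformed (ragged) rows fail with the 1-based line number; unknown or
    missing columns fail by name.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    unknown = set(header) - set(variables.names)
    if unknown:
        raise ValueError(f"{path}: unknown columns {sorted(unknown)}")
    if set(header) != set(variables.names):
        raise ValueError(f"{path}: missing columns {sorted(set(variables.names) - set(header))}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ValueError(f"{path}: line {lineno} has {len(cells)} fields, expected {len(header)}")
        rows.append([np.nan if c == MISSING_MARKER else float(c) for c in cells])
    df = pd.DataFrame(rows, columns=header)[list(variables.names)]
    prov = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        prov = json.loads(sidecar.read_text()).get("provenance", {})
    return CohortMatrix(data=df, variables=variables, provenance=prov)
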