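"""Factor-structure determination for the age-70 cognitive battery.

Three tools decide how many latent dimensions the ten subtests support:

* the eigen-spectrum of their correlation matrix;
* Horn's parallel analysis — observed eigenvalues are retained while they
  exceed a chosen percentile of eigenvalues from iid standard-normal data of
  the same n x p shape (principal-component eigenvalues, Horn's original
  formulation);
* exploratory factor analysis (maximum likelihood, direct-oblimin/quartimin
  rotation for k >= 2) to inspect the composition of multi-factor solutions.

Extraction and rotation are delegated to statsmodels; retention logic and the
random-data reference distribution are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.multivariate.factor import Factor
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = [
    "EigenSpectrum",
    "ParallelAnalysisResult",
    "EFASolution",
    "correlation_eigenvalues",
    "parallel_analysis",
    "efa",
]


@dataclass(frozen=True)
class EigenSpectrum:
    eigenvalues: np.ndarray  # descending

    @property
    def p(self) -> int:
        return len(self.eigenvalues)

    @property
    def first(self) -> float:
        return float(self.eigenvalues[0])


@dataclass(frozen=True)
class ParallelAnalysisResult:
    observed: EigenSpectrum
    thresholds: np.ndarray
    retained: int
    iterations: int
    percentile: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed": self.observed.eigenvalues.tolist(),
            "thresholds": self.thresholds.tolist(),
            "retained": self.retained,
            "iterations": self.iterations,
            "percentile": self.percentile,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class EFASolution:
    names: tuple[str, ...]
    pattern: np.ndarray       # p x k pattern loadings
    phi: np.ndarray           # k x k factor correlations
    uniquenesses: np.ndarray  # length p
    extraction: str
    rotation: str
    heywood: bool             # any communality >= 1 (flagged, never clipped)

    @property
    def k(self) -> int:
        return self.pattern.shape[1]

    def factor_members(self) -> list[set[str]]:
        """Assign each variable to the factor holding its largest |pattern| loading."""
        members: list[set[str]] = [set() for _ in range(self.k)]
        for i, name in enumerate(self.names):
            members[int(np.argmax(np.abs(self.pattern[i])))].add(name)
        return members


def correlation_eigenvalues(corr: np.ndarray) -> EigenSpectrum:
    """Descending eigenvalues of a correlation matrix; rejects asymmetric input."""
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    return EigenSpectrum(eigenvalues=np.linalg.eigvalsh(corr)[::-1].copy())


def parallel_analysis(
    observed: EigenSpectrum,
    n: int,
    iterations: int = 1000,
    percentile: float = 95.0,
    seed: int = 0,
) -> ParallelAnalysisResult:
    """Horn's parallel analysis on an observed eigen-spectrum.

    Reference eigenvalues come from correlation matrices of iid standard-normal
    n x p datasets; the retained count is the length of the leading run of
    observed eigenvalues strictly exceeding their rank's threshold.  Operating
    on the spectrum plus (n, p) is equivalent in distribution to operating on
    raw uncorrelated scores.
    """
    p = observed.p
    if n <= p:
        raise ValueError("parallel analysis needs n > p")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    rng = np.random.default_rng(seed)
    sims = np.empty((iterations, p))
    for it in range(iterations):
        x = rng.standard_normal((n, p))
        sims[it] = np.linalg.eigvalsh(np.corrcoef(x, rowvar=False))[::-1]
    thresholds = np.percentile(sims, percentile, axis=0)
    retained = 0
    for obs, thr in zip(observed.eigenvalues, thresholds):
        if obs > thr:
            retained += 1
        else:
            break
    return ParallelAnalysisResult(
        observed=observed,
        thresholds=thresholds,
        retained=retained,
        iterations=iterations,
        percentile=percentile,
        seed=seed,
    )


def _fix_signs(pattern: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # orient each factor so its dominant loading is positive
    flip = np.sign(pattern[np.abs(pattern).argmax(axis=0), np.arange(pattern.shape[1])])
    flip[flip == 0] = 1.0
    return pattern * flip, phi * np.outer(flip, flip)


def efa(
    corr: np.ndarray,
    n: int,
    k: int,
    names: tuple[str, ...] | list[str],
    rotation: str = "oblimin",
    extraction: str = "ml",
) -> EFASolution:
    """Exploratory factor analysis of a correlation matrix.

    Maximum-likelihood extraction (principal-axis selectable) with direct
    oblimin (gamma = 0, i.e. quartimin) rotation for k >= 2; k = 1 returns the
    unrotated first factor.  A Heywood case (communality >= 1) is flagged on
    the result rather than silently clipped.
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    if not 1 <= k < p:
        raise ValueError(f"k must lie in [1, {p - 1}]")
    if extraction not in ("ml", "pa"):
        raise ValueError(f"unknown extraction {extraction!r}")
    method = {"ml": "ml", "pa": "pa"}[extraction]
    res = Factor(corr=corr, n_factor=k, method=method, nobs=n).fit()
    loadings = np.asarray(res.loadings)
    if k == 1 or rotation == "none":
        pattern, phi = loadings, np.eye(k)
    elif rotation == "oblimin":
        pattern, t_mat = rotate_factors(loadings, "oblimin", 0.0, "oblique")
        phi = t_mat.T @ t_mat
    else:
        raise ValueError(f"unknown rotation {rotation!r}")
    pattern, phi = _fix_signs(pattern, phi)
    communality = np.diag(pattern @ phi @ pattern.T)
    uniq = 1.0 - communality
    return EFASolution(
        names=tuple(names),
        pattern=pattern,
        phi=phi,
        uniquenesses=uniq,
        extraction=extraction,
        rotation="none" if k == 1 else rotation,
        heywood=bool(np.any(communality >= 1.0 - 1e-10)),
    )
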