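"""Estimation and inference for RAM-compiled models.

Summary-based ML minimises the normal-theory discrepancy

    F_ML(theta) = ln|Sigma| + tr(S Sigma^{-1}) - ln|S| - p

with chi-square = (n_eff - 1) * F_ML(theta_hat).  FIML maximises the casewise
normal log-likelihood over each row's observed subset of (mu(theta),
Sigma(theta)); its chi-square is the likelihood ratio against the saturated
model (whose MLE is found by EM).  Both paths share analytic gradients built
from the RAM derivative identity dSigma = B dA Sigma_all + B dS B' +
Sigma_all dA' B' with B = (I - A)^{-1}.

Standard errors: inverse expected information for summary fits, observed
information (finite differences of the analytic gradient) for FIML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from edusem.sem_engine.model import Covariance, ModelSpec, Path, RAMMatrices, compile_ram
from edusem.summary_data import MomentInput

__all__ = [
    "FitResult",
    "FitIndices",
    "ComparisonResult",
    "fit_ml",
    "fit_fiml",
    "standardize",
    "fit_indices",
    "compare",
    "modification_indices",
    "drop_test",
]

GRADIENT_TOL = 1e-10  # convergence: inf-norm of the gradient, relative to 1 + |f|
MULTISTART = 5
_BIG = 1e10


# ---------------------------------------------------------------------------
# results


@dataclass
class FitResult:
    """Estimates and inferential summaries of one fitted model."""

    model: str
    method: str                       # "ml" | "fiml"
    estimates: dict[str, float]
    se: dict[str, float]
    std_estimates: dict[str, float]   # per-cell, keyed "target~source" / "a~~b"
    discrepancy: float                # F_ML (ml) or -2 lnL (fiml)
    loglik: float | None
    chi_square: float
    df: int
    n_eff: int
    n_free: int
    aic: float
    aic_scale: str                    # "relative" (chi2 + 2k) | "loglik" (-2lnL + 2k)
    converged: bool
    warnings: list[str] = field(default_factory=list)
    # private plumbing for refits/baselines (not part of the reported surface)
    ram: RAMMatrices | None = None
    theta: np.ndarray | None = None
    spec: ModelSpec | None = None
    data: object | None = None        # MomentInput or CohortMatrix
    baseline_chi_square: float | None = None
    baseline_df: int | None = None

    def estimate(self, label: str) -> float:
        return self.estimates[label]

    def std(self, key: str) -> float:
        return self.std_estimates[key]


@dataclass(frozen=True)
class FitIndices:
    rmsea: float
    cfi: float
    tli: float
    aic: float

    def as_dict(self) -> dict[str, float]:
        return {"rmsea": self.rmsea, "cfi": self.cfi, "tli": self.tli, "aic": self.aic}


@dataclass(frozen=True)
class ComparisonResult:
    restricted: str
    full: str
    delta_chi_square: float
    delta_df: int
    p_value: float
    delta_aic: float


# ---------------------------------------------------------------------------
# shared RAM plumbing


def _b_matrix(A: np.ndarray) -> np.ndarray:
    t = A.shape[0]
    return np.linalg.solve(np.eye(t) - A, np.eye(t))


def _latent_scale_guess(ram: RAMMatrices, sample_cov: np.ndarray) -> dict[str, float]:
    """Rough variance guess per latent: its fixed S value if any, else half the
    sample variance of a marker indicator (fixed unit loading), else 1."""
    obs_index = {v: i for i, v in enumerate(ram.observed)}
    scale: dict[str, float] = {}
    for name in ram.names:
        if name in obs_index:
            continue
        j = ram.index(name)
        if ram.S0[j, j] > 0:
            scale[name] = float(ram.S0[j, j])
            continue
        marker = next(
            (i for i in range(ram.p) if ram.A0[i, j] == 1.0),
            None,
        )
        scale[name] = 0.5 * float(sample_cov[marker, marker]) if marker is not None else 1.0
    return scale


def _start_vector(ram: RAMMatrices, sample_cov: np.ndarray, sample_mean: np.ndarray | None) -> np.ndarray:
    """Start values: loadings 0.7*sd(indicator)/sd(factor guess), uniquenesses
    0.5*variance, exogenous variances at the sample variance, regressions and
    residual covariances 0, latent covariances 0.3, intercepts at the mean."""
    obs_index = {v: i for i, v in enumerate(ram.observed)}
    lat_scale = _latent_scale_guess(ram, sample_cov)
    theta0 = np.zeros(ram.n_free)
    for k, label in enumerate(ram.free_labels):
        if ram.starts.get(label) is not None:
            theta0[k] = ram.starts[label]
            continue
        mat, i, j = ram.cells[label][0]
        vi = ram.names[i]
        if mat == "A":
            source = ram.names[j]
            target_obs = vi in obs_index
            source_latent = source not in obs_index
            if target_obs and source_latent:  # factor loading
                theta0[k] = 0.7 * np.sqrt(sample_cov[obs_index[vi], obs_index[vi]] / lat_scale[source])
            elif not target_obs and source_latent:  # latent regression (e.g. second-order)
                theta0[k] = np.sqrt(0.5 * lat_scale[vi] / lat_scale[source])
            else:
                theta0[k] = 0.0
        elif mat == "S":
            vj = ram.names[j]
            if i == j:
                if vi in obs_index:
                    var = sample_cov[obs_index[vi], obs_index[vi]]
                    theta0[k] = var if ram.cell_is_exogenous(vi) else 0.5 * var
                else:
                    theta0[k] = (0.5 if not ram.cell_is_exogenous(vi) else 1.0) * lat_scale[vi]
            else:
                theta0[k] = 0.3 if (vi not in obs_index and vj not in obs_index) else 0.0
        else:  # mean
            theta0[k] = sample_mean[obs_index[vi]] if sample_mean is not None else 0.0
    return theta0


def _grad_from_GM(
    ram: RAMMatrices,
    B: np.ndarray,
    S: np.ndarray,
    m: np.ndarray,
    G_obs: np.ndarray,
    v_obs: np.ndarray | None,
) -> np.ndarray:
    """Map d f = tr(G dSigma) + v' dmu into theta-space via the RAM cells."""
    t, p = ram.t, ram.p
    M = np.zeros((t, t))
    M[:p, :p] = G_obs
    WS = B.T @ M @ B
    X = B @ S @ B.T @ M @ B
    if v_obs is not None:
        vt = np.zeros(t)
        vt[:p] = v_obs
        Btv = B.T @ vt
        Bm = B @ m
    grad = np.zeros(ram.n_free)
    for k, label in enumerate(ram.free_labels):
        acc = 0.0
        for mat, i, j in ram.cells[label]:
            if mat == "A":
                acc += 2.0 * X[j, i]
                if v_obs is not None:
                    acc += Btv[i] * Bm[j]
            elif mat == "S":
                acc += WS[i, i] if i == j else 2.0 * WS[i, j]
            else:
                if v_obs is not None:
                    acc += Btv[i]
        grad[k] = acc
    return grad


class _MLObjective:
    """F_ML discrepancy (optionally with mean structure) and its gradient."""

    def __init__(self, ram: RAMMatrices, sample_cov: np.ndarray, sample_mean: np.ndarray | None, n_eff: int):
        self.ram = ram
        self.S_samp = np.asarray(sample_cov, dtype=float)
        self.mean_samp = None if sample_mean is None or not ram.mean_structure else np.asarray(sample_mean, float)
        self.n_eff = n_eff
        sign, self.lndetS = np.linalg.slogdet(self.S_samp)
        if sign <= 0:
            raise ValueError("sample covariance matrix is not positive definite")
        self.p = ram.p

    def value_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        ram = self.ram
        A, S, m = ram.materialize(theta)
        try:
            B = _b_matrix(A)
            sigma_all = B @ S @ B.T
            sigma = sigma_all[: self.p, : self.p]
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return _BIG, np.zeros(ram.n_free)
        sigma_inv = np.linalg.inv(sigma)
        lndet = 2.0 * np.log(np.diag(chol)).sum()
        value = lndet + float(np.sum(sigma_inv * self.S_samp)) - self.lndetS - self.p
        G = sigma_inv @ (sigma - self.S_samp) @ sigma_inv
        v = None
        if self.mean_samp is not None:
            mu = (B @ m)[: self.p]
            d = self.mean_samp - mu
            value += float(d @ sigma_inv @ d)
            G += -sigma_inv @ np.outer(d, d) @ sigma_inv
            v = -2.0 * sigma_inv @ d
        grad = _grad_from_GM(ram, B, S, m, G, v)
        return value, grad


# ---------------------------------------------------------------------------
# FIML machinery


@dataclass
class _PatternStats:
    obs_idx: np.ndarray     # observed column indices for this pattern
    n: int
    mean: np.ndarray
    cov: np.ndarray         # MLE (ddof=0) within-pattern covariance


def _pattern_stats(x: np.ndarray) -> tuple[list[_PatternStats], int]:
    """Group rows by missingness pattern; rows with nothing observed are dropped."""
    mask = ~np.isnan(x)
    dropped = int((~mask.any(axis=1)).sum())
    keep = mask.any(axis=1)
    x, mask = x[keep], mask[keep]
    patterns: list[_PatternStats] = []
    codes = np.array([m.tobytes() for m in mask])
    for code in np.unique(codes):
        rows = x[codes == code]
        obs = np.flatnonzero(mask[codes == code][0])
        sub = rows[:, obs]
        mean = sub.mean(axis=0)
        centered = sub - mean
        cov = centered.T @ centered / len(sub)
        patterns.append(_PatternStats(obs_idx=obs, n=len(sub), mean=mean, cov=cov))
    return patterns, dropped


def _fiml_neg2ll(patterns: list[_PatternStats], sigma: np.ndarray, mu: np.ndarray) -> float:
    total = 0.0
    ln2pi = np.log(2.0 * np.pi)
    for pat in patterns:
        o = pat.obs_idx
        soo = sigma[np.ix_(o, o)]
        chol = np.linalg.cholesky(soo)
        lndet = 2.0 * np.log(np.diag(chol)).sum()
        sinv = np.linalg.inv(soo)
        d = pat.mean - mu[o]
        quad = float(np.sum(sinv * pat.cov)) + float(d @ sinv @ d)
        total += pat.n * (len(o) * ln2pi + lndet + quad)
    return total


class _FIMLObjective:
    """-2 lnL over missingness-pattern sufficient statistics, with gradient."""

    def __init__(self, ram: RAMMatrices, patterns: list[_PatternStats]):
        if not ram.mean_structure:
            raise ValueError("FIML requires a mean structure")
        self.ram = ram
        self.patterns = patterns
        self.p = ram.p

    def value_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        ram = self.ram
        A, S, m = ram.materialize(theta)
        try:
            B = _b_matrix(A)
            sigma_all = B @ S @ B.T
            sigma = sigma_all[: self.p, : self.p]
            np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return _BIG, np.zeros(ram.n_free)
        mu = (B @ m)[: self.p]
        value = 0.0
        G = np.zeros((self.p, self.p))
        v = np.zeros(self.p)
        ln2pi = np.log(2.0 * np.pi)
        try:
            for pat in self.patterns:
                o = pat.obs_idx
                soo = sigma[np.ix_(o, o)]
                chol = np.linalg.cholesky(soo)
                lndet = 2.0 * np.log(np.diag(chol)).sum()
                sinv = np.linalg.inv(soo)
                d = pat.mean - mu[o]
                Ak = pat.cov + np.outer(d, d)
                value += pat.n * (len(o) * ln2pi + lndet + float(np.sum(sinv * Ak)))
                G[np.ix_(o, o)] += pat.n * (sinv - sinv @ Ak @ sinv)
                v[o] += -2.0 * pat.n * (sinv @ d)
        except np.linalg.LinAlgError:
            return _BIG, np.zeros(ram.n_free)
        grad = _grad_from_GM(ram, B, S, m, G, v)
        return value, grad


def _em_saturated(patterns: list[_PatternStats], p: int, tol: float = 1e-10, max_iter: int = 5000):
    """Saturated MVN MLE (mu, Sigma) under missing data via EM on pattern stats."""
    n_total = sum(pat.n for pat in patterns)
    # initialise from available-case moments
    mu = np.zeros(p)
    counts = np.zeros(p)
    for pat in patterns:
        mu[pat.obs_idx] += pat.n * pat.mean
        counts[pat.obs_idx] += pat.n
    mu = mu / np.maximum(counts, 1)
    sigma = np.eye(p)
    for pat in patterns:
        o = pat.obs_idx
        sigma[np.ix_(o, o)] = pat.cov + np.outer(pat.mean - mu[o], pat.mean - mu[o])
    sigma = (sigma + sigma.T) / 2 + 1e-6 * np.eye(p)
    prev = np.inf
    for _ in range(max_iter):
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        for pat in patterns:
            o = pat.obs_idx
            miss = np.setdiff1d(np.arange(p), o)
            soo_inv = np.linalg.inv(sigma[np.ix_(o, o)])
            d = pat.mean - mu[o]
            # E[x_o], E[x_o x_o'] from pattern moments
            exo = pat.mean
            exoxo = pat.cov + np.outer(exo, exo)
            T1[o] += pat.n * exo
            T2[np.ix_(o, o)] += pat.n * exoxo
            if len(miss):
                W = sigma[np.ix_(miss, o)] @ soo_inv
                exm = mu[miss] + W @ d
                V = sigma[np.ix_(miss, miss)] - W @ sigma[np.ix_(o, miss)]
                # cross moments: E[x_m x_o'] = mu_m exo' + W (exoxo - exo exo' ... )
                cross = np.outer(mu[miss] - W @ mu[o], exo) + W @ exoxo
                T1[miss] += pat.n * exm
                T2[np.ix_(miss, o)] += pat.n * cross
                T2[np.ix_(o, miss)] += pat.n * cross.T
                T2[np.ix_(miss, miss)] += pat.n * (
                    V + np.outer(mu[miss], mu[miss]) + np.outer(W @ d, mu[miss])
                    + np.outer(mu[miss], W @ d)
                    + W @ exoxo @ W.T - np.outer(W @ exo, W @ mu[o]) - np.outer(W @ mu[o], W @ exo)
                    + np.outer(W @ mu[o], W @ mu[o])
                )
        mu = T1 / n_total
        sigma = T2 / n_total - np.outer(mu, mu)
        sigma = (sigma + sigma.T) / 2
        cur = _fiml_neg2ll(patterns, sigma, mu)
        if abs(prev - cur) < tol * (1 + abs(cur)):
            break
        prev = cur
    return mu, sigma, _fiml_neg2ll(patterns, sigma, mu)


def _independence_neg2ll(patterns: list[_PatternStats], p: int) -> float:
    """-2 lnL of the independence model: per-variable univariate normal MLEs."""
    # independence factorises the likelihood across variables, so the MLE per
    # variable uses exactly its observed values
    n_j = np.zeros(p)
    s1 = np.zeros(p)
    s2 = np.zeros(p)
    for pat in patterns:
        o = pat.obs_idx
        n_j[o] += pat.n
        s1[o] += pat.n * pat.mean
        s2[o] += pat.n * (np.diag(pat.cov) + pat.mean**2)
    total = 0.0
    for j in range(p):
        if n_j[j] == 0:
            continue
        mean = s1[j] / n_j[j]
        var = s2[j] / n_j[j] - mean**2
        total += n_j[j] * (np.log(2 * np.pi) + np.log(var) + 1.0)
    return total


# ---------------------------------------------------------------------------
# optimisation and post-processing


def _fisher_scoring(objective, theta0: np.ndarray, hess_fn, tol: float, max_iter: int = 300):
    """Newton iterations on the expected information with backtracking."""
    theta = np.asarray(theta0, dtype=float).copy()
    f, g = objective.value_and_grad(theta)
    if f >= _BIG / 2:
        return theta, f, g, False

    def done(f, g):
        return float(np.max(np.abs(g))) < tol * (1.0 + abs(f))

    for _ in range(max_iter):
        if done(f, g):
            return theta, f, g, True
        H = hess_fn(theta)
        ridge = 0.0
        eye = np.eye(len(theta))
        step = None
        for _ in range(10):
            try:
                c, low = cho_factor(H + ridge * eye)
                step = -cho_solve((c, low), g)
                break
            except np.linalg.LinAlgError:
                ridge = max(ridge * 10.0, 1e-10 * max(np.abs(np.diag(H)).max(), 1.0))
        if step is None:
            break
        gd = float(g @ step)
        if gd >= 0:  # not a descent direction; re-ridge heavily
            step = -g / max(np.abs(np.diag(H)).max(), 1.0)
            gd = float(g @ step)
        alpha, accepted = 1.0, False
        for _ in range(50):
            fn, gn = objective.value_and_grad(theta + alpha * step)
            if fn < _BIG / 2 and fn <= f + 1e-4 * alpha * gd:
                theta = theta + alpha * step
                f, g = fn, gn
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
    return theta, f, g, done(f, g)


def _optimize(objective, theta0: np.ndarray, hess_fn, seed: int = 0):
    """Fisher scoring with L-BFGS fallback and jittered multi-starts."""
    rng = np.random.default_rng(seed)
    tol = GRADIENT_TOL
    best = None
    start = theta0
    for attempt in range(MULTISTART + 1):
        theta, f, g, ok = _fisher_scoring(objective, start, hess_fn, tol)
        if not ok:
            res = minimize(lambda th: objective.value_and_grad(th), theta, jac=True,
                           method="L-BFGS-B", options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12})
            if res.fun < f:
                theta, f, g = res.x, float(res.fun), np.asarray(res.jac)
            # one final scoring polish from the L-BFGS point
            theta, f, g, ok = _fisher_scoring(objective, theta, hess_fn, tol, max_iter=50)
            ok = ok or float(np.max(np.abs(g))) < 1e3 * tol * (1.0 + abs(f))
        if best is None or f < best[1]:
            best = (theta, f, ok)
        if ok:
            return theta, f, True
        start = theta0 * (1 + 0.2 * rng.standard_normal(len(theta0))) + 0.1 * rng.standard_normal(len(theta0))
    return best[0], best[1], best[2]


def _standardized_cells(ram: RAMMatrices, theta: np.ndarray) -> dict[str, float]:
    """Per-cell standardized solution from the implied total covariance."""
    A, S, m = ram.materialize(theta)
    B = _b_matrix(A)
    sigma_all = B @ S @ B.T
    sd = np.sqrt(np.clip(np.diag(sigma_all), 1e-300, None))
    out: dict[str, float] = {}
    for i in range(ram.t):
        for j in range(ram.t):
            if A[i, j] != 0.0:
                out[f"{ram.names[i]}~{ram.names[j]}"] = A[i, j] * sd[j] / sd[i]
    for i in range(ram.t):
        for j in range(i, ram.t):
            if S[i, j] != 0.0 or i == j:
                key = f"{ram.names[min(i, j)]}~~{ram.names[max(i, j)]}" if i != j else f"{ram.names[i]}~~{ram.names[i]}"
                out[key] = S[i, j] / (sd[i] * sd[j])
    return out


def _admissibility_warnings(ram: RAMMatrices, theta: np.ndarray) -> list[str]:
    notes = []
    A, S, _ = ram.materialize(theta)
    for i in range(ram.t):
        if S[i, i] < 0:
            notes.append(f"negative variance estimate for {ram.names[i]} ({S[i, i]:.4g})")
    return notes


def _param_derivs(ram: RAMMatrices, theta: np.ndarray):
    """Per-free-parameter derivatives (dSigma_obs, dmu_obs) from the RAM identity."""
    A, S, m = ram.materialize(theta)
    B = _b_matrix(A)
    sigma_all = B @ S @ B.T
    p = ram.p
    derivs, dmus = [], []
    for label in ram.free_labels:
        dA = np.zeros((ram.t, ram.t))
        dS = np.zeros((ram.t, ram.t))
        dm = np.zeros(ram.t)
        for mat, i, j in ram.cells[label]:
            if mat == "A":
                dA[i, j] += 1.0
            elif mat == "S":
                dS[i, j] += 1.0
                if i != j:
                    dS[j, i] += 1.0
            else:
                dm[i] += 1.0
        dsig_all = B @ dA @ sigma_all + B @ dS @ B.T + sigma_all @ dA.T @ B.T
        derivs.append(dsig_all[:p, :p])
        dmus.append((B @ dA @ B @ m + B @ dm)[:p] if ram.mean_structure else None)
    return sigma_all[:p, :p], derivs, dmus


def _expected_information(ram: RAMMatrices, theta: np.ndarray, n_eff: int) -> np.ndarray:
    """Expected (Fisher) information of the free parameters for a summary fit."""
    sigma, derivs, dmus = _param_derivs(ram, theta)
    sigma_inv = np.linalg.inv(sigma)
    k = ram.n_free
    info = np.zeros((k, k))
    half_n = (n_eff - 1) / 2.0
    sd = [sigma_inv @ d for d in derivs]
    for a in range(k):
        for b in range(a, k):
            val = half_n * float(np.sum(sd[a] * sd[b].T))
            if ram.mean_structure:
                val += (n_eff - 1) * float(dmus[a] @ sigma_inv @ dmus[b])
            info[a, b] = info[b, a] = val
    return info


def _fiml_expected_hessian(ram: RAMMatrices, theta: np.ndarray, patterns: list["_PatternStats"]) -> np.ndarray:
    """Expected Hessian of -2 lnL over missingness patterns."""
    _, derivs, dmus = _param_derivs(ram, theta)
    A, S, m = ram.materialize(theta)
    B = _b_matrix(A)
    sigma = (B @ S @ B.T)[: ram.p, : ram.p]
    k = ram.n_free
    H = np.zeros((k, k))
    for pat in patterns:
        o = pat.obs_idx
        sinv = np.linalg.inv(sigma[np.ix_(o, o)])
        sd = [sinv @ d[np.ix_(o, o)] for d in derivs]
        dmo = [d[o] for d in dmus]
        for a in range(k):
            for b in range(a, k):
                val = pat.n * (float(np.sum(sd[a] * sd[b].T)) + 2.0 * float(dmo[a] @ sinv @ dmo[b]))
                H[a, b] += val
                if a != b:
                    H[b, a] += val
    return H


def _se_from_information(info: np.ndarray, labels: tuple[str, ...]) -> tuple[dict[str, float], list[str]]:
    notes = []
    try:
        acov = np.linalg.inv(info)
        var = np.diag(acov).copy()
        if np.any(var < 0):
            notes.append("negative variance in inverse information; SEs partially unavailable")
            var = np.where(var < 0, np.nan, var)
        se = dict(zip(labels, np.sqrt(var)))
    except np.linalg.LinAlgError:
        notes.append("information matrix singular; SEs unavailable")
        se = {lab: float("nan") for lab in labels}
    return se, notes


def _fd_hessian(objective, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Hessian via central differences of the analytic gradient."""
    k = len(theta)
    H = np.zeros((k, k))
    for j in range(k):
        h = rel_step * max(1.0, abs(theta[j]))
        up = theta.copy()
        up[j] += h
        dn = theta.copy()
        dn[j] -= h
        _, gu = objective.value_and_grad(up)
        _, gd = objective.value_and_grad(dn)
        H[:, j] = (gu - gd) / (2 * h)
    return (H + H.T) / 2


# ---------------------------------------------------------------------------
# public fitting API


def fit_ml(moments: MomentInput, spec: ModelSpec, seed: int = 0) -> FitResult:
    """Fit a model to sample moments by normal-theory maximum likelihood.

    The observed variables of `spec` must name columns of `moments`; the
    sample covariance is reordered to the spec's observed order.
    """
    ram = compile_ram(spec)
    idx = [moments.variables.names.index(v) for v in spec.observed]
    S_samp = moments.cov[np.ix_(idx, idx)]
    mean_samp = None if moments.mean is None else np.asarray(moments.mean)[idx]
    obj = _MLObjective(ram, S_samp, mean_samp, moments.n_eff)
    theta0 = _start_vector(ram, S_samp, mean_samp)
    scale = 2.0 / (moments.n_eff - 1)

    def hess_fn(th):
        return scale * _expected_information(ram, th, moments.n_eff)

    theta, f_val, converged = _optimize(obj, theta0, hess_fn, seed=seed)
    f_min = max(float(f_val), 0.0)
    if obj.mean_samp is None and f_min < 1e-12:
        f_min = 0.0
    chi2 = (moments.n_eff - 1) * f_min
    df = ram.n_moments() - ram.n_free
    info = _expected_information(ram, theta, moments.n_eff)
    se, se_notes = _se_from_information(info, ram.free_labels)
    notes = _admissibility_warnings(ram, theta) + se_notes
    if not converged:
        notes.append("optimizer did not converge after multi-start retries")
    return FitResult(
        model=spec.name,
        method="ml",
        estimates=dict(zip(ram.free_labels, theta)),
        se=se,
        std_estimates=_standardized_cells(ram, theta),
        discrepancy=f_min,
        loglik=None,
        chi_square=chi2,
        df=df,
        n_eff=moments.n_eff,
        n_free=ram.n_free,
        aic=chi2 + 2 * ram.n_free,
        aic_scale="relative",
        converged=converged,
        warnings=notes,
        ram=ram,
        theta=theta,
        spec=spec,
        data=moments,
    )


def fit_fiml(cohort, spec: ModelSpec, seed: int = 0) -> FitResult:
    """Fit a model to raw data with missing values by FIML.

    `cohort` is a :class:`~edusem.synthetic_cohort.CohortMatrix` (or any object
    with a ``data`` DataFrame).  Mean structure is switched on automatically;
    rows with no observed value are excluded (count recorded as a warning).
    """
    if not spec.mean_structure:
        spec = spec.with_mean_structure(True)
    ram = compile_ram(spec)
    x = cohort.data[list(spec.observed)].to_numpy(dtype=float)
    patterns, dropped = _pattern_stats(x)
    p = ram.p
    obj = _FIMLObjective(ram, patterns)
    # start from available-case moments
    mu_sat, sigma_sat, neg2ll_sat = _em_saturated(patterns, p)
    theta0 = _start_vector(ram, sigma_sat, mu_sat)
    theta, neg2ll, converged = _optimize(
        obj, theta0, lambda th: _fiml_expected_hessian(ram, th, patterns), seed=seed
    )
    neg2ll = float(neg2ll)
    chi2 = max(neg2ll - neg2ll_sat, 0.0)
    df = p * (p + 3) // 2 - ram.n_free
    H = _fd_hessian(obj, theta)
    se, se_notes = _se_from_information(H / 2.0, ram.free_labels)
    notes = _admissibility_warnings(ram, theta) + se_notes
    if dropped:
        notes.append(f"excluded {dropped} rows with no observed values")
    if not converged:
        notes.append("optimizer did not converge after multi-start retries")
    return FitResult(
        model=spec.name,
        method="fiml",
        estimates=dict(zip(ram.free_labels, theta)),
        se=se,
        std_estimates=_standardized_cells(ram, theta),
        discrepancy=neg2ll,
        loglik=-neg2ll / 2.0,
        chi_square=chi2,
        df=df,
        n_eff=sum(pat.n for pat in patterns),
        n_free=ram.n_free,
        aic=neg2ll + 2 * ram.n_free,
        aic_scale="loglik",
        converged=converged,
        warnings=notes,
        ram=ram,
        theta=theta,
        spec=spec,
        data=cohort,
        baseline_chi_square=max(_independence_neg2ll(patterns, p) - neg2ll_sat, 0.0),
        baseline_df=p * (p + 3) // 2 - 2 * p,
    )


def standardize(fit: FitResult) -> FitResult:
    """Return the fit with its standardized solution (idempotent).

    Standardized coefficients rescale every variable — latent and observed —
    to unit model-implied variance, putting paths in the correlation metric.
    """
    if not fit.converged:
        warnings.warn("standardizing a non-converged fit")
    if fit.std_estimates:
        return fit
    return replace(fit, std_estimates=_standardized_cells(fit.ram, fit.theta))


def _ml_baseline(fit: FitResult) -> tuple[float, int]:
    moments: MomentInput = fit.data
    idx = [moments.variables.names.index(v) for v in fit.spec.observed]
    S_samp = moments.cov[np.ix_(idx, idx)]
    p = len(idx)
    f_b = float(np.sum(np.log(np.diag(S_samp))) - np.linalg.slogdet(S_samp)[1])
    return (fit.n_eff - 1) * f_b, p * (p - 1) // 2


def fit_indices(fit: FitResult, baseline: FitResult | None = None) -> FitIndices:
    """RMSEA, CFI, TLI and AIC for one fit.

    The baseline is the independence model on the same variables and data
    (free variances, free means under FIML); it is computed in closed form
    when not supplied.  With df = 0, RMSEA and TLI are undefined (NaN).
    """
    if baseline is not None:
        chi_b, df_b = baseline.chi_square, baseline.df
    elif fit.method == "ml":
        chi_b, df_b = _ml_baseline(fit)
    else:
        chi_b, df_b = fit.baseline_chi_square, fit.baseline_df
    chi, df, n = fit.chi_square, fit.df, fit.n_eff
    if df > 0:
        rmsea = float(np.sqrt(max(chi - df, 0.0) / (df * (n - 1))))
        tli = ((chi_b / df_b) - (chi / df)) / ((chi_b / df_b) - 1.0)
    else:
        rmsea = float("nan")
        tli = float("nan")
    denom = max(chi_b - df_b, chi - df, 0.0)
    cfi = 1.0 - max(chi - df, 0.0) / denom if denom > 0 else 1.0
    return FitIndices(rmsea=rmsea, cfi=float(cfi), tli=float(tli), aic=fit.aic)


def compare(restricted: FitResult, full: FitResult, tol: float = 1e-6) -> ComparisonResult:
    """Likelihood-ratio comparison of two nested fits on the same data."""
    if restricted.method != full.method or restricted.n_eff != full.n_eff:
        raise ValueError("comparisons require the same method and data")
    delta_df = restricted.df - full.df
    delta_chi = restricted.chi_square - full.chi_square
    if delta_df <= 0 and restricted.df != full.df:
        raise ValueError("restricted model must have fewer free parameters")
    if delta_chi < -tol * (1 + abs(full.chi_square)):
        raise ValueError(
            f"restricted model fits better (delta chi2 = {delta_chi:.4g}); check nesting/convergence"
        )
    delta_chi = max(delta_chi, 0.0)
    p = float(stats.chi2.sf(delta_chi, delta_df)) if delta_df > 0 else 1.0
    return ComparisonResult(
        restricted=restricted.model,
        full=full.model,
        delta_chi_square=delta_chi,
        delta_df=delta_df,
        p_value=p,
        delta_aic=restricted.aic - full.aic,
    )


def _chi2_scale_objective(fit: FitResult, ram: RAMMatrices):
    """Objective on the chi-square scale for score tests, for either method."""
    if fit.method == "ml":
        moments: MomentInput = fit.data
        idx = [moments.variables.names.index(v) for v in fit.spec.observed]
        S_samp = moments.cov[np.ix_(idx, idx)]
        mean_samp = None if moments.mean is None else np.asarray(moments.mean)[idx]
        inner = _MLObjective(ram, S_samp, mean_samp, fit.n_eff)
        scale = fit.n_eff - 1

        class Obj:
            def value_and_grad(self, th):
                v, g = inner.value_and_grad(th)
                return scale * v, scale * g

        return Obj()
    x = fit.data.data[list(fit.spec.observed)].to_numpy(dtype=float)
    patterns, _ = _pattern_stats(x)
    return _FIMLObjective(ram, patterns)


def modification_indices(fit: FitResult, candidates: list[Path | Covariance]) -> dict[str, float]:
    """1-df score-test statistics for freeing currently fixed parameters.

    For each candidate the model is extended by that single parameter at zero
    and MI = g' H^{-1} g / 2 is evaluated at the fitted solution (g, H =
    gradient and Hessian of the chi-square-scale discrepancy), estimating the
    chi-square drop a refit with the parameter free would achieve.
    """
    if not fit.converged:
        raise ValueError("modification indices need a converged fit")
    out: dict[str, float] = {}
    for cand in candidates:
        label = cand.label or cand.default_label()
        if label in fit.estimates:
            raise ValueError(f"candidate {label!r} is already free")
        ext_spec = fit.spec.add(replace(cand, free=True, start=0.0))
        ram = compile_ram(ext_spec)
        theta = np.array([fit.estimates.get(lab, 0.0) for lab in ram.free_labels])
        obj = _chi2_scale_objective(fit, ram)
        _, g = obj.value_and_grad(theta)
        H = _fd_hessian(obj, theta)
        try:
            mi = 0.5 * float(g @ np.linalg.solve(H, g))
        except np.linalg.LinAlgError:
            mi = float("nan")
        out[label] = mi
    return out


def drop_test(fit: FitResult, label: str, seed: int = 0) -> ComparisonResult:
    """Refit with one parameter fixed at zero; likelihood-ratio test of the drop."""
    if label not in fit.estimates:
        raise KeyError(f"parameter {label!r} is not free in model {fit.model!r}")
    restricted_spec = replace(fit.spec.fix_parameter(label, 0.0), name=f"{fit.model}-drop({label})")
    if fit.method == "ml":
        restricted = fit_ml(fit.data, restricted_spec, seed=seed)
    else:
        restricted = fit_fiml(fit.data, restricted_spec, seed=seed)
    return compare(restricted, fit)
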