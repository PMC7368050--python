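"""Joint estimation of signature weights and the latent context distribution.

The estimator decomposes an observed 96-context mutation spectrum m (total
count N) into a sparse non-negative combination of catalog signatures S by
maximizing

    l(w, p) = sum_i { m_i log p_i - (alpha/2) (p_i - sum_k s_ik w_k)^2 }
              - lambda * sum_k c_k (gamma w_k + (1 - gamma) w_k^2)
    s.t. w_k >= 0,  p_i >= 0,  sum_i p_i = 1

The first term is the multinomial log-likelihood of the observed counts under
a latent context distribution p; the second ties p to the linear signature
fit with precision alpha = 1/sigma^2; the last is an L1 (or elastic-net)
penalty with per-signature penalty factors c_k that encode biological priors
(smaller c_k = stronger prior that signature k is active).

The objective is biconvex and is maximized by alternating convex search:
a penalized non-negative least-squares step in w (coordinate descent) and an
exact Lagrange-multiplier step in p (96 decoupled quadratics plus a scalar
root solve). alpha is re-estimated from the regression residuals after every
w-step, and lambda is tuned empirically by a context-block cross-validation
with a 0.5- or 1-standard-deviation rule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, nnls

from ._cd import nncd_path, solve_nncd
from .contexts import CONTEXTS_PER_CLASS, N_CONTEXTS, SUBSTITUTION_CLASSES
from .spectra import MutationSpectrum, SignatureCatalog

#: finite stand-in for an infinite alpha when the linear fit is exact
ALPHA_CAP = 1e8
#: penalty factor assigned to signatures with a zero OLS coefficient
ADAPTIVE_PENALTY_CAP = 1e6

_DEFAULT_GAMMA_GRID = tuple(np.round(np.linspace(0.1, 1.0, 10), 10))


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------


@dataclass
class PenaltyConfig:
    """Penalty settings: per-signature factors, lambda, elastic-net mixing.

    ``lam=None`` requests empirical tuning by cross-validation. ``gamma=1``
    is the pure L1 penalty; with ``elastic_net=True`` gamma is grid-searched
    jointly with lambda.
    """

    c: np.ndarray | None = None
    lam: float | None = None
    gamma: float = 1.0
    lambda_grid: np.ndarray | None = None
    sd_multiplier: float = 1.0
    elastic_net: bool = False
    gamma_grid: tuple[float, ...] = _DEFAULT_GAMMA_GRID

    def __post_init__(self) -> None:
        if self.c is not None:
            self.c = np.asarray(self.c, dtype=float)
            if np.any(self.c < 0) or not np.all(np.isfinite(self.c)):
                raise ValueError("penalty factors c must be finite and >= 0")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
            if g.ndim != 1 or g.size == 0 or np.any(g <= 0):
                raise ValueError("lambda_grid must be non-empty and strictly positive")
            self.lambda_grid = np.sort(g)[::-1]  # descending
        if self.sd_multiplier not in (0.5, 1.0):
            raise ValueError("sd_multiplier must be 0.5 or 1.0")


@dataclass(frozen=True)
class NoiseModel:
    """Precision of the linear signature fit, alpha = 1/sigma^2.

    ``alpha_min`` floors alpha so early iterations (p far from optimum) do
    not grossly overestimate sigma^2; ``confidence`` deflates the raw 1/sigma^2
    to guard against violated linear-model assumptions (e.g. unknown
    signatures). Defaults follow the published calibration (floor 400,
    confidence 0.1).
    """

    alpha: float = 400.0
    alpha_min: float = 400.0
    confidence: float = 0.1
    alpha_cap: float = ALPHA_CAP

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass(frozen=True)
class FitSettings:
    """Outer-loop controls for the alternating optimization."""

    epsilon: float = 1e-8
    t_max: int = 50
    retune_threshold: float = 1e-4
    cv_repeats: int = 20
    seed: int = 0
    update_alpha: bool = True

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.t_max < 1 or self.cv_repeats < 1:
            raise ValueError("epsilon > 0, t_max >= 1, cv_repeats >= 1 required")


@dataclass(frozen=True)
class PStepSolution:
    """Latent distribution update together with its Lagrange multiplier."""

    p: np.ndarray
    lagrange: float


@dataclass
class TuningResult:
    lam: float
    gamma: float
    mean_mse: np.ndarray  # (n_gamma, n_lambda) mean CV-MSE
    lambda_grid: np.ndarray
    gamma_grid: tuple[float, ...]
    all_zero: bool = False  # every grid point produced w = 0


@dataclass
class FitResult:
    """Outcome of one spectrum decomposition."""

    w: np.ndarray
    p: np.ndarray
    signature_names: list[str]
    alpha_final: float
    lambda_chosen: float
    gamma_chosen: float
    n_iterations: int
    converged: bool
    assigned_fraction: float
    objective_trace: np.ndarray
    seed: int

    @property
    def w_normalized(self) -> np.ndarray:
        """Weights as proportions of the assigned mass (raw w is canonical)."""
        s = self.w.sum()
        return self.w / s if s > 0 else self.w.copy()

    def active(self, threshold: float = 0.0) -> list[str]:
        return [n for n, v in zip(self.signature_names, self.w) if v > threshold]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "signature": self.signature_names,
                "raw_weight": self.w,
                "normalized_weight": self.w_normalized,
            }
        )


# ---------------------------------------------------------------------------
# penalty factors
# ---------------------------------------------------------------------------


def make_prior_penalties(
    signature_names: list[str], active: set[str] | list[str], prior_strength: float
) -> np.ndarray:
    """Penalty factors encoding prior belief that ``active`` signatures act.

    Active signatures get factor ``prior_strength`` (e.g. 0.5, 0.1 or 0.01 —
    smaller is a stronger prior), all others 1.
    """
    if not 0.0 < prior_strength <= 1.0:
        raise ValueError("prior_strength must lie in (0, 1]")
    unknown = sorted(set(active) - set(signature_names))
    if unknown:
        raise ValueError(f"unknown signature name(s) in prior: {unknown}")
    c = np.ones(len(signature_names))
    for name in active:
        c[signature_names.index(name)] = prior_strength
    return c


def adaptive_penalties(
    p: np.ndarray, S: np.ndarray, cap: float = ADAPTIVE_PENALTY_CAP
) -> np.ndarray:
    """Adaptive-LASSO penalty factors c = 1 / beta_OLS.

    beta_OLS is the non-negative ordinary least-squares fit of p on S;
    zero coefficients map to ``cap``, effectively excluding those signatures
    unless the data strongly demand them.
    """
    beta, _ = nnls(S, p)
    with np.errstate(divide="ignore"):
        c = np.where(beta > 1.0 / cap, 1.0 / np.maximum(beta, 1e-300), cap)
    return np.minimum(c, cap)


# ---------------------------------------------------------------------------
# w-step
# ---------------------------------------------------------------------------


def w_step(
    p: np.ndarray,
    S: np.ndarray | SignatureCatalog,
    noise: NoiseModel,
    pen: PenaltyConfig,
    w0: np.ndarray | None = None,
) -> np.ndarray:
    """Penalized non-negative least-squares update of the signature weights.

    Minimizes (alpha/2)||p - Sw||^2 + lambda sum_k c_k (gamma w_k +
    (1-gamma) w_k^2) over w >= 0 by cyclic coordinate descent with
    closed-form non-negative soft-thresholding updates.
    """
    if isinstance(S, SignatureCatalog):
        S = S.probabilities
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("p contains non-finite values")
    if pen.lam is None or pen.lam < 0:
        raise ValueError("w_step requires a fixed lambda >= 0")
    c = np.ones(S.shape[1]) if pen.c is None else pen.c
    if np.any(c < 0):
        raise ValueError("penalty factors must be >= 0")
    G = S.T @ S
    b = S.T @ p
    lam_eff = pen.lam / noise.alpha  # objective divided through by alpha
    return solve_nncd(G, b, c, lam_eff, pen.gamma, w0=w0)


def lambda_max(
    p: np.ndarray, S: np.ndarray, noise: NoiseModel, c: np.ndarray, gamma: float
) -> float:
    """Smallest lambda at which the pure-L1 solution is identically zero."""
    b = S.T @ p
    g = max(gamma, 1e-2)  # gamma = 0 has no finite zero threshold
    return float(noise.alpha * np.max(b / (np.maximum(c, 1e-300) * g)))


def default_lambda_grid(
    p: np.ndarray,
    S: np.ndarray,
    noise: NoiseModel,
    c: np.ndarray,
    gamma: float,
    n_points: int = 50,
    decades: float = 4.0,
) -> np.ndarray:
    """Descending log-spaced grid from lambda_max down to lambda_max * 10^-4."""
    lmax = lambda_max(p, S, noise, c, gamma)
    if lmax <= 0:
        lmax = 1.0
    return np.geomspace(lmax, lmax * 10.0 ** (-decades), n_points)


# ---------------------------------------------------------------------------
# p-step
# ---------------------------------------------------------------------------


def _p_roots(t: np.ndarray, s: np.ndarray) -> np.ndarray:
    # positive root of p^2 - t p - s/4 = 0, computed cancellation-free
    disc = np.sqrt(t * t + s)
    return np.where(t >= 0, 0.5 * (t + disc), 0.5 * s / (disc - t))


def p_step(
    m: np.ndarray | MutationSpectrum,
    p_tilde: np.ndarray,
    noise: NoiseModel,
) -> PStepSolution:
    """Exact update of the latent distribution given the fitted mean.

    Maximizes sum_i { m_i log p_i - (alpha/2)(p_i - ptilde_i)^2 } on the
    probability simplex. With a Lagrange multiplier L for the sum constraint
    each coordinate solves p_i^2 - (L/alpha + ptilde_i) p_i - m_i/alpha = 0;
    only the positive root is kept (the negative root violates p_i >= 0), so
    p_i = 0 exactly where m_i = 0. L is the unique scalar making the
    coordinates sum to 1, found by bracketed root finding.
    """
    if isinstance(m, MutationSpectrum):
        m = m.counts
    m = np.asarray(m, dtype=float)
    p_tilde = np.asarray(p_tilde, dtype=float)
    alpha = noise.alpha
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    N = m.sum()
    if N <= 0:
        raise ValueError("p_step needs at least one observed mutation")
    pos = m > 0
    s = 4.0 * m[pos] / alpha
    pt = p_tilde[pos]

    def psum(lam: float) -> float:
        return float(_p_roots(pt + lam / alpha, s).sum())

    # sum(lam) is strictly increasing; bracket around the exact-sampling
    # solution lam = -N and expand geometrically.
    lo, hi = -float(N), 0.0
    step = max(float(N), alpha, 1.0)
    while psum(lo) >= 1.0:
        lo -= step
        step *= 2.0
    step = max(float(N), alpha, 1.0)
    while psum(hi) <= 1.0:
        hi += step
        step *= 2.0
    lam = brentq(lambda x: psum(x) - 1.0, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=300)

    p = np.zeros_like(m)
    p[pos] = _p_roots(pt + lam / alpha, s)
    return PStepSolution(p=p, lagrange=float(lam))


# ---------------------------------------------------------------------------
# alpha estimation
# ---------------------------------------------------------------------------


def estimate_alpha(
    residual_sse: float, k_nonzero: int, n: int, noise: NoiseModel
) -> NoiseModel:
    """Update alpha from the linear-fit residuals: sigma^2 = SSE / (n - k).

    alpha is the confidence-deflated reciprocal, floored at ``alpha_min``
    and capped at ``alpha_cap`` (the SSE = 0 case maps to the cap, not
    infinity).
    """
    if residual_sse < 0:
        raise ValueError("SSE must be >= 0")
    if k_nonzero >= n:
        raise ValueError(f"degrees of freedom exhausted: k={k_nonzero} >= n={n}")
    if residual_sse == 0.0:
        alpha_raw = noise.alpha_cap
    else:
        sigma2 = residual_sse / (n - k_nonzero)
        alpha_raw = noise.confidence / sigma2
    alpha = min(noise.alpha_cap, max(noise.alpha_min, alpha_raw))
    return dataclasses.replace(noise, alpha=alpha)


# ---------------------------------------------------------------------------
# lambda tuning by context-block cross-validation
# ---------------------------------------------------------------------------


def cv_partition(rng: np.random.Generator) -> list[np.ndarray]:
    """Split the 96 contexts into 8 blocks of 12, 2 per substitution class.

    Contexts of the same substitution class are correlated, so every block
    holds exactly two randomly chosen contexts from each of the 6 classes.
    """
    blocks: list[list[int]] = [[] for _ in range(8)]
    for cls in range(len(SUBSTITUTION_CLASSES)):
        perm = rng.permutation(CONTEXTS_PER_CLASS) + cls * CONTEXTS_PER_CLASS
        for b in range(8):
            blocks[b].extend(perm[2 * b : 2 * b + 2])
    return [np.sort(np.array(b)) for b in blocks]


def tune_lambda(
    p: np.ndarray,
    S: np.ndarray | SignatureCatalog,
    noise: NoiseModel,
    pen: PenaltyConfig,
    settings: FitSettings,
    rng: np.random.Generator | None = None,
    partitions: list[list[np.ndarray]] | None = None,
) -> TuningResult:
    """Choose lambda (and gamma under elastic net) by blocked CV on contexts.

    For every candidate on the grid, weights are fitted on 84 contexts and
    scored by the mean squared error on the 12 held-out contexts; the 8
    blocks are cycled and the whole partition repeated ``cv_repeats`` times.
    The returned lambda is the largest one (sparsest solution) whose mean
    CV-MSE is within ``sd_multiplier`` standard deviations (across repeats,
    at the minimizing grid point) of the minimum. Under elastic net the
    largest gamma, then the largest lambda, within the band is picked.
    """
    if isinstance(S, SignatureCatalog):
        S = S.probabilities
    p = np.asarray(p, dtype=float)
    c = np.ones(S.shape[1]) if pen.c is None else pen.c
    gammas = tuple(pen.gamma_grid) if pen.elastic_net else (pen.gamma,)
    if pen.lambda_grid is not None:
        grid = pen.lambda_grid
    else:
        grid = default_lambda_grid(p, S, noise, c, min(gammas))
    n_lam, n_gam = len(grid), len(gammas)
    lam_eff = np.ascontiguousarray(grid / noise.alpha)

    if rng is None:
        rng = np.random.default_rng(settings.seed)
    if partitions is None:
        partitions = [cv_partition(rng) for _ in range(settings.cv_repeats)]
    n_rep = len(partitions)

    # fold-level CV MSE, shape (n_rep * 8 folds, n_gam, n_lam)
    n_folds = len(partitions[0])
    fold_mse = np.zeros((n_rep * n_folds, n_gam, n_lam))
    any_nonzero = False
    cvec = np.ascontiguousarray(c, dtype=float)
    row = 0
    for blocks in partitions:
        for test_idx in blocks:
            mask = np.ones(N_CONTEXTS, dtype=bool)
            mask[test_idx] = False
            S_tr, S_te = S[mask], S[test_idx]
            G = np.ascontiguousarray(S_tr.T @ S_tr)
            b = np.ascontiguousarray(S_tr.T @ p[mask])
            p_te = p[test_idx]
            for g, gamma in enumerate(gammas):
                W = nncd_path(G, b, cvec, lam_eff, float(gamma), 1e-13, 100_000)
                if not any_nonzero and np.any(W != 0):
                    any_nonzero = True
                resid = p_te[None, :] - W @ S_te.T
                fold_mse[row, g] = np.mean(resid * resid, axis=1)
            row += 1

    mean_mse = fold_mse.mean(axis=0)
    g_min, j_min = np.unravel_index(np.argmin(mean_mse), mean_mse.shape)
    # SD of the held-out fold MSEs at the minimizing grid point
    sd = fold_mse[:, g_min, j_min].std(ddof=1) if fold_mse.shape[0] > 1 else 0.0
    band = mean_mse[g_min, j_min] + pen.sd_multiplier * sd

    if not any_nonzero:
        return TuningResult(
            lam=float(grid[0]),
            gamma=float(max(gammas)),
            mean_mse=mean_mse,
            lambda_grid=grid,
            gamma_grid=gammas,
            all_zero=True,
        )

    # largest gamma, then largest lambda (grid is descending), within band
    for g in reversed(range(n_gam)):
        in_band = np.where(mean_mse[g] <= band)[0]
        if in_band.size:
            return TuningResult(
                lam=float(grid[in_band[0]]),
                gamma=float(gammas[g]),
                mean_mse=mean_mse,
                lambda_grid=grid,
                gamma_grid=gammas,
            )
    raise AssertionError("unreachable: the minimizing grid point is in its own band")


# ---------------------------------------------------------------------------
# objective and outer loop
# ---------------------------------------------------------------------------


def objective(
    m: np.ndarray,
    p: np.ndarray,
    p_tilde: np.ndarray,
    w: np.ndarray,
    alpha: float,
    lam: float,
    gamma: float,
    c: np.ndarray,
) -> float:
    """Penalized joint log-likelihood (up to the multinomial constant)."""
    pos = m > 0
    ll = float(np.sum(m[pos] * np.log(p[pos])))
    ll -= 0.5 * alpha * float(np.sum((p - p_tilde) ** 2))
    ll -= lam * float(np.sum(c * (gamma * w + (1.0 - gamma) * w * w)))
    return ll


def fit(
    spectrum: MutationSpectrum,
    catalog: SignatureCatalog,
    pen: PenaltyConfig | None = None,
    noise: NoiseModel | None = None,
    settings: FitSettings | None = None,
) -> FitResult:
    """Decompose a mutation spectrum into sparse signature weights.

    Initializes the latent distribution at the sampling MLE m/N, then
    alternates the w-step and the p-step. alpha is re-estimated after every
    w-step; lambda is tuned by CV at the start and re-tuned whenever p moves
    by more than ``retune_threshold`` (squared L2) in one iteration, and
    frozen otherwise so CV subsetting noise cannot stall convergence. Stops
    when the squared L2 change of p drops below ``epsilon`` or after
    ``t_max`` iterations.
    """
    pen = PenaltyConfig() if pen is None else pen
    noise = NoiseModel() if noise is None else noise
    settings = FitSettings() if settings is None else settings

    m = spectrum.counts
    N = spectrum.total
    if N == 0:
        raise ValueError("cannot fit an empty spectrum (N = 0)")
    S = catalog.probabilities
    K = catalog.n_signatures
    c = np.ones(K) if pen.c is None else pen.c

    rng = np.random.default_rng(settings.seed)
    p = m / N
    w = np.zeros(K)
    gamma = pen.gamma
    tuning_enabled = pen.lam is None
    need_tune = tuning_enabled
    # The tuned penalty is carried across iterations on the least-squares
    # scale (lambda / alpha): that is the quantity the CV folds actually
    # validated, and it keeps the w-step problem invariant when alpha is
    # re-estimated between iterations. A user-fixed lambda keeps the
    # absolute scale of the joint objective.
    lam_eff = None if tuning_enabled else pen.lam / noise.alpha
    trace: list[float] = []
    converged = False
    n_iter = 0

    for t in range(settings.t_max):
        if need_tune:
            tuned = tune_lambda(p, S, noise, pen, settings, rng=rng)
            lam_eff, gamma = tuned.lam / noise.alpha, tuned.gamma
            need_tune = False
        lam = lam_eff * noise.alpha if tuning_enabled else pen.lam
        step_pen = dataclasses.replace(pen, c=c, lam=lam, gamma=gamma)
        w = w_step(p, S, noise, step_pen, w0=w)
        p_tilde = S @ w
        if settings.update_alpha:
            sse = float(np.sum((p - p_tilde) ** 2))
            k_nonzero = int(np.count_nonzero(w))
            noise = estimate_alpha(sse, k_nonzero, N_CONTEXTS, noise)
        sol = p_step(m, p_tilde, noise)
        dp = float(np.sum((sol.p - p) ** 2))
        p = sol.p
        trace.append(objective(m, p, p_tilde, w, noise.alpha, lam, gamma, c))
        n_iter = t + 1
        if tuning_enabled and dp > settings.retune_threshold:
            need_tune = True
        if dp < settings.epsilon:
            converged = True
            break

    return FitResult(
        w=w,
        p=p,
        signature_names=list(catalog.signature_names),
        alpha_final=noise.alpha,
        lambda_chosen=float(lam),
        gamma_chosen=float(gamma),
        n_iterations=n_iter,
        converged=converged,
        assigned_fraction=float(w.sum()),
        objective_trace=np.array(trace),
        seed=settings.seed,
    )
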