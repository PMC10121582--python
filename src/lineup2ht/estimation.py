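"""Maximum-likelihood estimation of the 2-HT model.

The likelihood is product-multinomial: per condition, the culprit-present and
culprit-absent trees are independent multinomial samples over three outcome
categories whose probabilities come from
:func:`lineup2ht.model.category_probabilities`.

The primary optimizer is the classical expectation–maximization algorithm for
multinomial processing tree models: each observed category count is
distributed over the latent branches that terminate in that category
(E-step), and every free parameter is re-estimated as the ratio of its
expected "success" traversals to all its traversals (M-step).  EM respects
the [0, 1] box constraints by construction and handles boundary solutions
(e.g. b = 0) gracefully.  A projected quasi-Newton optimizer (L-BFGS-B) is
available as an independent cross-check via ``method="lbfgs"``.

Goodness of fit is the likelihood-ratio statistic
``G² = 2 Σ obs · ln(obs / expected)`` (zero-count cells contribute 0),
asymptotically chi-square with ``df = 4 · n_conditions − n_free``.
Standard errors come from the inverse expected Fisher information at the MLE;
estimates on the boundary are flagged because their asymptotics are
distorted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .data_io import ResponseTable
from .model import PARAM_NAMES, Fix, ModelSpec, category_probabilities

__all__ = [
    "FitOptions",
    "FitResult",
    "log_likelihood",
    "fit",
    "expected_counts",
    "standard_errors",
    "saturated_log_likelihood",
]

_BOUNDARY_TOL = 1e-6

# Branch table of the two trees. Each latent branch is (category index in the
# flat 6-category order, success-exponent row, failure-exponent row, constant
# factor kind). Parameter columns follow PARAM_NAMES = (dP, g, b, dA);
# constant kind: 0 -> 1, 1 -> c, 2 -> (1 - c).
_BRANCHES: list[tuple[int, tuple[int, int, int, int], tuple[int, int, int, int], int]] = [
    # culprit-present tree
    (0, (1, 0, 0, 0), (0, 0, 0, 0), 0),  # detect culprit -> suspect ID
    (0, (0, 0, 1, 0), (1, 0, 0, 0), 0),  # no detection, biased selection
    (0, (0, 1, 0, 0), (1, 0, 1, 0), 1),  # no detection, guess, hits suspect
    (1, (0, 1, 0, 0), (1, 0, 1, 0), 2),  # no detection, guess, hits filler
    (2, (0, 0, 0, 0), (1, 1, 1, 0), 0),  # no detection, no selection -> reject
    # culprit-absent tree
    (5, (0, 0, 0, 1), (0, 0, 0, 0), 0),  # detect absence -> reject
    (3, (0, 0, 1, 0), (0, 0, 0, 1), 0),  # no detection, biased selection
    (3, (0, 1, 0, 0), (0, 0, 1, 1), 1),  # no detection, guess, hits suspect
    (4, (0, 1, 0, 0), (0, 0, 1, 1), 2),  # no detection, guess, hits filler
    (5, (0, 0, 0, 0), (0, 1, 1, 1), 0),  # no detection, no selection -> reject
]
_BRANCH_CAT = np.array([b[0] for b in _BRANCHES])
_BRANCH_A = np.array([b[1] for b in _BRANCHES])          # (10, 4) success exponents
_BRANCH_B = np.array([b[2] for b in _BRANCHES])          # (10, 4) failure exponents
_BRANCH_CONST_KIND = np.array([b[3] for b in _BRANCHES])
_CAT_OF_BRANCH = np.zeros((10, 6))
_CAT_OF_BRANCH[np.arange(10), _BRANCH_CAT] = 1.0


def _branch_constants(c: float) -> np.ndarray:
    return np.choose(_BRANCH_CONST_KIND, [1.0, c, 1.0 - c])


def _branch_probabilities(theta: np.ndarray, c: float) -> np.ndarray:
    """Branch probabilities per condition, shape ``(n_conditions, 10)``."""
    t = theta[:, None, :]  # (ncond, 1, 4)
    succ = np.where(_BRANCH_A.astype(bool), t, 1.0)
    fail = np.where(_BRANCH_B.astype(bool), 1.0 - t, 1.0)
    return _branch_constants(c) * np.prod(succ * fail, axis=2)


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings.

    ``tolerance`` is the absolute log-likelihood change at which EM stops;
    ``n_restarts`` uniform random starting points (plus one central start at
    0.5) are tried and the best log-likelihood wins, ties broken by lowest
    restart index.  ``seed`` makes the restarts deterministic.
    """

    tolerance: float = 1e-10
    max_iter: int = 10_000
    n_restarts: int = 10
    seed: int = 0
    method: str = "em"  # "em" or "lbfgs"


@dataclass(frozen=True)
class FitResult:
    """MLE of a :class:`~lineup2ht.model.ModelSpec` on a :class:`ResponseTable`."""

    spec: ModelSpec
    free_names: tuple[str, ...]
    free_estimates: np.ndarray
    standard_errors: np.ndarray
    log_likelihood: float
    g_squared: float
    df: int
    p_value: float
    converged: bool
    n_restarts_used: int
    n_iterations: int
    boundary_flags: tuple[str, ...]
    se_flags: tuple[str, ...] = ()

    @property
    def estimates(self) -> dict[str, dict[str, float]]:
        """Expanded per-condition parameter estimates."""
        return self.spec.parameter_table(self.free_estimates)

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Free estimates rounded for presentation, keyed by free-slot label."""
        return {
            name: round(float(v), ndigits)
            for name, v in zip(self.free_names, self.free_estimates)
        }

    def to_dict(self) -> dict:
        return {
            "model": self.spec.to_dict(),
            "free_parameters": {
                name: {
                    "estimate": float(v),
                    "se": None if not np.isfinite(se) else float(se),
                }
                for name, v, se in zip(
                    self.free_names, self.free_estimates, self.standard_errors
                )
            },
            "estimates_by_condition": self.estimates,
            "log_likelihood": float(self.log_likelihood),
            "g_squared": float(self.g_squared),
            "df": int(self.df),
            "p_value": float(self.p_value),
            "converged": bool(self.converged),
            "n_restarts_used": int(self.n_restarts_used),
            "n_iterations": int(self.n_iterations),
            "boundary_flags": list(self.boundary_flags),
            "se_flags": list(self.se_flags),
        }


def _check_alignment(spec: ModelSpec, data: ResponseTable) -> ResponseTable:
    if set(spec.condition_names) != set(data.condition_names):
        raise ValueError(
            f"model conditions {spec.condition_names} do not match "
            f"data conditions {data.condition_names}"
        )
    if data.condition_names != spec.condition_names:
        data = data.reordered(spec.condition_names)
    return data


def log_likelihood(
    free_vector: Sequence[float], spec: ModelSpec, data: ResponseTable
) -> float:
    """Product-multinomial log-likelihood kernel ``Σ n · ln p``.

    Returns ``-inf`` when a category with positive observed count has zero
    probability; zero-count categories never contribute, so an all-zero table
    yields 0 by convention.
    """
    data = _check_alignment(spec, data)
    theta = spec.expand(free_vector)
    probs = category_probabilities(theta, spec.design)
    counts = data.flat_counts
    pos = counts > 0
    if np.any(probs[pos] <= 0.0):
        return float("-inf")
    return float(np.sum(counts[pos] * np.log(probs[pos])))


def saturated_log_likelihood(data: ResponseTable) -> float:
    """Kernel log-likelihood of the saturated model (p̂ = observed proportions)."""
    counts = data.counts.astype(float)
    totals = counts.sum(axis=2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, counts / totals, 0.0)
        terms = np.where(counts > 0, counts * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return float(terms.sum())


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _em_structures(spec: ModelSpec):
    """Pre-compute index arrays for fast expansion and the M-step.

    Returns the free slots, the M-step membership list, an integer map from
    ``(condition, parameter)`` to free-slot index (−1 for fixed parameters)
    and the matrix of fixed values.
    """
    slots, assignment = spec._slots()
    cond_idx = {c: i for i, c in enumerate(spec.condition_names)}
    members = []
    expand_map = np.full((spec.n_conditions, len(PARAM_NAMES)), -1, dtype=np.intp)
    fixed = np.zeros((spec.n_conditions, len(PARAM_NAMES)))
    for s, (param, conds) in enumerate(slots):
        j = PARAM_NAMES.index(param)
        rows = np.array([cond_idx[c] for c in conds])
        members.append((j, rows))
        expand_map[rows, j] = s
    for (param, cond), con in assignment.items():
        if isinstance(con, Fix):
            fixed[cond_idx[cond], PARAM_NAMES.index(param)] = con.value
    return slots, members, expand_map, fixed


def _fast_expand(free: np.ndarray, expand_map: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    theta = free[np.maximum(expand_map, 0)]
    return np.where(expand_map >= 0, theta, fixed)


def _em_run(
    start: np.ndarray,
    counts: np.ndarray,
    members,
    expand_map: np.ndarray,
    fixed: np.ndarray,
    c: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, bool, int]:
    """SQUAREM-accelerated EM.

    Plain EM converges only linearly and crawls when the MLE approaches a
    boundary; the squared extrapolation (two EM steps, then a step-length
    extrapolation along the change vectors, falling back to the plain EM
    result whenever the extrapolated point does not improve the likelihood)
    keeps every iterate an ascent step while converging orders of magnitude
    faster near boundaries.
    """
    pos = counts > 0

    def loglik(free: np.ndarray) -> float:
        theta = _fast_expand(free, expand_map, fixed)
        cat = _branch_probabilities(theta, c) @ _CAT_OF_BRANCH
        if np.any(cat[pos] <= 0):
            return -np.inf
        return float(np.sum(counts[pos] * np.log(cat[pos])))

    def em_step(free: np.ndarray) -> np.ndarray:
        theta = _fast_expand(free, expand_map, fixed)
        bp = _branch_probabilities(theta, c)            # (ncond, 10)
        cat = bp @ _CAT_OF_BRANCH                       # (ncond, 6)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(cat > 0, counts / np.where(cat > 0, cat, 1.0), 0.0)
        m = bp * ratio[:, _BRANCH_CAT]                  # expected branch counts
        out = free.copy()
        for s, (j, conds) in enumerate(members):
            num = float(np.sum(m[conds][:, _BRANCH_A[:, j] == 1]))
            den = num + float(np.sum(m[conds][:, _BRANCH_B[:, j] == 1]))
            if den > 0:
                out[s] = num / den
        return out

    x0 = start.copy()
    ll_old = loglik(x0)
    n_steps = 0
    while n_steps < max_iter:
        x1 = em_step(x0)
        x2 = em_step(x1)
        n_steps += 2
        r = x1 - x0
        v = (x2 - x1) - r
        vnorm = float(np.linalg.norm(v))
        if vnorm < 1e-15:
            x_new = x2
        else:
            alpha = -max(float(np.linalg.norm(r)) / vnorm, 1.0)
            x_new = np.clip(x0 - 2.0 * alpha * r + alpha * alpha * v, 0.0, 1.0)
            # stabilization: accept the extrapolation only if it ascends
            if loglik(x_new) < loglik(x2):
                x_new = x2
            else:
                x_new = em_step(x_new)
                n_steps += 1
        ll = loglik(x_new)
        if np.isfinite(ll) and abs(ll - ll_old) < tol:
            return x_new, ll, True, n_steps
        ll_old = ll
        x0 = x_new
    return x0, ll_old, False, n_steps


def _nll_for_lbfgs(expand_map: np.ndarray, fixed: np.ndarray, counts: np.ndarray, c: float):
    def nll(free: np.ndarray) -> float:
        theta = _fast_expand(np.clip(free, 0.0, 1.0), expand_map, fixed)
        probs = category_probabilities(theta, c)
        pos = counts > 0
        return -float(np.sum(counts[pos] * np.log(np.maximum(probs[pos], 1e-300))))

    return nll


def fit(
    spec: ModelSpec,
    data: ResponseTable,
    options: FitOptions | Mapping | None = None,
    compute_se: bool = True,
) -> FitResult:
    """Maximum-likelihood fit of ``spec`` to ``data``.

    Runs the optimizer from ``n_restarts + 1`` deterministic starting points
    (a central start at 0.5 plus seeded uniform draws) and keeps the best
    log-likelihood.  Never raises on non-convergence; the result carries
    ``converged=False`` instead.
    """
    if options is None:
        options = FitOptions()
    elif isinstance(options, Mapping):
        options = FitOptions(**options)
    data = _check_alignment(spec, data)
    counts = data.flat_counts.astype(float)
    c = spec.design.suspect_constant
    slots, members, expand_map, fixed = _em_structures(spec)
    n_free = len(slots)

    rng = np.random.default_rng(options.seed)
    starts = [np.full(n_free, 0.5)]
    starts += [rng.uniform(0.02, 0.98, size=n_free) for _ in range(options.n_restarts)]

    best: tuple[float, int, np.ndarray, bool, int] | None = None
    for i, start in enumerate(starts):
        if n_free == 0:
            free, ll, ok, it = np.empty(0), log_likelihood([], spec, data), True, 0
        elif options.method == "em":
            free, ll, ok, it = _em_run(
                start, counts, members, expand_map, fixed, c,
                options.tolerance, options.max_iter,
            )
        elif options.method == "lbfgs":
            res = optimize.minimize(
                _nll_for_lbfgs(expand_map, fixed, counts, c),
                start,
                method="L-BFGS-B",
                bounds=[(0.0, 1.0)] * n_free,
                options={"maxiter": options.max_iter, "ftol": 1e-14, "gtol": 1e-10},
            )
            free, ll, ok, it = np.clip(res.x, 0.0, 1.0), -res.fun, bool(res.success), res.nit
        else:
            raise ValueError(f"unknown method {options.method!r}")
        if best is None or ll > best[0] + 1e-12:
            best = (ll, i, free, ok, it)

    ll, best_idx, free, converged, n_iter = best
    g2, p, df = _gof(spec, data, free)
    boundary = tuple(
        name
        for name, v in zip(spec.free_parameter_names, free)
        if v <= _BOUNDARY_TOL or v >= 1.0 - _BOUNDARY_TOL
    )
    if compute_se and n_free:
        ses, se_flags = _expected_information_se(spec, data, free)
    else:
        ses, se_flags = np.full(n_free, np.nan), ()
    return FitResult(
        spec=spec,
        free_names=spec.free_parameter_names,
        free_estimates=free,
        standard_errors=ses,
        log_likelihood=ll,
        g_squared=g2,
        df=df,
        p_value=p,
        converged=converged,
        n_restarts_used=len(starts),
        n_iterations=n_iter,
        boundary_flags=boundary,
        se_flags=se_flags,
    )


def _gof(spec: ModelSpec, data: ResponseTable, free: np.ndarray) -> tuple[float, float, int]:
    expected = _expected_counts(spec, data, free)
    obs = data.flat_counts.astype(float)
    pos = obs > 0
    with np.errstate(divide="ignore"):
        g2 = 2.0 * float(np.sum(obs[pos] * np.log(obs[pos] / expected[pos])))
    g2 = max(g2, 0.0)
    df = spec.df
    p = float(stats.chi2.sf(g2, df)) if df > 0 else 1.0
    return g2, p, df


def _expected_counts(spec: ModelSpec, data: ResponseTable, free: np.ndarray) -> np.ndarray:
    theta = spec.expand(free)
    probs = category_probabilities(theta, spec.design)  # (ncond, 6)
    totals = data.tree_totals.astype(float)             # (ncond, 2)
    return probs * np.repeat(totals, 3, axis=1)


def expected_counts(fit_result: FitResult, data: ResponseTable) -> np.ndarray:
    """Model-implied counts, shape ``(n_conditions, 2, 3)`` in data-cell order.

    Per condition and lineup type the expected counts sum to the observed
    total (the multinomial totals are fixed by design).
    """
    data = _check_alignment(fit_result.spec, data)
    flat = _expected_counts(fit_result.spec, data, fit_result.free_estimates)
    return flat.reshape(data.n_conditions, 2, 3)


# ---------------------------------------------------------------------------
# Standard errors
# ---------------------------------------------------------------------------

def _category_prob_jacobian(spec: ModelSpec, free: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """d p_cat / d free, shape ``(ncond, 6, n_free)``, by central differences.

    Steps are pulled inside [0, 1] at the boundary (one-sided there).
    """
    c = spec.design.suspect_constant
    n_free = free.size
    jac = np.empty((spec.n_conditions, 6, n_free))
    for s in range(n_free):
        lo = max(free[s] - h, 0.0)
        hi = min(free[s] + h, 1.0)
        f_hi, f_lo = free.copy(), free.copy()
        f_hi[s], f_lo[s] = hi, lo
        p_hi = category_probabilities(spec.expand(f_hi), c)
        p_lo = category_probabilities(spec.expand(f_lo), c)
        jac[:, :, s] = (p_hi - p_lo) / (hi - lo)
    return jac


def expected_fisher_information(
    spec: ModelSpec, data: ResponseTable, free: np.ndarray
) -> np.ndarray:
    """Expected information of the free parameters at ``free``.

    ``I[s, t] = Σ_cond Σ_tree N_tree Σ_cat (∂p/∂θ_s)(∂p/∂θ_t) / p``.
    Categories with probability 0 are skipped (they carry no information and
    their limit contribution is 0 whenever the numerator vanishes faster).
    """
    data = _check_alignment(spec, data)
    theta = spec.expand(free)
    probs = category_probabilities(theta, spec.design)
    totals = np.repeat(data.tree_totals.astype(float), 3, axis=1)
    jac = _category_prob_jacobian(spec, free)
    w = np.where(probs > 1e-12, totals / np.maximum(probs, 1e-12), 0.0)
    return np.einsum("ck,cks,ckt->st", w, jac, jac)


def _expected_information_se(
    spec: ModelSpec, data: ResponseTable, free: np.ndarray
) -> tuple[np.ndarray, tuple[str, ...]]:
    info = expected_fisher_information(spec, data, free)
    names = spec.free_parameter_names
    flags: list[str] = []
    try:
        cov = np.linalg.inv(info)
        var = np.diag(cov).copy()
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
        var = np.diag(cov).copy()
        flags.append("singular information matrix; pseudo-inverse used")
    ses = np.where(var > 0, np.sqrt(np.maximum(var, 0.0)), np.nan)
    for name, v, est in zip(names, var, free):
        if not np.isfinite(v) or v <= 0:
            flags.append(f"SE undefined for {name}")
        if est <= _BOUNDARY_TOL or est >= 1.0 - _BOUNDARY_TOL:
            flags.append(
                f"{name} at boundary; SE from unconstrained information, interpret with caution"
            )
    return ses, tuple(flags)


def standard_errors(fit_result: FitResult, data: ResponseTable) -> np.ndarray:
    """Standard errors of the free parameters of a converged fit.

    Square roots of the diagonal of the inverse expected Fisher information
    at the MLE; ``nan`` marks parameters whose SE is undefined (singular
    information).  Boundary estimates are listed in ``fit_result.se_flags``.
    """
    ses, _ = _expected_information_se(
        fit_result.spec, _check_alignment(fit_result.spec, data), fit_result.free_estimates
    )
    return ses
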