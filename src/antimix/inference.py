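"""Maximum simulated likelihood estimation and LR-test diagnostics.

Estimation maximizes the simulated panel mixed logit log-likelihood over the
mixing means, the (lower-triangular) Choleski entries, and any fixed
coefficients, holding the quasi-random draw set fixed — the standard
simulated-ML setup in which likelihood values at different parameter points
are comparable because they share one draw set.

Likelihood-ratio testing compares restricted and unrestricted simulated
log-likelihoods against a chi-square.  With asymmetric draws the optimum can
land in any of the ``2**n`` sign quadrants of the Choleski factor, and the
simulated log-likelihood differs between quadrants even though the implied
covariance is identical; :func:`cross_quadrant_lr` tabulates the LR statistic
over every ordered (unrestricted-quadrant, restricted-quadrant) pair, whose
negative share and p-value spread are the diagnostic of interest.

When a zero-standard-deviation restriction removes one mixing dimension, the
restricted model's draws should keep the prime bases originally assigned to
the surviving dimensions (``keep_assigned``) rather than restart from the
first primes (``naive_first``); :func:`reduce_draw_config` implements both
policies and :func:`prime_policy_gap` measures the log-likelihood difference
they induce.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .mmnl_core import (
    ChoicePanel,
    MixingParams,
    QuadrantScanReport,
    all_quadrants,
    conventional_loglik,
    flip_factor,
    simulated_loglik,
)
from .qmc_draws import CANONICAL_PRIMES, DrawConfig, NormalDrawSet, build_draws

__all__ = [
    "RestrictionSpec",
    "FitResult",
    "LRTestResult",
    "CrossQuadrantReport",
    "MixedLogit",
    "fit",
    "lr_test",
    "rejection_threshold",
    "cross_quadrant_lr",
    "reduce_draw_config",
    "prime_policy_gap",
    "apply_mean_restriction",
    "apply_sd_zero_restriction",
    "starting_value_sweep",
]


@dataclass(frozen=True)
class RestrictionSpec:
    """A single parameter restriction on the mixing distribution.

    ``fix_mean`` pins the mean of one mixed parameter at ``value`` (its
    standard deviation stays free).  ``fix_sd_zero`` removes the mixing of
    one parameter entirely: its constant becomes a fixed (still estimated)
    coefficient and the draw configuration loses that dimension, with
    ``prime_policy`` deciding which primes the surviving dimensions use.
    """

    kind: str
    target: str
    value: float = 0.0
    prime_policy: str = "keep_assigned"

    def __post_init__(self) -> None:
        if self.kind not in ("fix_mean", "fix_sd_zero"):
            raise ValueError("kind must be 'fix_mean' or 'fix_sd_zero'")
        if self.prime_policy not in ("keep_assigned", "naive_first"):
            raise ValueError(
                "prime_policy must be 'keep_assigned' or 'naive_first'"
            )
        if self.kind == "fix_sd_zero" and self.value != 0.0:
            raise ValueError("fix_sd_zero restricts the SD to exactly zero")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one simulated-ML optimization."""

    params: MixingParams  # canonical quadrant (non-negative Choleski diagonal)
    raw_chol: np.ndarray  # signed estimate as the optimizer left it
    loglik: float
    converged: bool
    quadrant: tuple
    n_iter: int
    grad_norm: float
    restriction: RestrictionSpec | None = None


@dataclass(frozen=True)
class LRTestResult:
    """2 (LL_u - LL_r) against an upper-tail chi-square."""

    statistic: float
    df: int
    p_value: float
    negative_flag: bool


def lr_test(ll_unrestricted: float, ll_restricted: float, df: int) -> LRTestResult:
    """Likelihood-ratio test of a nested restriction.

    A negative statistic — impossible for exact likelihoods of nested models,
    but possible when restricted and unrestricted simulated values come from
    different quadrants — is flagged and its p-value reported as NaN
    (undefined by convention), never clipped to zero.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    statistic = 2.0 * (ll_unrestricted - ll_restricted)
    negative = statistic < 0.0
    p = float("nan") if negative else float(stats.chi2.sf(statistic, df))
    return LRTestResult(
        statistic=float(statistic), df=int(df), p_value=p, negative_flag=negative
    )


def rejection_threshold(alpha: float, df: int) -> float:
    """Minimum LL_u - LL_r that rejects at level ``alpha``: half the
    chi-square(df) critical value (1.92 for alpha = .05, df = 1)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.ppf(1.0 - alpha, df) / 2.0)


@dataclass(frozen=True)
class CrossQuadrantReport:
    """LR statistics over all ordered (unrestricted, restricted) quadrant pairs.

    Rows index the unrestricted scan's quadrants, columns the restricted
    scan's.  P-value summaries cover only the non-negative statistics, the
    negative ones being counted in ``share_negative``.
    """

    lr_matrix: np.ndarray
    p_values: np.ndarray  # NaN where the statistic is negative
    df: int
    share_negative: float
    p_min: float
    p_max: float
    p_sd: float

    @property
    def n_pairs(self) -> int:
        return self.lr_matrix.size

    def rejection_rate(self, alpha: float) -> float:
        """Share of positive-statistic pairs rejecting at level ``alpha``."""
        p = self.p_values[np.isfinite(self.p_values)]
        if p.size == 0:
            return float("nan")
        return float(np.mean(p < alpha))


def cross_quadrant_lr(
    scan_u: QuadrantScanReport, scan_r: QuadrantScanReport, df: int
) -> CrossQuadrantReport:
    """Cross every unrestricted quadrant value with every restricted one.

    With asymmetric draws the optimizer may leave the two models in different
    quadrants, so any ordered pair can occur in practice; the matrix shows
    the whole range of LR statistics a practitioner could have obtained.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    llu = scan_u.values[:, None]
    llr = scan_r.values[None, :]
    lr = 2.0 * (llu - llr)
    p = np.where(lr < 0.0, np.nan, stats.chi2.sf(np.clip(lr, 0.0, None), df))
    pos = p[np.isfinite(p)]
    if pos.size == 0:
        p_min = p_max = p_sd = float("nan")
    else:
        p_min = float(pos.min())
        p_max = float(pos.max())
        p_sd = float(pos.std(ddof=1)) if pos.size > 1 else 0.0
    return CrossQuadrantReport(
        lr_matrix=lr,
        p_values=p,
        df=int(df),
        share_negative=float(np.mean(lr < 0.0)),
        p_min=p_min,
        p_max=p_max,
        p_sd=p_sd,
    )


def reduce_draw_config(
    config: DrawConfig, removed_dim: str, policy: str = "keep_assigned"
) -> DrawConfig:
    """Drop one mixing dimension from a draw configuration.

    ``keep_assigned`` keeps each surviving dimension's originally assigned
    prime; ``naive_first`` reassigns the first n-1 canonical primes in order
    (the default behaviour of most estimation software).  Under full
    antithetics R must be a multiple of ``2**(n-1)``; if the incoming R is
    not (it always is when it was a multiple of ``2**n``), it is rounded up
    to the nearest valid multiple.
    """
    if policy not in ("keep_assigned", "naive_first"):
        raise ValueError("policy must be 'keep_assigned' or 'naive_first'")
    if removed_dim not in config.dim_names:
        raise KeyError(f"no mixing dimension named {removed_dim!r}")
    if config.n_dims == 1:
        raise ValueError(
            "cannot remove the last mixing dimension: the restricted model "
            "would have no mixing"
        )
    keep = [i for i, d in enumerate(config.dim_names) if d != removed_dim]
    names = tuple(config.dim_names[i] for i in keep)
    if policy == "keep_assigned":
        primes = tuple(config.primes[i] for i in keep)
    else:
        primes = CANONICAL_PRIMES[: len(keep)]
    n = config.n_dims - 1
    r = config.draws_per_individual
    if config.antithetic_mode == "full":
        block = 2**n
        if r % block:
            r = ((r // block) + 1) * block
    elif config.antithetic_mode == "one_dim" and r % 2:
        r += 1
    return replace(
        config,
        n_dims=n,
        primes=primes,
        dim_names=names,
        draws_per_individual=r,
    )


def apply_mean_restriction(
    params: MixingParams, dim: int, value: float = 0.0
) -> MixingParams:
    """Pin the mean of mixing dimension ``dim`` at ``value``."""
    means = params.means.copy()
    means[dim] = value
    return replace(params, means=means)


def apply_sd_zero_restriction(params: MixingParams, dim: int) -> MixingParams:
    """Remove mixing dimension ``dim``; its constant becomes fixed at its mean.

    The restricted mixing covariance is the original one with the removed
    dimension's row and column deleted (its variance, and hence all its
    covariances, are zero under the restriction); the surviving block is
    re-factorized to the canonical Choleski.
    """
    n = params.n_dims
    keep = [k for k in range(n) if k != dim]
    cov = params.covariance[np.ix_(keep, keep)]
    fixed = dict(params.fixed_asc)
    fixed[params.mixed_alts[dim]] = float(params.means[dim])
    return MixingParams(
        means=params.means[keep],
        chol=np.linalg.cholesky(cov),
        mixed_alts=tuple(params.mixed_alts[k] for k in keep),
        fixed_asc=fixed,
        fixed_coeffs=params.fixed_coeffs,
    )


def prime_policy_gap(
    panel: ChoicePanel,
    params_restricted: MixingParams,
    config: DrawConfig,
    removed_dim: str,
) -> float:
    """Restricted log-likelihood difference between prime policies.

    Evaluates the restricted simulated log-likelihood with draws reduced
    under ``keep_assigned`` and under ``naive_first`` (identical R) and
    returns LL(keep_assigned) - LL(naive_first).  Both are quasi-Monte Carlo
    approximations of the same integral, so the gap vanishes as R grows; at
    practical R it can exceed the LR rejection threshold.  With no surviving
    mixing dimension no draws enter at all and the gap is exactly zero.
    """
    if config.n_dims == 1:
        return 0.0
    ll = {}
    for policy in ("keep_assigned", "naive_first"):
        reduced = reduce_draw_config(config, removed_dim, policy)
        draws = build_draws(reduced)
        ll[policy] = simulated_loglik(panel, params_restricted, draws)
    return ll["keep_assigned"] - ll["naive_first"]


# ---------------------------------------------------------------------------
# estimation


def _tril_indices(n: int, diag_only: bool) -> tuple[np.ndarray, np.ndarray]:
    if diag_only:
        idx = np.arange(n)
        return idx, idx
    return np.tril_indices(n)


class MixedLogit(BaseEstimator):
    """Panel mixed multinomial logit fitted by maximum simulated likelihood.

    Parameters
    ----------
    draw_config : DrawConfig
        Quasi-random draw specification (primes, R, antithetic mode).  Under
        a ``fix_sd_zero`` restriction the configuration is reduced with the
        restriction's prime policy before draws are built.
    start : MixingParams
        Starting values; also fixes which alternatives are mixed and whether
        the Choleski factor is diagonal (no off-diagonal start entries) or
        full lower-triangular.
    restriction : RestrictionSpec, optional
        Restriction imposed during estimation.
    correlated : bool, optional
        Estimate the full lower triangle of the Choleski factor.  Default:
        inferred from the starting factor (True iff it has a nonzero
        off-diagonal entry).
    gtol : float
        Gradient max-norm convergence tolerance of the quasi-Newton search.
    maxiter : int
        Iteration cap.
    rel_step : float
        Relative step of the central-difference gradient.

    Attributes
    ----------
    params_ : MixingParams
        Estimate in the canonical quadrant (non-negative Choleski diagonal).
    raw_chol_ : ndarray
        Signed Choleski estimate as returned by the optimizer.
    quadrant_ : tuple
        Sign pattern of the raw Choleski diagonal.
    loglik_ : float
        Simulated log-likelihood at the optimum.
    converged_ : bool
    n_iter_ : int
    result_ : FitResult
    """

    def __init__(
        self,
        draw_config: DrawConfig = None,
        start: MixingParams = None,
        restriction: RestrictionSpec | None = None,
        correlated: bool | None = None,
        gtol: float = 1e-4,
        maxiter: int = 500,
        rel_step: float = 1e-6,
    ):
        self.draw_config = draw_config
        self.start = start
        self.restriction = restriction
        self.correlated = correlated
        self.gtol = gtol
        self.maxiter = maxiter
        self.rel_step = rel_step

    # -- parameter packing ---------------------------------------------------

    def _setup(self):
        if self.draw_config is None or self.start is None:
            raise ValueError("draw_config and start are required")
        config, start = self.draw_config, self.start
        if start.n_dims != config.n_dims:
            raise ValueError(
                f"start has {start.n_dims} mixing dimensions but draw_config "
                f"has {config.n_dims}"
            )
        restrictions = self.restriction
        if restrictions is None:
            restrictions = ()
        elif isinstance(restrictions, RestrictionSpec):
            restrictions = (restrictions,)
        fixed_mean = {}
        for restriction in restrictions:
            if config is None or restriction.target not in config.dim_names:
                raise KeyError(
                    f"restriction targets unknown dimension "
                    f"{restriction.target!r}"
                )
            k = config.dim_names.index(restriction.target)
            if restriction.kind == "fix_mean":
                start = apply_mean_restriction(start, k, restriction.value)
                fixed_mean[k] = restriction.value
            else:
                if k in fixed_mean:
                    raise ValueError(
                        "cannot remove a dimension whose mean is separately "
                        "restricted"
                    )
                start = apply_sd_zero_restriction(start, k)
                fixed_mean = {
                    (j if j < k else j - 1): v
                    for j, v in fixed_mean.items()
                    if j != k
                }
                if config.n_dims == 1:
                    # last mixing dimension removed: the restricted model is
                    # a conventional logit with fixed constants and no draws
                    config = None
                else:
                    config = reduce_draw_config(
                        config, restriction.target, restriction.prime_policy
                    )
        correlated = self.correlated
        if correlated is None:
            offdiag = start.chol - np.diag(np.diag(start.chol))
            correlated = bool(offdiag.size and np.abs(offdiag).max() > 0)
        return config, start, fixed_mean, correlated

    def _pack(self, params: MixingParams, fixed_mean, correlated) -> np.ndarray:
        n = params.n_dims
        free_means = [params.means[k] for k in range(n) if k not in fixed_mean]
        rows, cols = _tril_indices(n, not correlated)
        chol_entries = params.chol[rows, cols]
        fixed = [params.fixed_asc[a] for a in sorted(params.fixed_asc)]
        coeffs = [] if params.fixed_coeffs is None else list(params.fixed_coeffs)
        return np.concatenate([free_means, chol_entries, fixed, coeffs])

    def _unpack(self, theta, template: MixingParams, fixed_mean, correlated):
        n = template.n_dims
        free_idx = [k for k in range(n) if k not in fixed_mean]
        means = template.means.copy()
        pos = len(free_idx)
        means[free_idx] = theta[:pos]
        for k, v in fixed_mean.items():
            means[k] = v
        rows, cols = _tril_indices(n, not correlated)
        chol = np.zeros((n, n))
        chol[rows, cols] = theta[pos : pos + rows.size]
        pos += rows.size
        fixed_alts = sorted(template.fixed_asc)
        fixed = dict(zip(fixed_alts, theta[pos : pos + len(fixed_alts)]))
        pos += len(fixed_alts)
        coeffs = None
        if template.fixed_coeffs is not None:
            coeffs = theta[pos:]
        return MixingParams(
            means=means,
            chol=chol,
            mixed_alts=template.mixed_alts,
            fixed_asc=fixed,
            fixed_coeffs=coeffs,
        )

    # -- fitting -------------------------------------------------------------

    def fit(self, panel: ChoicePanel, y=None):
        config, start, fixed_mean, correlated = self._setup()
        draws = build_draws(config) if config is not None else None
        theta0 = self._pack(start, fixed_mean, correlated)

        def negll(theta):
            p = self._unpack(theta, start, fixed_mean, correlated)
            if draws is None:
                return -conventional_loglik(panel, p)
            return -simulated_loglik(panel, p, draws)

        rel = self.rel_step

        def grad(theta):
            g = np.empty_like(theta)
            for i in range(theta.size):
                h = rel * max(1.0, abs(theta[i]))
                tp, tm = theta.copy(), theta.copy()
                tp[i] += h
                tm[i] -= h
                g[i] = (negll(tp) - negll(tm)) / (2.0 * h)
            return g

        res = optimize.minimize(
            negll,
            theta0,
            jac=grad,
            method="BFGS",
            options={"gtol": self.gtol, "maxiter": self.maxiter},
        )
        grad_norm = float(np.abs(res.jac).max())
        params_hat = self._unpack(res.x, start, fixed_mean, correlated)
        diag = np.diag(params_hat.chol)
        quadrant = tuple(-1 if d < 0 else 1 for d in diag)
        canonical = replace(
            params_hat, chol=flip_factor(params_hat.chol, quadrant)
        )
        self.result_ = FitResult(
            params=canonical,
            raw_chol=params_hat.chol,
            loglik=float(-res.fun),
            converged=bool(res.success or grad_norm <= self.gtol),
            quadrant=quadrant,
            n_iter=int(res.nit),
            grad_norm=grad_norm,
            restriction=self.restriction,
        )
        self.params_ = canonical
        self.raw_chol_ = params_hat.chol
        self.quadrant_ = quadrant
        self.loglik_ = self.result_.loglik
        self.converged_ = self.result_.converged
        self.n_iter_ = self.result_.n_iter
        return self


def fit(
    panel: ChoicePanel,
    draw_config: DrawConfig,
    start: MixingParams,
    restriction: RestrictionSpec | None = None,
    **options,
) -> FitResult:
    """Maximize the simulated log-likelihood; see :class:`MixedLogit`."""
    est = MixedLogit(
        draw_config=draw_config, start=start, restriction=restriction, **options
    )
    est.fit(panel)
    return est.result_


def starting_value_sweep(
    panel: ChoicePanel,
    draw_config: DrawConfig,
    start: MixingParams,
    n_starts: int,
    scale: float = 0.5,
    seed: int = 0,
    restriction: RestrictionSpec | None = None,
    **options,
) -> list[FitResult]:
    """Re-fit from ``n_starts`` perturbed starting points.

    Perturbs the starting means and Choleski entries uniformly within
    ``+-scale`` (seeded), the standard robustness check for simulated
    likelihoods: with asymmetric draws the optima scatter across quadrants
    with differing log-likelihoods, with fully antithetic draws they agree to
    optimizer tolerance.
    """
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_starts):
        means = start.means + rng.uniform(-scale, scale, start.n_dims)
        chol = start.chol + np.tril(
            rng.uniform(-scale, scale, start.chol.shape)
        )
        perturbed = replace(start, means=means, chol=chol)
        results.append(
            fit(panel, draw_config, perturbed, restriction=restriction, **options)
        )
    return results
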