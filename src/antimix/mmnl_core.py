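"""Panel mixed multinomial logit likelihood and quadrant diagnostics.

The panel mixed logit likelihood for individual i integrates the product of
conditional logit choice probabilities over the mixing distribution of the
random coefficients beta_i:

    L_i(theta) = E_beta[ prod_t P(chosen_it | beta) ],   beta ~ N(b, QQ')

and the simulated likelihood replaces the expectation by an average over R
quasi-random draws z_ir,

    SL_i = (1/R) sum_r prod_t P(chosen_it | b + Q z_ir),

with Q a lower-triangular Choleski factor of the mixing covariance.  Because
the covariance QQ' is invariant to flipping the sign of any column of Q,
``2**n`` distinct factorizations — one per sign "quadrant" — parameterize the
same model.  The true likelihood is identical across quadrants; the simulated
one is identical only if the draw set is symmetric under every coordinate
sign flip.  :func:`quadrant_scan` measures the departure.

All panel products are kept in log space; the draw average uses a
per-individual log-sum-exp (a 20-fold product of choice probabilities
underflows in raw space).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .qmc_draws import NormalDrawSet

__all__ = [
    "ChoicePanel",
    "MixingParams",
    "QuadrantSigns",
    "QuadrantScanReport",
    "logit_choice_prob",
    "panel_logprob_given_beta",
    "transform_draws",
    "simulated_loglik",
    "flip_factor",
    "all_quadrants",
    "quadrant_scan",
]


@dataclass(frozen=True)
class ChoicePanel:
    """Panel of discrete choices over a fixed universe of J alternatives.

    Parameters
    ----------
    chosen
        One integer array per individual giving the chosen alternative index
        in each of that individual's T_i choice situations.
    n_alts
        Number of alternatives J (alternative indices are 0 .. J-1).
    base_alt
        Alternative whose systematic utility is fixed at zero.
    alt_labels
        Optional display labels, defaults to ``alt_0 .. alt_{J-1}``.
    attributes
        Optional per-individual arrays of shape (T_i, J, K) of alternative
        attributes entering utility through fixed coefficients.
    attr_names
        Labels for the K attribute columns.
    """

    chosen: tuple
    n_alts: int
    base_alt: int = 0
    alt_labels: tuple[str, ...] = ()
    attributes: tuple | None = None
    attr_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_alts < 2:
            raise ValueError("need at least 2 alternatives")
        if not (0 <= self.base_alt < self.n_alts):
            raise ValueError("base_alt out of range")
        ch = tuple(np.asarray(c, dtype=np.intp) for c in self.chosen)
        if not ch:
            raise ValueError("panel must contain at least one individual")
        for c in ch:
            if c.ndim != 1 or c.size < 1:
                raise ValueError("each individual needs >= 1 choice situation")
            if (c < 0).any() or (c >= self.n_alts).any():
                raise ValueError("chosen alternative index out of range")
        object.__setattr__(self, "chosen", ch)
        labels = tuple(self.alt_labels)
        if not labels:
            labels = tuple(f"alt_{j}" for j in range(self.n_alts))
        if len(labels) != self.n_alts:
            raise ValueError("alt_labels length must equal n_alts")
        object.__setattr__(self, "alt_labels", labels)
        if self.attributes is not None:
            attrs = tuple(np.asarray(a, dtype=float) for a in self.attributes)
            if len(attrs) != len(ch):
                raise ValueError("attributes must match individuals")
            k = attrs[0].shape[-1]
            for a, c in zip(attrs, ch):
                if a.shape != (c.size, self.n_alts, k):
                    raise ValueError("attribute array shape must be (T_i, J, K)")
            object.__setattr__(self, "attributes", attrs)

    @property
    def n_individuals(self) -> int:
        return len(self.chosen)

    @property
    def n_situations(self) -> np.ndarray:
        """T_i per individual."""
        return np.array([c.size for c in self.chosen])

    @property
    def choice_counts(self) -> np.ndarray:
        """(I, J) counts of how often each individual chose each alternative."""
        counts = np.zeros((self.n_individuals, self.n_alts))
        for i, c in enumerate(self.chosen):
            np.add.at(counts[i], c, 1.0)
        return counts

    def non_base_alts(self) -> tuple[int, ...]:
        return tuple(j for j in range(self.n_alts) if j != self.base_alt)


@dataclass(frozen=True)
class MixingParams:
    """Mean vector and Choleski factor of the normal mixing distribution.

    ``mixed_alts[k]`` names the alternative whose alternative-specific
    constant is served by mixing dimension k (ordering must match the draw
    configuration's dimension order).  Non-mixed, non-base alternatives may
    carry fixed constants through ``fixed_asc``; attribute coefficients, when
    the panel has attributes, through ``fixed_coeffs``.
    """

    means: np.ndarray
    chol: np.ndarray
    mixed_alts: tuple[int, ...]
    fixed_asc: Mapping[int, float] = field(default_factory=dict)
    fixed_coeffs: np.ndarray | None = None

    def __post_init__(self) -> None:
        means = np.atleast_1d(np.asarray(self.means, dtype=float))
        chol = np.atleast_2d(np.asarray(self.chol, dtype=float))
        n = means.size
        if chol.shape != (n, n):
            raise ValueError("chol must be n x n with n = len(means)")
        if not np.allclose(chol, np.tril(chol)):
            raise ValueError("chol must be lower triangular")
        if len(self.mixed_alts) != n or len(set(self.mixed_alts)) != n:
            raise ValueError("mixed_alts must be n distinct alternative indices")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "chol", np.tril(chol))
        object.__setattr__(self, "mixed_alts", tuple(int(a) for a in self.mixed_alts))
        object.__setattr__(self, "fixed_asc", dict(self.fixed_asc))
        if self.fixed_coeffs is not None:
            object.__setattr__(
                self, "fixed_coeffs", np.atleast_1d(np.asarray(self.fixed_coeffs, float))
            )

    @property
    def n_dims(self) -> int:
        return self.means.size

    @property
    def covariance(self) -> np.ndarray:
        return self.chol @ self.chol.T


#: A quadrant: one of the 2**n sign patterns of the Choleski columns.
QuadrantSigns = tuple


def all_quadrants(n_dims: int) -> list[QuadrantSigns]:
    """All 2**n sign patterns, mask-ordered (bit k set -> dimension k is -1)."""
    out = []
    for mask in range(2**n_dims):
        out.append(tuple(-1 if (mask >> k) & 1 else 1 for k in range(n_dims)))
    return out


def logit_choice_prob(systematic_utilities: np.ndarray) -> np.ndarray:
    """Conditional logit (softmax) choice probabilities over J alternatives."""
    u = np.asarray(systematic_utilities, dtype=float)
    if not np.isfinite(u).all():
        raise ValueError("utilities must be finite")
    e = np.exp(u - u.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def panel_logprob_given_beta(
    panel: ChoicePanel,
    individual: int,
    beta: np.ndarray,
    params: MixingParams | None = None,
) -> float:
    """Log of the panel product of logit choice probabilities for one
    individual at fixed mixed-coefficient values ``beta``.

    ``beta`` holds one value per mixing dimension; placement into the
    alternative-specific constants, and any fixed constants/attribute
    coefficients, follow ``params`` (defaulting to beta_k serving the k-th
    non-base alternative).
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if params is None:
        params = MixingParams(
            means=np.zeros(beta.size),
            chol=np.zeros((beta.size, beta.size)),
            mixed_alts=ChoicePanel.non_base_alts(panel)[: beta.size],
        )
    util = _systematic_utilities(panel, individual, params, beta)
    chosen = panel.chosen[individual]
    lse = logsumexp(util, axis=-1)
    return float(util[np.arange(chosen.size), chosen].sum() - lse.sum())


def _asc_vector(panel: ChoicePanel, params: MixingParams, beta: np.ndarray) -> np.ndarray:
    """Constants per alternative (..., J) given mixed values beta (..., n)."""
    shape = beta.shape[:-1] + (panel.n_alts,)
    asc = np.zeros(shape)
    for k, a in enumerate(params.mixed_alts):
        asc[..., a] = beta[..., k]
    for a, v in params.fixed_asc.items():
        asc[..., a] = v
    asc[..., panel.base_alt] = 0.0
    return asc


def _systematic_utilities(
    panel: ChoicePanel, individual: int, params: MixingParams, beta: np.ndarray
) -> np.ndarray:
    """(T_i, J) utilities for one individual at one beta."""
    asc = _asc_vector(panel, params, beta)
    t = panel.chosen[individual].size
    util = np.broadcast_to(asc, (t, panel.n_alts)).copy()
    if panel.attributes is not None and params.fixed_coeffs is not None:
        util += panel.attributes[individual] @ params.fixed_coeffs
    return util


def transform_draws(z: np.ndarray, params: MixingParams) -> np.ndarray:
    """Map standard-normal draws to mixing-distribution draws b + Q z."""
    z = np.asarray(z, dtype=float)
    return params.means + z @ params.chol.T


def _panel_logprob_matrix(
    panel: ChoicePanel, params: MixingParams, betas: np.ndarray
) -> np.ndarray:
    """(I, R) log panel products at per-individual, per-draw coefficients.

    Fast path: with alternative-specific constants only, utilities do not
    vary over choice situations, so the panel log-product reduces to
    sum_j count_ij * asc_j - T_i * logsumexp_j(asc_j) per draw.
    """
    i_n, r, _ = betas.shape
    asc = _asc_vector(panel, params, betas)  # (I, R, J)
    if panel.attributes is None or params.fixed_coeffs is None:
        counts = panel.choice_counts  # (I, J)
        lse = logsumexp(asc, axis=-1)  # (I, R)
        chosen_sum = np.einsum("ij,irj->ir", counts, asc)
        return chosen_sum - panel.n_situations[:, None] * lse
    logp = np.empty((i_n, r))
    for i in range(i_n):
        util = asc[i][:, None, :] + (
            panel.attributes[i] @ params.fixed_coeffs
        )  # (R, T_i, J)
        chosen = panel.chosen[i]
        lse = logsumexp(util, axis=-1)  # (R, T_i)
        logp[i] = (
            util[:, np.arange(chosen.size), chosen].sum(axis=1) - lse.sum(axis=1)
        )
    return logp


def conventional_loglik(panel: ChoicePanel, params: MixingParams) -> float:
    """Conventional (no-mixing) multinomial logit log-likelihood.

    Evaluates the panel product at the mixing means with the heterogeneity
    switched off — the limit of :func:`simulated_loglik` as the Choleski
    factor goes to zero, and exact for models with no mixed parameters
    (``params`` of dimension zero with only fixed constants).
    """
    n = params.n_dims
    betas = np.broadcast_to(
        params.means, (panel.n_individuals, 1, n)
    )
    logp = _panel_logprob_matrix(panel, params, betas)
    return float(logp[:, 0].sum())


KernelFn = Callable[[np.ndarray, ChoicePanel], np.ndarray]


def simulated_loglik(
    panel: ChoicePanel,
    params: MixingParams,
    draws: NormalDrawSet,
    kernel: KernelFn | None = None,
) -> float:
    """Simulated panel mixed logit log-likelihood.

    Averages, per individual, the exponentiated panel log-products over the
    R draws (log-sum-exp in draw space), then sums the log averages over
    individuals.  Deterministic given (panel, params, draws).

    ``kernel`` is a test hook replacing the logit panel kernel: it receives
    the transformed coefficients (I, R, n) and the panel, and must return
    (I, R) conditional log-likelihood values.
    """
    c = draws.config
    if c.n_dims != params.n_dims:
        raise ValueError(
            f"draw set has {c.n_dims} dimensions, params have {params.n_dims}"
        )
    if c.n_individuals != panel.n_individuals:
        raise ValueError("draw set and panel disagree on individual count")
    betas = transform_draws(draws.points, params)  # (I, R, n)
    if kernel is None:
        logp = _panel_logprob_matrix(panel, params, betas)
    else:
        logp = kernel(betas, panel)
    r = c.draws_per_individual
    ll_i = logsumexp(logp, axis=1) - np.log(r)
    bad = np.flatnonzero(~np.isfinite(ll_i))
    if bad.size:
        raise FloatingPointError(
            "simulated probability underflowed to zero for individual(s) "
            f"{bad.tolist()}"
        )
    return float(ll_i.sum())


def flip_factor(chol: np.ndarray, signs: Sequence[int]) -> np.ndarray:
    """Multiply column k of a lower-triangular factor by ``signs[k]``.

    Column sign flips are exactly the transformations that leave Q Q'
    unchanged while moving the factor between quadrants; the quadrant label
    of the result is the sign pattern of its diagonal (for positive-diagonal
    input).
    """
    chol = np.asarray(chol, dtype=float)
    s = np.asarray(signs, dtype=float)
    if s.shape != (chol.shape[0],) or not np.isin(s, (-1.0, 1.0)).all():
        raise ValueError("signs must be an n-vector of +-1")
    return chol * s[None, :]


@dataclass(frozen=True)
class QuadrantScanReport:
    """Simulated log-likelihood in every sign quadrant of the Choleski factor."""

    per_quadrant_ll: dict

    def __post_init__(self) -> None:
        if not self.per_quadrant_ll:
            raise ValueError("empty scan")
        n = len(next(iter(self.per_quadrant_ll)))
        if len(self.per_quadrant_ll) != 2**n:
            raise ValueError("scan must cover all 2**n quadrants")

    @property
    def n_dims(self) -> int:
        return len(next(iter(self.per_quadrant_ll)))

    @property
    def values(self) -> np.ndarray:
        """Log-likelihoods in quadrant mask order."""
        return np.array(
            [self.per_quadrant_ll[q] for q in all_quadrants(self.n_dims)]
        )

    @property
    def max_abs_difference(self) -> float:
        v = self.values
        return float(v.max() - v.min())


def quadrant_scan(
    panel: ChoicePanel,
    params: MixingParams,
    draws: NormalDrawSet,
    kernel: KernelFn | None = None,
) -> QuadrantScanReport:
    """Evaluate the simulated log-likelihood in all 2**n quadrants.

    Every quadrant uses the *same* draw set, mirroring how an optimizer holds
    draws fixed while the Choleski signs move; all quadrants share one
    covariance, so any spread is pure simulation noise.
    """
    if (np.diag(params.chol) < 0).any():
        raise ValueError("quadrant_scan expects a canonical (non-negative "
                         "diagonal) Choleski factor")
    out = {}
    for signs in all_quadrants(params.n_dims):
        p = MixingParams(
            means=params.means,
            chol=flip_factor(params.chol, signs),
            mixed_alts=params.mixed_alts,
            fixed_asc=params.fixed_asc,
            fixed_coeffs=params.fixed_coeffs,
        )
        out[signs] = simulated_loglik(panel, p, draws, kernel=kernel)
    return QuadrantScanReport(per_quadrant_ll=out)
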