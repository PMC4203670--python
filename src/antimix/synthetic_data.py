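"""Synthetic panel choice data from a known mixed logit process.

The generator emulates a controlled simulation design: I individuals each
make T choices among J alternatives; the base alternative's systematic
utility is zero; each non-base alternative carries an alternative-specific
constant drawn once per individual from a multivariate normal.  Choices are
utility-maximizing with additive independent Gumbel(0, 1) noise, which is
distributionally identical to sampling from the conditional logit
probabilities.

Because the sample is finite, the realized mean and covariance of the latent
constants differ from the generating values; both are recorded so that the
simulated likelihood can be evaluated "at the true optimum" of the realized
sample, the natural reference point for quadrant diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mmnl_core import ChoicePanel, MixingParams

__all__ = ["SimSpec", "SimulatedPanel", "simulate_panel", "realized_moments",
           "params_from_moments"]

#: Named presets for the generating mixing distribution, as
#: (means, standard deviations) of the non-base constants.
PRESETS = {
    # all constants well away from zero, unit heterogeneity
    "default": ((1.0, 1.0, 1.0), (1.0, 1.0, 1.0)),
    # middle constant with small heterogeneity (SD 0.1), the regime where a
    # zero-SD restriction on that dimension is nearly true; removing a middle
    # dimension is also what distinguishes the two prime policies
    "paper-like-c": ((1.0, 1.0, 1.0), (1.0, 0.1, 1.0)),
    # first constant close to zero, so restricting its mean to zero is only
    # mildly false and LR statistics are dominated by simulation noise
    "mildly-false-mean": ((0.1, 1.0, 1.0), (1.0, 1.0, 1.0)),
}


@dataclass(frozen=True)
class SimSpec:
    """Generating process for a synthetic choice panel.

    Defaults follow the canonical design of the quadrant experiments:
    1,000 individuals, 20 choices each, 4 alternatives, three independently
    normal alternative-specific constants with nonzero means, base
    alternative utility fixed at zero.
    """

    n_individuals: int = 1000
    n_situations: int = 20
    n_alternatives: int = 4
    base_alternative: int = 0
    mixing_means: tuple = (1.0, 1.0, 1.0)
    mixing_cov: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_individuals, self.n_situations, self.n_alternatives) < 1:
            raise ValueError("I, T and J must all be >= 1")
        if not (0 <= self.base_alternative < self.n_alternatives):
            raise ValueError("base_alternative out of range")
        means = tuple(float(m) for m in np.atleast_1d(self.mixing_means))
        cov = np.atleast_2d(np.asarray(self.mixing_cov, dtype=float))
        n = self.n_alternatives - 1
        if len(means) != n or cov.shape != (n, n):
            raise ValueError(
                f"means must have length J-1={n} and cov be {n}x{n}"
            )
        if not np.allclose(cov, cov.T):
            raise ValueError("mixing_cov must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ValueError("mixing_cov must be positive semi-definite")
        object.__setattr__(self, "mixing_means", means)
        object.__setattr__(
            self, "mixing_cov", tuple(tuple(float(v) for v in row) for row in cov)
        )

    @classmethod
    def preset(cls, name: str, **overrides) -> "SimSpec":
        """Build a spec from a named (means, SDs) preset; see ``PRESETS``."""
        means, sds = PRESETS[name]
        cov = np.diag(np.square(sds))
        return cls(mixing_means=means, mixing_cov=tuple(map(tuple, cov)),
                   **overrides)


@dataclass(frozen=True)
class SimulatedPanel:
    """A generated panel together with its latent coefficients and moments."""

    panel: ChoicePanel
    latent_betas: np.ndarray
    realized_means: np.ndarray
    realized_cov: np.ndarray
    spec: SimSpec


def simulate_panel(spec: SimSpec) -> SimulatedPanel:
    """Generate a panel under ``spec``; bit-for-bit reproducible per seed.

    One generator stream is consumed in a fixed order — individual
    coefficients first, then Gumbel noise situation-major — so a spec fully
    determines the panel.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_alternatives - 1
    means = np.asarray(spec.mixing_means)
    cov = np.asarray(spec.mixing_cov)
    betas = rng.multivariate_normal(
        means, cov, size=spec.n_individuals, check_valid="raise"
    )  # (I, J-1)
    eps = rng.gumbel(
        size=(spec.n_individuals, spec.n_situations, spec.n_alternatives)
    )
    util = eps.copy()
    non_base = [j for j in range(spec.n_alternatives) if j != spec.base_alternative]
    for k, j in enumerate(non_base):
        util[:, :, j] += betas[:, k, None]
    chosen = util.argmax(axis=2)  # ties -> lowest index (probability zero)
    panel = ChoicePanel(
        chosen=tuple(chosen[i] for i in range(spec.n_individuals)),
        n_alts=spec.n_alternatives,
        base_alt=spec.base_alternative,
    )
    if spec.n_individuals > 1:
        r_means = betas.mean(axis=0)
        r_cov = np.cov(betas, rowvar=False, ddof=1).reshape(n, n)
    else:
        r_means = betas[0].copy()
        r_cov = np.full((n, n), np.nan)
    return SimulatedPanel(
        panel=panel,
        latent_betas=betas,
        realized_means=r_means,
        realized_cov=r_cov,
        spec=spec,
    )


def realized_moments(sim: SimulatedPanel) -> tuple[np.ndarray, np.ndarray]:
    """Exact sample mean and covariance (denominator I-1) of the latent betas."""
    if sim.latent_betas.shape[0] < 2:
        raise ValueError("sample covariance undefined for a single individual")
    return sim.realized_means.copy(), sim.realized_cov.copy()


def params_from_moments(
    sim: SimulatedPanel, use: str = "realized"
) -> MixingParams:
    """Mixing parameters at the sample's own optimum (or the generating one).

    ``use="realized"`` takes the sample moments of the latent coefficients
    (the default for quadrant-scan experiments); ``use="spec"`` takes the
    generating population values.  The Choleski factor is the canonical one
    with non-negative diagonal.
    """
    if use == "realized":
        means, cov = realized_moments(sim)
    elif use == "spec":
        means = np.asarray(sim.spec.mixing_means)
        cov = np.asarray(sim.spec.mixing_cov)
    else:
        raise ValueError("use must be 'realized' or 'spec'")
    chol = np.linalg.cholesky(cov)
    non_base = [
        j
        for j in range(sim.spec.n_alternatives)
        if j != sim.spec.base_alternative
    ]
    return MixingParams(means=means, chol=chol, mixed_alts=tuple(non_base))
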