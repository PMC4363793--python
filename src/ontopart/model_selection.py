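"""Marginal-likelihood estimation and Bayes-factor model choice.

Two estimators of ln marginal likelihood (lnML):

* **harmonic mean** of the posterior likelihood sample — cheap (reuses
  the MCMC trace) but high-variance;
* **stepping-stone sampling** — a ladder of power posteriors
  ``prior x likelihood^beta`` with powers ``beta_j = (j/K)^(1/alpha)``
  (Beta(alpha,1) quantiles), annealed from the posterior (beta=1) to
  the prior (beta=0).  Step ``s`` samples at the lower power
  ``beta_s`` and contributes ``logmeanexp[(beta_{s-1} - beta_s) lnL]``;
  the contributions telescope to lnML and are exact for a constant
  likelihood.  Each step inherits its start state from the previous
  step, so the first fraction of every step doubles as that step's
  burn-in.

Bayes factors are reported as 2lnBF with the conventional
interpretation bands (negligible / positive / strong / very strong).
Estimates from datasets with and without autapomorphic characters are
not comparable and mixing them raises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from ontopart.errors import ComparabilityError, OntopartError
from ontopart.mcmc import McmcConfig, PhyloPosterior


@dataclass
class SteppingStoneConfig:
    n_steps: int = 50
    alpha: float = 0.4
    per_step_generations: int = 1000
    sample_interval: int = 10
    burn_in_fraction: float = 0.25
    n_runs: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0 <= self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must be in [0,1)")

    def powers(self) -> np.ndarray:
        """beta_K=1 down to beta_0=0 (K+1 values, strictly decreasing)."""
        j = np.arange(self.n_steps, -1, -1)
        return (j / self.n_steps) ** (1.0 / self.alpha)


@dataclass
class LogMarginalLikelihood:
    value: float
    method: str  # "ss" or "hm"
    model_id: str | None = None
    variant: str = "with"  # autapomorphy variant of the dataset
    per_run: tuple = ()

    @property
    def spread(self) -> float:
        """max - min across runs (the published reporting convention)."""
        if len(self.per_run) < 2:
            return 0.0
        return float(max(self.per_run) - min(self.per_run))


def harmonic_mean_logml(log_likelihood_trace) -> float:
    """Harmonic-mean lnML from a post-burn-in likelihood trace:
    ``-logmeanexp(-lnL)``, computed with log-sum-exp stability."""
    trace = np.asarray(list(log_likelihood_trace), dtype=float)
    if trace.size == 0:
        raise OntopartError("empty likelihood trace")
    return float(-(logsumexp(-trace) - math.log(trace.size)))


# ---------------------------------------------------------------------------
# Generic power-posterior machinery


def _power_chain(posterior, rng, beta, n_generations, sample_interval,
                 init_state=None):
    """MH chain targeting prior x likelihood^beta over a posterior object
    exposing init_state/propose/log_likelihood/log_prior.  Returns
    (lnL samples, final state)."""
    state = posterior.init_state(rng) if init_state is None else init_state
    ll = posterior.log_likelihood(state)
    lp = posterior.log_prior(state)
    out = []
    for gen in range(1, n_generations + 1):
        prop = posterior.propose(state, rng)
        if prop is not None:
            new_state, log_h = prop
            nll = posterior.log_likelihood(new_state)
            nlp = posterior.log_prior(new_state)
            log_alpha = beta * (nll - ll) + (nlp - lp) + log_h
            if log_alpha >= 0 or rng.random() < math.exp(max(log_alpha, -700)):
                state, ll, lp = new_state, nll, nlp
        if gen % sample_interval == 0:
            out.append(ll)
    return out, state


def power_posterior_logml(posterior, config: SteppingStoneConfig,
                          rng: np.random.Generator) -> float:
    """One stepping-stone pass over the power ladder for an arbitrary
    posterior object; returns the lnML estimate."""
    powers = config.powers()
    n_gen = config.per_step_generations
    n_burn = int(math.floor(
        (n_gen // config.sample_interval) * config.burn_in_fraction
    ))
    # initial annealing segment at beta=1 serves as the ladder's burn-in
    _, state = _power_chain(
        posterior, rng, 1.0, max(n_gen // 2, config.sample_interval),
        config.sample_interval,
    )
    logml = 0.0
    for s in range(1, len(powers)):
        beta_hi, beta_lo = float(powers[s - 1]), float(powers[s])
        lls, state = _power_chain(
            posterior, rng, beta_lo, n_gen, config.sample_interval, state
        )
        kept = np.asarray(lls[n_burn:], dtype=float)
        if kept.size == 0 or not np.isfinite(kept).any():
            raise OntopartError(f"divergent stepping-stone step {s} (no finite lnL)")
        logml += float(
            logsumexp((beta_hi - beta_lo) * kept) - math.log(kept.size)
        )
    return logml


def stepping_stone_logml(
    matrix,
    scheme,
    linkage,
    ss_config: SteppingStoneConfig,
    mcmc_config: McmcConfig | None = None,
    model_id: str | None = None,
    variant: str = "with",
) -> LogMarginalLikelihood:
    """Stepping-stone lnML of a partitioned Mkv model on ``matrix``.

    Runs ``n_runs`` independent ladders; the reported value is the mean
    of the per-run estimates and ``spread`` their range.
    """
    if mcmc_config is None:
        mcmc_config = McmcConfig()
    per_run = []
    for r in range(ss_config.n_runs):
        rng = np.random.default_rng((ss_config.seed, 7919, r))
        posterior = PhyloPosterior(matrix, scheme, linkage, mcmc_config)
        per_run.append(power_posterior_logml(posterior, ss_config, rng))
    return LogMarginalLikelihood(
        value=float(np.mean(per_run)),
        method="ss",
        model_id=model_id,
        variant=variant,
        per_run=tuple(per_run),
    )


# ---------------------------------------------------------------------------
# Bayes factors


KASS_RAFTERY_BANDS = (
    (0.0, 2.0, "negligible"),
    (2.0, 6.0, "positive"),
    (6.0, 10.0, "strong"),
    (10.0, math.inf, "very strong"),
)


@dataclass(frozen=True)
class BayesFactorResult:
    model_1: str | None
    model_0: str | None
    lnml_1: float
    lnml_0: float
    two_ln_bf: float
    interpretation: str


def _interpret(two_ln_bf: float) -> str:
    mag = abs(two_ln_bf)
    for lo, hi, label in KASS_RAFTERY_BANDS:
        if lo <= mag < hi:
            return label
    return "very strong"


def bayes_factor(lnml_1, lnml_0) -> BayesFactorResult:
    """2lnBF = 2(lnML_1 - lnML_0) with its interpretation band
    (computed on the magnitude; the sign says which model wins).

    Accepts floats or :class:`LogMarginalLikelihood` objects; the latter
    must come from the same autapomorphy variant of the dataset —
    likelihoods are not comparable across variants.
    """

    def unpack(x):
        if isinstance(x, LogMarginalLikelihood):
            return x.value, x.model_id, x.variant
        return float(x), None, None

    v1, id1, var1 = unpack(lnml_1)
    v0, id0, var0 = unpack(lnml_0)
    if var1 is not None and var0 is not None and var1 != var0:
        raise ComparabilityError(
            f"cannot compare lnML across dataset variants {var1!r} vs {var0!r}"
        )
    two = 2.0 * (v1 - v0)
    return BayesFactorResult(
        model_1=id1,
        model_0=id0,
        lnml_1=v1,
        lnml_0=v0,
        two_ln_bf=two,
        interpretation=_interpret(two),
    )
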