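"""Hierarchical Bayesian estimation of the Q-learning model."""

from rlpupil.inference.model import QLearningHierarchicalModel, build_model
from rlpupil.inference.nuts import SamplerConfig, nuts_sample
from rlpupil.inference.samples import PosteriorSamples
from rlpupil.inference.diagnostics import (
    rhat,
    convergence_report,
    max_rhat,
    posterior_predictive_check,
)

__all__ = [
    "QLearningHierarchicalModel",
    "build_model",
    "SamplerConfig",
    "nuts_sample",
    "sample_posterior",
    "PosteriorSamples",
    "rhat",
    "convergence_report",
    "max_rhat",
    "posterior_predictive_check",
]


def sample_posterior(
    model: QLearningHierarchicalModel,
    config: SamplerConfig | None = None,
    rng_seed=None,
) -> PosteriorSamples:
    """Fit a model with the built-in NUTS backend and package the draws.

    Divergent transitions are surfaced in the metadata (and in a warning
    when more than 1% of post-warmup transitions diverge), never hidden.
    """
    import warnings

    cfg = config or SamplerConfig()
    draws, stats = nuts_sample(model.logp_grad, model.dim, cfg, rng_seed)
    n_div = sum(s.divergences for s in stats)
    post = cfg.chains * (cfg.iterations - cfg.warmup)
    if n_div > 0.01 * post:
        warnings.warn(
            f"{n_div} divergent transitions across {cfg.chains} chains; "
            "treat posterior summaries with caution",
            RuntimeWarning,
            stacklevel=2,
        )
    meta = {
        "n_chains": cfg.chains,
        "n_iterations": cfg.iterations,
        "n_warmup": cfg.warmup,
        "seed": rng_seed if isinstance(rng_seed, int) else None,
        "divergences": n_div,
        "step_sizes": [s.step_size for s in stats],
        "accept_means": [s.accept_mean for s in stats],
    }
    return PosteriorSamples.from_unconstrained(model, draws, meta)
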