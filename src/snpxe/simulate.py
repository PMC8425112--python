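"""Synthetic case-control data with planted SNP-environment interactions.

Genotypes are drawn under Hardy-Weinberg equilibrium from a minor
allele frequency; the environmental factor is multinomial over its
levels; outcomes follow a logistic (Bernoulli) or linear (Gaussian)
model whose linear predictor is built from a chosen interaction
pattern's coded design, so every coefficient is on the log-odds scale
and OR = exp(coefficient).  SNPs are simulated independently — no
linkage disequilibrium or population structure.

All randomness flows through a single integer seed; stochastic steps
draw from substreams spawned from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .patterns import PatternSpec, build_design, code_env, code_snp, parse_label

__all__ = [
    "PlantedEffect",
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_environment",
    "simulate_outcome",
    "simulate_dataset",
    "make_simdata2_like",
]


@dataclass
class PlantedEffect:
    """A true interaction pattern and its generating coefficients.

    ``interaction_coefs`` has one entry per environment dummy (k-1 for
    k levels), ordered by level; ``snp_coef`` / ``env_coefs`` are the
    main-effect coefficients, used only when the pattern's structure
    includes them.
    """

    spec: PatternSpec
    snp_name: str
    interaction_coefs: tuple[float, ...]
    snp_coef: float = 0.0
    env_coefs: tuple[float, ...] = ()


@dataclass
class SimulationConfig:
    n: int = 2000
    snps: list[tuple[str, float]] = field(default_factory=lambda: [("snp1", 0.3)])
    env_name: str = "env_g3"
    env_levels: tuple = (1, 2, 3)
    env_probs: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    truth: list[PlantedEffect] = field(default_factory=list)
    baseline: float = 0.0  # intercept on the link scale (log-odds / mean)
    family: str = "logistic"
    noise_sd: float = 1.0
    outcome_name: str = "outcome"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, maf in self.snps:
            if not 0 < maf <= 0.5:
                raise ValueError(f"MAF for {name} must be in (0, 0.5], got {maf}")
        p = np.asarray(self.env_probs, dtype=float)
        if len(p) != len(self.env_levels) or not np.isclose(p.sum(), 1.0):
            raise ValueError("env_probs must match env_levels and sum to 1")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genotypes(n: int, maf: float, seed=0) -> np.ndarray:
    """Draw n genotypes (minor-allele counts) under Hardy-Weinberg equilibrium.

    P(2) = maf^2, P(1) = 2*maf*(1-maf), P(0) = (1-maf)^2.
    """
    if not 0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    rng = _rng(seed)
    q = maf
    probs = [(1 - q) ** 2, 2 * q * (1 - q), q ** 2]
    return rng.choice([0, 1, 2], size=n, p=probs)


def simulate_environment(n: int, probs=(1 / 3, 1 / 3, 1 / 3), levels=(1, 2, 3), seed=0) -> np.ndarray:
    """Draw an ordinal/categorical environmental factor from level probabilities."""
    rng = _rng(seed)
    return rng.choice(list(levels), size=n, p=list(probs))


def _linear_predictor(
    effect: PlantedEffect, genotypes: np.ndarray, env: np.ndarray
) -> np.ndarray:
    spec = effect.spec
    s = code_snp(genotypes, spec.mode, spec.snp_dir)
    dummies, ref = code_env(env, spec.env_dir, "ordinal")
    design, coded = build_design(s, dummies, spec.structure)
    lp = np.zeros(len(genotypes))
    k1 = dummies.shape[1]
    coefs = np.asarray(effect.interaction_coefs, dtype=float)
    if len(coefs) != k1:
        raise ValueError(
            f"{effect.snp_name}: need {k1} interaction coefficients "
            f"(one per environment dummy), got {len(coefs)}"
        )
    lp += coded.interaction_cols.to_numpy() @ coefs
    if coded.snp_main_included:
        lp += effect.snp_coef * s
    if coded.env_main_included:
        env_coefs = np.asarray(effect.env_coefs, dtype=float)
        if len(env_coefs) != k1:
            raise ValueError(f"{effect.snp_name}: need {k1} environment main-effect coefficients")
        lp += dummies.to_numpy() @ env_coefs
    return lp


def simulate_outcome(
    config: SimulationConfig, genotypes: dict[str, np.ndarray], env: np.ndarray, seed=0
) -> np.ndarray:
    """Draw the outcome from the planted truth given genotypes and environment.

    With no planted effects the outcome follows the intercept-only
    (null) model.  Logistic family: Y ~ Bernoulli(expit(lp)); linear:
    Y = lp + Normal(0, noise_sd).
    """
    rng = _rng(seed)
    n = len(env)
    lp = np.full(n, float(config.baseline))
    for effect in config.truth:
        if effect.snp_name not in genotypes:
            raise KeyError(f"planted effect references unknown SNP {effect.snp_name!r}")
        lp = lp + _linear_predictor(effect, genotypes[effect.snp_name], env)
    if config.family == "logistic":
        return rng.binomial(1, expit(lp)).astype(float)
    if config.family == "linear":
        return lp + rng.normal(0.0, config.noise_sd, size=n)
    raise ValueError(f"family must be 'logistic' or 'linear', got {config.family!r}")


def simulate_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Full subject table: id, outcome, environment, one column per SNP."""
    root = np.random.default_rng(config.seed)
    streams = root.spawn(len(config.snps) + 2)
    genotypes = {
        name: simulate_genotypes(config.n, maf, streams[i])
        for i, (name, maf) in enumerate(config.snps)
    }
    env = simulate_environment(
        config.n, config.env_probs, config.env_levels, streams[-2]
    )
    y = simulate_outcome(config, genotypes, env, streams[-1])
    out = {"id": np.arange(1, config.n + 1), config.outcome_name: y,
           config.env_name: env}
    out.update(genotypes)
    return pd.DataFrame(out)


# Table-2-style marginal structure: 5 SNPs with these MAFs against a
# 3-level ordinal exposure, n = 2000, binary outcome.
_SIMDATA2_MAFS = [
    ("snp1", 0.210),
    ("snp2", 0.071),
    ("snp3", 0.343),
    ("snp4", 0.342),
    ("snp5", 0.445),
]


def make_simdata2_like(seed: int = 0) -> pd.DataFrame:
    """A 2000-subject dataset emulating the published example's schema.

    Five Hardy-Weinberg SNPs with the example's MAFs, a uniform
    3-level ordinal exposure, and a binary outcome carrying two
    planted interactions: an additive-SNP interaction-only effect on
    snp2 (Int_AE_oo, ORs 0.7 and 2.4 for the level-2 and level-3
    dummies) and a recessive reverse-environment interaction-only
    effect on snp3 (Int_RE_or, ORs 2.0 and 1.8); the other SNPs are
    null.  Baseline prevalence 0.2.  The planted effect sizes are
    illustrative — the published dataset's generating model is not
    public, so its per-pattern p-values are not reproduction targets.
    """
    config = SimulationConfig(
        n=2000,
        snps=list(_SIMDATA2_MAFS),
        truth=[
            PlantedEffect(
                spec=parse_label("Int_AE_oo"), snp_name="snp2",
                interaction_coefs=(np.log(0.7), np.log(2.4)),
            ),
            PlantedEffect(
                spec=parse_label("Int_RE_or"), snp_name="snp3",
                interaction_coefs=(np.log(2.0), np.log(1.8)),
            ),
        ],
        baseline=float(logit(0.2)),
        seed=seed,
    )
    return simulate_dataset(config)
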