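"""Synthetic cohorts: planted decision policies, trials, and choices.

The generator emulates the structure of the human experiment: four task
variants, ~50 participants per variant, ~500 trials each, two-alternative
choices. Two planting policies are supported:

* ``logistic`` - each participant's choices are Bernoulli draws from the
  hierarchical logistic model itself, with coefficients drawn around planted
  population means. This gives exact ground truth for parameter-recovery
  checks (inference correctness, no model mismatch).
* ``observer`` - each participant is a simulated observer
  (:mod:`occam.observers`) with parameters drawn from a population
  distribution. This exercises the full nonlinear path from stimuli to
  choices, including model mismatch.

The default human-like planted regime uses relative sensitivities
{dimensionality 4.66, boundary 1.12, volume 0.23, robustness 2.21} around a
unit likelihood coefficient, a regime in which people reportedly operate.
All randomness derives from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import observers, sensitivity, taskgen

__all__ = [
    "ObserverPopulation",
    "CohortSpec",
    "HUMAN_LIKE_BETA_MEAN",
    "HUMAN_LIKE_BETA_SCALE",
    "generate_cohort",
    "reference_bands",
]

# population means for (intercept, likelihood, dimensionality, boundary,
# volume, robustness); likelihood 1 makes the FIA-term coefficients directly
# the relative sensitivities
HUMAN_LIKE_BETA_MEAN = np.array([0.0, 1.0, 4.66, 1.12, 0.23, 2.21])
HUMAN_LIKE_BETA_SCALE = np.array([0.1, 0.1, 0.96, 0.10, 0.12, 0.12])


@dataclass(frozen=True)
class ObserverPopulation:
    """Population distribution over observer parameters (Gaussian, truncated to valid ranges)."""

    strategy: str = "posterior_sample"
    rho: tuple[float, float] = (0.0, 0.0)             # (mean, sd)
    integration: tuple[float, float] = (1.0, 0.0)
    temperature: tuple[float, float] = (0.0, 0.0)
    lapse: tuple[float, float] = (0.0, 0.0)

    def draw(self, rng: np.random.Generator) -> observers.ObserverConfig:
        def trunc(ms, lo, hi):
            m, s = ms
            return float(np.clip(m + s * rng.standard_normal(), lo, hi))

        return observers.ObserverConfig(
            strategy=self.strategy,
            sensory_noise_rho=trunc(self.rho, 0.0, np.inf),
            integration_strength=trunc(self.integration, 0.0, 1.0),
            choice_temperature=trunc(self.temperature, 0.0, np.inf),
            lapse_rate=trunc(self.lapse, 0.0, 0.4999),
        )


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic cohort: group sizes, trial counts, and the planted policy."""

    variants: Sequence[str] = taskgen.VARIANT_NAMES
    n_participants: int = 50          # per variant
    n_trials: int = 500               # per participant
    policy: Literal["logistic", "observer"] = "logistic"
    beta_mean: np.ndarray = field(default_factory=lambda: HUMAN_LIKE_BETA_MEAN.copy())
    beta_scale: np.ndarray = field(default_factory=lambda: HUMAN_LIKE_BETA_SCALE.copy())
    lapse_mean: float = 0.0           # logistic policy: planted lapse rate
    lapse_scale: float = 0.0
    observer_population: ObserverPopulation = ObserverPopulation()
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants per variant")
        if len(np.asarray(self.beta_mean)) != 6 or len(np.asarray(self.beta_scale)) != 6:
            raise ValueError("beta_mean / beta_scale must have 6 entries")


def _variant_map(task_variants: Optional[Sequence[taskgen.TaskVariant]]):
    vs = task_variants if task_variants is not None else taskgen.default_variants()
    return {v.name: v for v in vs}


def generate_cohort(
    spec: CohortSpec,
    task_variants: Optional[Sequence[taskgen.TaskVariant]] = None,
) -> dict:
    """Generate trials, choices, the regression design, and ground truth.

    Returns ``{"choices", "design", "ground_truth", "manifest"}``; ``design``
    is ready for :func:`occam.sensitivity.fit_hierarchical` and ``choices``
    is the canonical interchange table (one row per trial with the scored
    choice). Identical specs (same master seed) give identical outputs.
    """
    vmap = _variant_map(task_variants)
    root = np.random.SeedSequence(spec.master_seed)
    design_frames, choice_frames, truth_rows = [], [], []
    n_dropped = 0
    for vi, vname in enumerate(spec.variants):
        variant = vmap[vname]
        for j in range(spec.n_participants):
            pid = f"{vname}_p{j:03d}"
            ss = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(vi, j)
            )
            rng = np.random.default_rng(ss)
            batch = taskgen.sample_trials(variant, spec.n_trials, rng)
            if spec.policy == "logistic":
                beta = np.asarray(spec.beta_mean) + np.asarray(
                    spec.beta_scale
                ) * rng.standard_normal(6)
                lapse = float(
                    np.clip(
                        spec.lapse_mean + spec.lapse_scale * rng.standard_normal(),
                        0.0,
                        0.4999,
                    )
                )
                design = sensitivity.build_design(variant, batch, None, pid)
                X = np.column_stack(
                    [
                        np.ones(len(design)),
                        design[list(sensitivity.DELTA_COLUMNS)].to_numpy(),
                    ]
                )
                p_up = lapse / 2.0 + (1.0 - lapse) * expit(X @ beta)
                design["choice_up"] = (rng.random(len(design)) < p_up).astype(int)
                choices = np.where(design["choice_up"].to_numpy() == 1, 2, 1)
                kept = design["trial_id"].to_numpy()
                truth_rows.append(
                    {
                        "participant_id": pid,
                        "variant": vname,
                        "policy": "logistic",
                        **{
                            f"beta_{name}": beta[k]
                            for k, name in enumerate(("intercept",) + sensitivity.TERMS)
                        },
                        "lapse_rate": lapse,
                    }
                )
                rec = pd.DataFrame(
                    {
                        "participant_id": pid,
                        "trial_id": kept,
                        "variant": vname,
                        "true_model": design["true_model"].to_numpy(),
                        "choice": choices,
                    }
                )
            else:
                obs = spec.observer_population.draw(rng)
                session = observers.simulate_session(
                    obs, variant, spec.n_trials, rng, observer_id=pid, batch=batch
                )
                design = sensitivity.build_design(
                    variant, batch, session["choice"].to_numpy(), pid
                )
                truth_rows.append(
                    {
                        "participant_id": pid,
                        "variant": vname,
                        "policy": "observer",
                        "strategy": obs.strategy,
                        "sensory_noise_rho": obs.sensory_noise_rho,
                        "integration_strength": obs.integration_strength,
                        "choice_temperature": obs.choice_temperature,
                        "lapse_rate": obs.lapse_rate,
                        "accuracy_generative": session.attrs["accuracy_generative"],
                        "accuracy_ml": session.attrs["accuracy_ml"],
                    }
                )
                rec = pd.DataFrame(
                    {
                        "participant_id": pid,
                        "trial_id": session["trial_id"],
                        "variant": vname,
                        "true_model": session["true_model"],
                        "choice": session["choice"],
                    }
                )
            rec["correct_generative"] = rec["choice"] == rec["true_model"]
            n_dropped += design.attrs.get("n_dropped", 0)
            design_frames.append(design)
            choice_frames.append(rec)
    design = pd.concat(design_frames, ignore_index=True)
    design.attrs["n_dropped"] = n_dropped
    manifest = {
        "master_seed": spec.master_seed,
        "policy": spec.policy,
        "variants": list(spec.variants),
        "n_participants_per_variant": spec.n_participants,
        "n_trials": spec.n_trials,
        "n_design_rows": len(design),
        "n_dropped_degenerate": n_dropped,
        "geometry": {name: v.to_dict() for name, v in vmap.items()},
    }
    return {
        "choices": pd.concat(choice_frames, ignore_index=True),
        "design": design,
        "ground_truth": pd.DataFrame(truth_rows),
        "manifest": manifest,
    }


def reference_bands(
    n_observers: int = 50,
    strategy: str = "posterior_sample",
    *,
    variants: Sequence[str] = taskgen.VARIANT_NAMES,
    n_trials: int = 500,
    master_seed: int = 0,
    task_variants: Optional[Sequence[taskgen.TaskVariant]] = None,
    fit_kwargs: Optional[dict] = None,
) -> dict:
    """Sensitivity reference distribution for a named observer strategy.

    Simulates ``n_observers`` sessions per variant with the given strategy,
    fits the hierarchical regression, and returns the posterior of the
    population relative sensitivities - the reference band against which
    human or planted cohorts are compared (the exact-posterior observer band
    centers near 1, the maximum-likelihood band near 0).
    """
    spec = CohortSpec(
        variants=variants,
        n_participants=n_observers,
        n_trials=n_trials,
        policy="observer",
        observer_population=ObserverPopulation(strategy=strategy),
        master_seed=master_seed,
    )
    cohort = generate_cohort(spec, task_variants)
    fit = sensitivity.fit_hierarchical(cohort["design"], **(fit_kwargs or {}))
    rs = sensitivity.relative_sensitivity(fit, force=not fit.converged)
    return {
        "fit": fit,
        "bands": rs["population"],
        "participant": rs["participant"],
        "converged": fit.converged,
        "manifest": cohort["manifest"],
    }
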