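"""Simulated decision-makers for the two-alternative model-selection task.

Strategies
----------
``max_likelihood``
    Chooses the model whose maximum-likelihood fit is best, i.e. whichever
    shape is closest to the empirical centroid; exact ties break by a fair
    coin.
``fia`` / ``exact_bayes``
    Choose by the FIA-approximated or exact-quadrature log evidence.
``posterior_sample``
    Samples the choice with probability equal to the exact Bayesian
    posterior (probability matching); its logistic choice curve against the
    evidence difference has unit slope, which is what makes it the
    "relative sensitivity one" reference observer.
``nin``
    Noise-Integration-Noise: each observed point is first corrupted by
    isotropic Gaussian sensory noise of std ``sensory_noise_rho``; a
    per-model score is formed that interpolates between the maximum
    log likelihood (``integration_strength = 0``, no integration over latent
    causes) and the full log marginal (``integration_strength = 1``, complete
    integration); the choice is then read out through a softmax with
    ``choice_temperature`` and a ``lapse_rate`` uniform mixture. The two
    integration endpoints reproduce the max-likelihood and exact-Bayes
    observers; integration is the mechanism that produces the simplicity
    bias, and the noise stages provably cannot mimic it (they shift or
    flatten the choice map differently).

Sessions are scored two ways: against the generating shape ("generative"
accuracy) and against the trial's maximum-likelihood solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from scipy.special import expit

from . import evidence, taskgen
from .manifolds import ModelManifold, NoiseModel

__all__ = [
    "ObserverConfig",
    "decide",
    "decide_batch",
    "simulate_session",
    "boundary_map",
    "boundary_crossings",
    "knn_choice_map",
]

Strategy = Literal["max_likelihood", "fia", "exact_bayes", "posterior_sample", "nin"]


@dataclass(frozen=True)
class ObserverConfig:
    """A simulated decision-maker: strategy plus noise/integration parameters."""

    strategy: Strategy = "exact_bayes"
    sensory_noise_rho: float = 0.0
    integration_strength: float = 1.0
    choice_temperature: float = 0.0
    lapse_rate: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sensory_noise_rho < 0:
            raise ValueError("sensory_noise_rho must be nonnegative")
        if not 0.0 <= self.integration_strength <= 1.0:
            raise ValueError("integration_strength must be in [0, 1]")
        if self.choice_temperature < 0:
            raise ValueError("choice_temperature must be nonnegative")
        if not 0.0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse_rate must be in [0, 0.5)")


# ---------------------------------------------------------------------------
# core decision machinery (batched)
# ---------------------------------------------------------------------------

def _corrupt(X, rho, rng):
    if rho <= 0:
        return X
    return X + rho * rng.standard_normal(X.shape)


def _readout(observer: ObserverConfig, logits, rng) -> np.ndarray:
    """Map evidence logits (model 2 minus model 1) to choices in {1, 2}."""
    logits = np.asarray(logits, dtype=float)
    if observer.strategy == "posterior_sample":
        p2 = expit(logits)
    elif observer.choice_temperature == 0.0:
        p2 = np.where(logits > 0, 1.0, np.where(logits < 0, 0.0, 0.5))
    else:
        p2 = expit(logits / observer.choice_temperature)
    u = rng.random(p2.shape)
    choice = np.where(u < p2, 2, 1)
    if observer.lapse_rate > 0:
        lapse = rng.random(p2.shape) < observer.lapse_rate
        coin = np.where(rng.random(p2.shape) < 0.5, 2, 1)
        choice = np.where(lapse, coin, choice)
    return choice


def _strategy_logits(
    observer: ObserverConfig,
    centroids,
    logit_fn,
):
    """Evidence logits for a batch given a method->logits evaluator."""
    if observer.strategy == "max_likelihood":
        return logit_fn("ml_only")
    if observer.strategy == "fia":
        return logit_fn("fia")
    if observer.strategy in ("exact_bayes", "posterior_sample"):
        return logit_fn("exact")
    if observer.strategy == "nin":
        w = observer.integration_strength
        if w == 0.0:
            return logit_fn("ml_only")
        if w == 1.0:
            return logit_fn("exact")
        return (1.0 - w) * logit_fn("ml_only") + w * logit_fn("exact")
    raise ValueError(f"unknown strategy {observer.strategy!r}")


def decide_batch(
    observer: ObserverConfig,
    variant: taskgen.TaskVariant,
    X,
    swapped,
    rng: np.random.Generator,
) -> np.ndarray:
    """Choices (1=down, 2=up) for a batch of trials of one variant."""
    X = _corrupt(np.asarray(X, dtype=float), observer.sensory_noise_rho, rng)
    centroids = X.mean(axis=1)
    logits = _strategy_logits(
        observer,
        centroids,
        lambda method: taskgen.choice_logits(variant, centroids, swapped, method),
    )
    return _readout(observer, logits, rng)


def decide(
    observer: ObserverConfig,
    pair: Sequence[ModelManifold],
    X,
    rng: np.random.Generator,
    noise: Optional[NoiseModel] = None,
) -> int:
    """Single-trial choice between an explicit (model 1, model 2) pair."""
    X = np.asarray(X, dtype=float)
    noise = noise or NoiseModel(sigma=1.0, n_obs=X.shape[0])
    Xc = _corrupt(X, observer.sensory_noise_rho, rng)
    centroid = Xc.mean(axis=0)[None, :]
    logits = _strategy_logits(
        observer,
        centroid,
        lambda method: evidence.choice_logit_batch(pair, centroid, noise, method),
    )
    return int(_readout(observer, logits, rng)[0])


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

def simulate_session(
    observer: ObserverConfig,
    variant: taskgen.TaskVariant,
    n_trials: int,
    rng: np.random.Generator,
    *,
    observer_id: str = "obs0",
    batch: Optional[dict] = None,
) -> pd.DataFrame:
    """Simulate one observer session; returns per-trial choice records.

    The frame carries ``accuracy_generative`` and ``accuracy_ml`` (fraction
    correct against the generating shape and against the trial's
    maximum-likelihood solution) in ``.attrs``. Pass ``batch`` to reuse
    pre-generated trials (paired observer comparisons).
    """
    if batch is None:
        batch = taskgen.sample_trials(variant, n_trials, rng)
    choices = decide_batch(observer, variant, batch["X"], batch["swapped"], rng)
    ml_logits = taskgen.choice_logits(variant, batch["centroid"], batch["swapped"], "ml_only")
    ml_solution = np.where(ml_logits > 0, 2, 1)
    rec = pd.DataFrame(
        {
            "observer_id": observer_id,
            "trial_id": np.arange(len(choices)),
            "variant": variant.name,
            "true_model": batch["true_model"],
            "swapped": batch["swapped"],
            "choice": choices,
            "correct_generative": choices == batch["true_model"],
            "correct_ml": choices == ml_solution,
            "centroid_x": batch["centroid"][:, 0],
            "centroid_y": batch["centroid"][:, 1],
        }
    )
    rec.attrs["accuracy_generative"] = float(rec["correct_generative"].mean())
    rec.attrs["accuracy_ml"] = float(rec["correct_ml"].mean())
    return rec


# ---------------------------------------------------------------------------
# choice maps
# ---------------------------------------------------------------------------

def boundary_map(
    observer: ObserverConfig,
    pair: Sequence[ModelManifold],
    grid: tuple[tuple[float, float], tuple[float, float], int, int],
    reps: int,
    rng: np.random.Generator,
    noise: NoiseModel,
) -> dict:
    """Monte-Carlo map of P(choose model 2) over data-centroid locations.

    ``grid`` is ``((x_lo, x_hi), (y_lo, y_hi), nx, ny)``. At each cell the
    trial's points are all placed at the cell center (the centroid is the
    location itself) and the observer decides ``reps`` times. Returns
    ``{"x", "y", "p2", "boundary_y"}`` with ``p2`` of shape (ny, nx) and
    ``boundary_y`` the logistic-fit 0.5 crossing of each column (NaN where
    the fit fails).
    """
    (x_lo, x_hi), (y_lo, y_hi), nx, ny = grid
    xs = np.linspace(x_lo, x_hi, nx)
    ys = np.linspace(y_lo, y_hi, ny)
    gx, gy = np.meshgrid(xs, ys)
    cells = np.stack([gx.ravel(), gy.ravel()], axis=-1)      # (nc, 2)
    X = np.repeat(cells[:, None, :], noise.n_obs, axis=1)    # (nc, N, 2)
    counts = np.zeros(len(cells))
    for _ in range(reps):
        Xc = _corrupt(X, observer.sensory_noise_rho, rng)
        centroids = Xc.mean(axis=1)
        logits = _strategy_logits(
            observer,
            centroids,
            lambda method: evidence.choice_logit_batch(pair, centroids, noise, method),
        )
        counts += _readout(observer, logits, rng) == 2
    p2 = (counts / reps).reshape(ny, nx)
    return {"x": xs, "y": ys, "p2": p2, "boundary_y": boundary_crossings(ys, p2)}


def boundary_crossings(ys, p2) -> np.ndarray:
    """0.5-level of each map column from a logistic fit along y."""
    ny, nx = p2.shape
    out = np.full(nx, np.nan)
    for j in range(nx):
        col = p2[:, j]
        if col.max() < 0.5 or col.min() > 0.5:
            continue
        # initial guess from the empirical crossing
        idx = int(np.argmin(np.abs(col - 0.5)))
        try:
            popt, _ = curve_fit(
                lambda y, y0, k: expit(k * (y - y0)),
                ys,
                col,
                p0=[ys[idx], 4.0 * np.sign(col[-1] - col[0] + 1e-12) / (ys[-1] - ys[0] + 1e-12)],
                maxfev=2000,
            )
            y0 = popt[0]
            if ys.min() <= y0 <= ys.max():
                out[j] = y0
        except RuntimeError:
            pass
    return out


def knn_choice_map(
    records: pd.DataFrame,
    k: int,
    grid: tuple[tuple[float, float], tuple[float, float], int, int],
) -> dict:
    """k-nearest-neighbor interpolation of recorded choices over centroid space.

    ``records`` needs columns ``centroid_x, centroid_y, choice``. Returns the
    mean choice-of-model-2 indicator among the k nearest recorded centroids
    for each grid cell.
    """
    if len(records) < k:
        raise ValueError(f"need at least k={k} records, got {len(records)}")
    (x_lo, x_hi), (y_lo, y_hi), nx, ny = grid
    xs = np.linspace(x_lo, x_hi, nx)
    ys = np.linspace(y_lo, y_hi, ny)
    gx, gy = np.meshgrid(xs, ys)
    pts = records[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
    tree = cKDTree(pts)
    _, idx = tree.query(np.stack([gx.ravel(), gy.ravel()], axis=-1), k=k)
    chose2 = (records["choice"].to_numpy() == 2).astype(float)
    p2 = chose2[idx]
    if k > 1:
        p2 = p2.mean(axis=-1)
    return {"x": xs, "y": ys, "p2": p2.reshape(ny, nx)}
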