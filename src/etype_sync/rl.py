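"""Attention-augmented Rescorla-Wagner model of color-based reversal learning.

The task presents two stimuli per trial, each a binding of three features
(color, location, motion direction).  One color is covertly associated with
reward; the association reverses un-cued between blocks.  The model keeps a
value ``V_i`` for every feature ``i``:

- features of the *chosen* stimulus update by the delta rule
  ``V <- V + eta * (R - V)`` with learning rate ``eta`` in [0, 1];
- features of the *unchosen* stimulus decay, ``V <- (1 - omega) * V``,
  with decay ``omega`` in [0, 1] (the "attention" augmentation);
- the next choice is a softmax over ``beta * sum_i V_i`` of each
  stimulus's bound features, with inverse temperature ``beta > 0``.

The module provides agent simulation, maximum-likelihood fitting with
block-wise cross-validation, trialwise latent variables (p(choice), positive
reward prediction error), and a state-space estimator of the learning trial
within a block (Bernoulli observations on a Gaussian random-walk latent,
smoothed from the whole-block, ideal-observer perspective).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm

__all__ = [
    "RlParams",
    "RlTrace",
    "LearningCurve",
    "update_values",
    "choice_probs",
    "negative_log_likelihood",
    "fit",
    "cross_validate",
    "trial_variables",
    "learning_trial",
]

# Feature inventory: two colors, two locations, two directions -> six values.
N_FEATURES = 6
_COLOR = (0, 1)
_LOCATION = (2, 3)
_DIRECTION = (4, 5)
V0 = 0.5  # initial feature value at session start

_BETA_MAX = 50.0
_LOG_BETA_BOUNDS = (np.log(1e-3), np.log(_BETA_MAX))


@dataclass
class RlParams:
    """Model parameters: learning rate, decay, inverse temperature."""

    eta: float
    omega: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError("eta must lie in [0, 1]")
        if not (0.0 <= self.omega <= 1.0):
            raise ValueError("omega must lie in [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass
class RlTrace:
    """Per-trial latent variables of the model run on a trial table."""

    value_chosen: np.ndarray  # mean feature value of the chosen stimulus
    value_sum_chosen: np.ndarray  # summed feature values (softmax argument)
    value_sum_unchosen: np.ndarray
    p_choice: np.ndarray  # softmax probability of the chosen stimulus
    rpe_pos: np.ndarray  # R - V(chosen) on rewarded trials, NaN otherwise
    nll: float  # total negative log-likelihood of the observed choices


@dataclass
class LearningCurve:
    """State-space learning curve of one block."""

    p_correct: np.ndarray  # smoothed posterior probability of a correct choice
    lower: np.ndarray  # 95% lower confidence bound
    upper: np.ndarray
    learning_trial: int | None  # 1-based; None when never above chance
    sigma2: float = field(default=float("nan"))  # estimated random-walk variance


def update_values(
    V: np.ndarray,
    chosen_features,
    unchosen_features,
    R: float,
    params: RlParams,
) -> np.ndarray:
    """One trial's value update: delta rule on chosen, decay on unchosen."""
    chosen = np.asarray(chosen_features, dtype=int)
    unchosen = np.asarray(unchosen_features, dtype=int)
    if np.intersect1d(chosen, unchosen).size:
        raise ValueError("a feature cannot be both chosen and unchosen")
    V = np.array(V, dtype=float, copy=True)
    V[chosen] += params.eta * (R - V[chosen])
    V[unchosen] *= 1.0 - params.omega
    return V


def choice_probs(V: np.ndarray, stimulus_feature_sets, beta: float) -> np.ndarray:
    """Softmax over the per-stimulus feature-value sums."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    sums = []
    for s in stimulus_feature_sets:
        s = np.asarray(s, dtype=int)
        if s.size == 0:
            raise ValueError("empty stimulus feature set")
        sums.append(float(np.sum(np.asarray(V, dtype=float)[s])))
    z = beta * np.asarray(sums)
    return np.exp(z - logsumexp(z))


def _trial_arrays(trials: pd.DataFrame):
    """Integer feature indices of the chosen/unchosen stimulus per trial.

    Features are binary per dimension, so the unchosen stimulus carries the
    complementary color/location/direction.
    """
    c = trials["chosen_color"].to_numpy(dtype=int)
    l = trials["chosen_location"].to_numpy(dtype=int)
    d = trials["chosen_direction"].to_numpy(dtype=int)
    chosen = np.stack([c, 2 + l, 4 + d], axis=1)
    unchosen = np.stack([1 - c, 2 + (1 - l), 4 + (1 - d)], axis=1)
    R = trials["reward"].to_numpy(dtype=float)
    return chosen, unchosen, R


def _run_model(chosen, unchosen, R, eta, omega, beta):
    """Forward pass over trials; returns per-trial log p(choice) and traces."""
    n = len(R)
    V = np.full(N_FEATURES, V0)
    logp = np.empty(n)
    v_sum_c = np.empty(n)
    v_sum_u = np.empty(n)
    v_mean_c = np.empty(n)
    for t in range(n):
        ci, ui = chosen[t], unchosen[t]
        sc = V[ci].sum()
        su = V[ui].sum()
        # log softmax of the chosen stimulus among the two
        m = max(beta * sc, beta * su)
        logp[t] = beta * sc - (m + np.log(np.exp(beta * sc - m) + np.exp(beta * su - m)))
        v_sum_c[t] = sc
        v_sum_u[t] = su
        v_mean_c[t] = sc / len(ci)
        V[ci] += eta * (R[t] - V[ci])
        V[ui] *= 1.0 - omega
    return logp, v_sum_c, v_sum_u, v_mean_c


def negative_log_likelihood(trials: pd.DataFrame, params: RlParams) -> float:
    """Total NLL of the observed choices under the model."""
    chosen, unchosen, R = _trial_arrays(trials)
    logp, *_ = _run_model(chosen, unchosen, R, params.eta, params.omega, params.beta)
    return float(-logp.sum())


def fit(
    trials: pd.DataFrame,
    n_starts: int = 10,
    seed: int | np.random.Generator = 0,
    fix_omega: float | None = None,
) -> tuple[RlParams, float]:
    """Maximum-likelihood fit of (eta, omega, beta).

    A capped simplex pre-search (Nelder-Mead, 20 iterations) initializes a
    bound-constrained gradient refinement (L-BFGS-B), repeated from
    ``n_starts`` random initializations; the best NLL wins.  ``beta`` is
    searched in log-space within (0, 50].  ``fix_omega`` clamps the decay
    (for nested-model comparisons).
    """
    if len(trials) < 100:
        raise ValueError("need at least 100 trials to fit")
    rng = np.random.default_rng(seed)
    chosen, unchosen, R = _trial_arrays(trials)

    def nll_vec(x):
        eta = float(np.clip(x[0], 0.0, 1.0))
        omega = float(np.clip(x[1], 0.0, 1.0)) if fix_omega is None else fix_omega
        beta = float(np.exp(np.clip(x[2], *_LOG_BETA_BOUNDS)))
        logp, *_ = _run_model(chosen, unchosen, R, eta, omega, beta)
        val = -logp.sum()
        return val if np.isfinite(val) else 1e12

    bounds = [(0.0, 1.0), (0.0, 1.0), _LOG_BETA_BOUNDS]
    best_x, best_nll = None, np.inf
    for _ in range(n_starts):
        x0 = np.array(
            [rng.uniform(0.05, 0.95), rng.uniform(0.0, 0.6), rng.uniform(np.log(0.5), np.log(20.0))]
        )
        pre = minimize(nll_vec, x0, method="Nelder-Mead", options={"maxiter": 20})
        res = minimize(nll_vec, pre.x, method="L-BFGS-B", bounds=bounds)
        if res.fun < best_nll:
            best_nll, best_x = float(res.fun), res.x
    if best_x is None:
        raise RuntimeError("optimizer failed on every start")
    params = RlParams(
        eta=float(np.clip(best_x[0], 0, 1)),
        omega=float(np.clip(best_x[1], 0, 1)) if fix_omega is None else fix_omega,
        beta=float(np.exp(np.clip(best_x[2], *_LOG_BETA_BOUNDS))),
    )
    return params, best_nll


def cross_validate(
    trials: pd.DataFrame,
    frac: float = 0.8,
    n_rep: int = 50,
    seed: int | np.random.Generator = 0,
    n_starts: int = 5,
    fix_omega: float | None = None,
) -> pd.DataFrame:
    """Block-wise 80/20 cross-validation of the model fit.

    Blocks are split into training and held-out sets; parameters are fit on
    the training blocks and the held-out NLL is evaluated by running the
    model over the whole session (values carry across blocks) while summing
    only held-out trials.  Returns one row per repetition with train/test
    NLL per trial.
    """
    if not (0 < frac < 1):
        raise ValueError("frac must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    blocks = trials["block_id"].unique()
    n_train = int(round(frac * len(blocks)))
    if n_train == 0 or n_train == len(blocks):
        raise ValueError("too few blocks to split at this fraction")
    chosen, unchosen, R = _trial_arrays(trials)
    rows = []
    for rep in range(n_rep):
        train_blocks = rng.choice(blocks, size=n_train, replace=False)
        train_mask = trials["block_id"].isin(train_blocks).to_numpy()
        params, _ = fit(
            trials[train_mask], n_starts=n_starts, seed=rng.integers(2**31), fix_omega=fix_omega
        )
        logp, *_ = _run_model(chosen, unchosen, R, params.eta, params.omega, params.beta)
        rows.append(
            {
                "rep": rep,
                "eta": params.eta,
                "omega": params.omega,
                "beta": params.beta,
                "train_nll_per_trial": float(-logp[train_mask].mean()),
                "test_nll_per_trial": float(-logp[~train_mask].mean()),
            }
        )
    return pd.DataFrame(rows)


def trial_variables(trials: pd.DataFrame, params: RlParams) -> RlTrace:
    """Trialwise p(choice), value sums and positive reward prediction error.

    RPE_pos = R - V(chosen stimulus) on rewarded trials (NaN elsewhere),
    with V(chosen) the mean value of the stimulus's three features so that
    the error lives on the outcome scale [0, 1].
    """
    chosen, unchosen, R = _trial_arrays(trials)
    logp, v_sum_c, v_sum_u, v_mean_c = _run_model(
        chosen, unchosen, R, params.eta, params.omega, params.beta
    )
    rpe = np.where(R == 1, R - v_mean_c, np.nan)
    return RlTrace(
        value_chosen=v_mean_c,
        value_sum_chosen=v_sum_c,
        value_sum_unchosen=v_sum_u,
        p_choice=np.exp(logp),
        rpe_pos=rpe,
        nll=float(-logp.sum()),
    )


# ---------------------------------------------------------------------------
# State-space learning-trial estimator
# ---------------------------------------------------------------------------


def _ss_filter_smooth(outcomes: np.ndarray, sigma2: float, x0: float = 0.0):
    """Forward filter + RTS smoother of the Bernoulli random-walk model.

    Latent ``x_t = x_{t-1} + e_t``, ``e ~ N(0, sigma2)``; observation
    ``n_t ~ Bernoulli(logistic(x_t))``; ``x_0`` anchored at chance (0).
    The filtered posterior uses the standard Gaussian (Laplace)
    approximation solved per trial by Newton iterations.
    """
    T = outcomes.size
    xf = np.empty(T)  # filtered mean
    vf = np.empty(T)  # filtered variance
    xp = np.empty(T)  # one-step predictions
    vp = np.empty(T)
    x_prev, v_prev = x0, sigma2
    for t in range(T):
        xpred = x_prev
        vpred = v_prev + sigma2
        x = xpred
        for _ in range(50):  # Newton on the posterior mode
            p = expit(x)
            g = (x - xpred) / vpred - (outcomes[t] - p)
            h = 1.0 / vpred + p * (1 - p)
            step = g / h
            x -= step
            if abs(step) < 1e-10:
                break
        p = expit(x)
        xf[t] = x
        vf[t] = 1.0 / (1.0 / vpred + p * (1 - p))
        xp[t], vp[t] = xpred, vpred
        x_prev, v_prev = xf[t], vf[t]
    # RTS smoothing
    xs = np.empty(T)
    vs = np.empty(T)
    xs[-1], vs[-1] = xf[-1], vf[-1]
    A = np.empty(T - 1) if T > 1 else np.empty(0)
    for t in range(T - 2, -1, -1):
        A[t] = vf[t] / vp[t + 1]
        xs[t] = xf[t] + A[t] * (xs[t + 1] - xp[t + 1])
        vs[t] = vf[t] + A[t] ** 2 * (vs[t + 1] - vp[t + 1])
    return xs, vs, A, xf, vf


def learning_trial(
    outcomes,
    max_em_iter: int = 100,
    tol: float = 1e-5,
    sigma2_init: float = 0.05,
    ci: float = 0.95,
) -> LearningCurve:
    """Learning curve and learning trial of one block of 0/1 outcomes.

    EM estimates the random-walk variance; the smoothed (whole-block,
    ideal-observer) posterior yields per-trial probability-correct bounds.
    The learning trial is the earliest trial whose lower bound exceeds the
    0.5 chance level.  Degenerate blocks are handled directly: all-correct
    blocks learn at trial 1, all-error blocks never learn.
    """
    outcomes = np.asarray(outcomes, dtype=float)
    if outcomes.size < 5:
        raise ValueError("block must contain at least 5 trials")
    if not np.all(np.isin(outcomes, (0.0, 1.0))):
        raise ValueError("outcomes must be 0 or 1")
    if outcomes.min() == 1.0:
        ones = np.ones_like(outcomes)
        return LearningCurve(ones, ones * 0.5 + 1e-6, ones, 1)
    if outcomes.max() == 0.0:
        zeros = np.zeros_like(outcomes)
        return LearningCurve(zeros, zeros, zeros + 0.5, None)

    sigma2 = sigma2_init
    for _ in range(max_em_iter):
        xs, vs, A, _, _ = _ss_filter_smooth(outcomes, sigma2)
        # E[(x_t - x_{t-1})^2] including the anchored x_0 = 0 step
        cov = A * vs[1:]
        d = (
            np.sum((xs[1:] - xs[:-1]) ** 2 + vs[1:] + vs[:-1] - 2 * cov)
            + xs[0] ** 2
            + vs[0]
        )
        new_sigma2 = float(np.clip(d / outcomes.size, 1e-6, 10.0))
        if abs(new_sigma2 - sigma2) < tol:
            sigma2 = new_sigma2
            break
        sigma2 = new_sigma2

    xs, vs, _, _, _ = _ss_filter_smooth(outcomes, sigma2)
    zcrit = float(norm.ppf(0.5 + ci / 2))
    lower = expit(xs - zcrit * np.sqrt(vs))
    upper = expit(xs + zcrit * np.sqrt(vs))
    above = np.nonzero(lower > 0.5)[0]
    lt = int(above[0]) + 1 if above.size else None
    return LearningCurve(expit(xs), lower, upper, lt, sigma2)
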