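"""Simulated forced-choice respondents and logistic recovery.

A respondent chooses the round shape with probability
``logistic(intercept_p + sum_j slope_j * x_j)`` where ``intercept_p`` varies
across participants (Gaussian spread ``participant_sd`` in log-odds).
Responses are coded 1 for a round choice, 0 for a spiky choice; per-stimulus
round scores are the percentage of round choices across participants.
Effects are recovered from the non-aggregated trials with a fixed-effects
logistic regression (participant heterogeneity is a robustness dimension of
the generator, not an estimand here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .errors import ArgumentError, SeparationError
from .model import ExperimentTable

__all__ = [
    "RespondentModel",
    "simulate_trials",
    "aggregate_round_score",
    "to_experiment_table",
    "glm_fit",
]


@dataclass(frozen=True)
class RespondentModel:
    """Latent decision model of one simulated participant population."""

    intercept: float = 0.0
    slopes: dict[str, float] = field(default_factory=dict)
    participant_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.participant_sd < 0:
            raise ArgumentError("participant_sd must be nonnegative")


def simulate_trials(
    predictors: pd.DataFrame,
    model: RespondentModel,
    n_participants: int,
    repetitions: int = 1,
) -> pd.DataFrame:
    """Simulate a forced-choice trial table.

    ``predictors`` must contain a ``stimulus`` column plus one column per
    predictor named in ``model.slopes``; values must be finite. Each
    participant responds to every stimulus ``repetitions`` times. Returns a
    tidy table with columns stimulus, participant, response and the
    predictor columns.
    """
    if n_participants < 1:
        raise ArgumentError("need at least one participant")
    if repetitions < 1:
        raise ArgumentError("need at least one repetition")
    if "stimulus" not in predictors.columns:
        raise ArgumentError("predictor table must have a 'stimulus' column")
    missing = [p for p in model.slopes if p not in predictors.columns]
    if missing:
        raise ArgumentError(f"predictor columns missing from table: {missing}")
    names = list(model.slopes)
    X = predictors[names].to_numpy(dtype=np.float64) if names else np.zeros(
        (len(predictors), 0)
    )
    if not np.all(np.isfinite(X)):
        raise ArgumentError("predictor values must be finite")

    rng = np.random.default_rng(model.seed)
    slopes = np.array([model.slopes[p] for p in names])
    eta_stim = X @ slopes if names else np.zeros(len(predictors))

    frames = []
    for p in range(n_participants):
        intercept_p = model.intercept + model.participant_sd * rng.standard_normal()
        prob = expit(intercept_p + eta_stim)
        for rep in range(repetitions):
            responses = rng.random(len(predictors)) < prob
            frame = predictors.copy()
            frame.insert(1, "participant", p)
            frame.insert(2, "repetition", rep)
            frame["response"] = responses.astype(int)
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def aggregate_round_score(trials: pd.DataFrame) -> pd.Series:
    """Per-stimulus round score: 100 x mean response across all trials."""
    if "stimulus" not in trials.columns or "response" not in trials.columns:
        raise ArgumentError("trial table needs 'stimulus' and 'response' columns")
    if trials.empty:
        raise ArgumentError("empty trial table")
    counts = trials.groupby("stimulus")["response"].count()
    if (counts < 1).any():
        raise ArgumentError("every stimulus needs at least one trial")
    return 100.0 * trials.groupby("stimulus")["response"].mean()


def to_experiment_table(trials: pd.DataFrame, name: str = "simulated",
                        continuity_available: bool = True) -> ExperimentTable:
    """Aggregate trials into the score-table format the fitter consumes."""
    scores = aggregate_round_score(trials)
    df = pd.DataFrame(
        {
            "stimulus": scores.index,
            "round_score": scores.to_numpy(),
            "scale_min": 0.0,
            "scale_max": 100.0,
        }
    )
    return ExperimentTable(df, name=name, continuity_available=continuity_available)


def _separated_predictor(y: np.ndarray, X: pd.DataFrame) -> str | None:
    for name in X.columns:
        x = X[name].to_numpy(dtype=np.float64)
        if x[y == 1].size and x[y == 0].size:
            if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
                return name
    return None


def glm_fit(trials: pd.DataFrame, predictor_names: list[str]) -> pd.DataFrame:
    """Fixed-effects logistic regression of response on the named predictors.

    Returns one row per term (const first) with maximum-likelihood estimate,
    Wald standard error, z and two-sided p. Perfectly separated data raise a
    diagnostic error naming the offending predictor.
    """
    if not predictor_names:
        raise ArgumentError("need at least one predictor")
    y = trials["response"].to_numpy(dtype=np.float64)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ArgumentError("responses must be coded 0/1")
    if np.unique(y).size < 2:
        raise ArgumentError("responses are all identical; logistic fit undefined")
    X = trials[list(predictor_names)].astype(np.float64)
    culprit = _separated_predictor(y, X)
    if culprit is not None:
        raise SeparationError(
            f"perfect separation on predictor {culprit!r}; estimates diverge"
        )
    design = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.Logit(y, design).fit(disp=False, maxiter=200)
    except Exception as exc:  # statsmodels' own separation guard
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    return pd.DataFrame(
        {
            "term": design.columns,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "z": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
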