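"""Linear prediction of round scores from Balance (and Continuity).

For one experiment, per-stimulus round scores are regressed on the acoustic
Balance index — plus Continuity when the stimulus set supports it — by
ordinary least squares, separately for every candidate boundary ``b`` in the
scan range. The boundary maximizing explained variance is selected. The
reported ``r^2`` is the squared correlation between observed and fitted
scores, and the ``t``/``p`` statistics come from the slope test of the
simple regression of observed on fitted scores, mirroring the usual
observed-vs-predicted scatter summary.

Scores are fitted on each study's native scale; no rescaling or predictor
standardization is applied, so coefficients are in score units per unit of
(linear-power) Balance or per log-unit of Continuity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError, RankDeficiencyError
from .indices import IndexResult

__all__ = ["ExperimentTable", "FitResult", "fit_linear", "scan_boundary", "predict"]


@dataclass(frozen=True)
class ExperimentTable:
    """Per-stimulus averaged round scores for one experiment.

    ``data`` columns: ``stimulus`` (unique label), ``round_score`` (on the
    study's own scale), ``scale_min``, ``scale_max``.
    """

    data: pd.DataFrame
    name: str = ""
    continuity_available: bool = True

    REQUIRED = ("stimulus", "round_score", "scale_min", "scale_max")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ArgumentError(f"score table missing columns: {missing}")
        if df["stimulus"].duplicated().any():
            dups = sorted(df.loc[df["stimulus"].duplicated(), "stimulus"].unique())
            raise ArgumentError(f"duplicate stimulus labels: {dups}")
        bad = df[
            (df["round_score"] < df["scale_min"]) | (df["round_score"] > df["scale_max"])
        ]
        if len(bad):
            raise ArgumentError(
                f"round scores outside the declared scale for: "
                f"{sorted(bad['stimulus'])}"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def scores(self) -> pd.Series:
        return self.data.set_index("stimulus")["round_score"]

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "ExperimentTable":
        return cls(pd.read_csv(path), **kwargs)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class FitResult:
    """Selected boundary, coefficients and fit statistics for one experiment."""

    b_star: int
    coefficients: dict[str, float]  # intercept, balance[, continuity]
    r2: float
    t_stat: float
    p_value: float
    predictions: dict[str, float]
    continuity_used: bool
    r2_by_b: dict[int, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "b_star": self.b_star,
            "coefficients": {k: repr(v) for k, v in self.coefficients.items()},
            "r2": repr(self.r2),
            "t_stat": repr(self.t_stat),
            "p_value": repr(self.p_value),
            "continuity_used": self.continuity_used,
            "predictions": {k: repr(v) for k, v in self.predictions.items()},
            "r2_by_b": {str(k): repr(v) for k, v in self.r2_by_b.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _observed_vs_fitted_stats(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float, float]:
    """(r2, t, p) of the simple regression of observed on fitted values.

    Degenerate cases (constant observed or fitted values) return the null
    contract r2 = 0, t = 0, p = 1.
    """
    if np.ptp(y) == 0.0 or np.ptp(yhat) == 0.0:
        return 0.0, 0.0, 1.0
    res = stats.linregress(yhat, y)
    r2 = float(res.rvalue**2)
    n = y.size
    if r2 >= 1.0:  # exact fit: infinite t, p -> 0
        return 1.0, float("inf"), 0.0
    t = float(res.rvalue * np.sqrt((n - 2) / (1.0 - r2)))
    return r2, t, float(res.pvalue)


def fit_linear(
    predictors: pd.DataFrame | np.ndarray,
    scores: np.ndarray | pd.Series,
) -> tuple[dict[str, float], float, float, float, np.ndarray]:
    """Ordinary least squares of scores on the given predictor columns.

    Returns ``(coefficients, r2, t, p, fitted)`` where ``coefficients`` maps
    ``intercept`` and each predictor column name to its estimate.
    """
    if isinstance(predictors, pd.DataFrame):
        names = list(predictors.columns)
        X = predictors.to_numpy(dtype=np.float64)
    else:
        X = np.atleast_2d(np.asarray(predictors, dtype=np.float64))
        if X.shape[0] == 1:
            X = X.T
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(scores, dtype=np.float64)
    n = y.size
    if X.shape[0] != n:
        raise ArgumentError(f"{X.shape[0]} predictor rows vs {n} scores")
    if n < 3:
        raise ArgumentError(f"need at least 3 stimuli to fit, got {n}")
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0.0:
            raise RankDeficiencyError(f"predictor {name!r} is constant")

    design = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise RankDeficiencyError("design matrix is rank deficient")
    fitted = design @ beta
    r2, t, p = _observed_vs_fitted_stats(y, fitted)
    coefficients = {"intercept": float(beta[0])}
    coefficients.update({name: float(b) for name, b in zip(names, beta[1:])})
    return coefficients, r2, t, p, fitted


def _predictor_frame(
    indices: list[IndexResult], b: int, use_continuity: bool
) -> pd.DataFrame:
    rows = {
        "balance": [ix.balance(b) for ix in indices],
    }
    if use_continuity:
        missing = [ix.label for ix in indices if ix.continuity is None]
        if missing:
            raise ArgumentError(
                f"continuity requested but absent for stimuli: {missing}"
            )
        rows["continuity"] = [ix.continuity for ix in indices]
    return pd.DataFrame(rows, index=[ix.label for ix in indices])


def scan_boundary(
    indices: list[IndexResult],
    table: ExperimentTable,
    b_range: tuple[int, int] | None = None,
    use_continuity: bool | None = None,
) -> FitResult:
    """Fit at every boundary in the scan range and keep the best.

    The fit with maximal explained variance wins; ties break toward the
    smallest ``b``. ``use_continuity`` defaults to the table's
    ``continuity_available`` flag (the Balance-only fallback mirrors
    experiments whose stimuli carry no interior envelope dip).
    """
    if not indices:
        raise ArgumentError("no stimuli to fit")
    by_label = {ix.label: ix for ix in indices}
    unmatched = [s for s in table.data["stimulus"] if s not in by_label]
    if unmatched:
        raise ArgumentError(f"score table stimuli without audio indices: {unmatched}")
    ordered = [by_label[s] for s in table.data["stimulus"]]

    if use_continuity is None:
        use_continuity = table.continuity_available and all(
            ix.continuity is not None for ix in ordered
        )
    if b_range is None:
        bs = sorted(ordered[0].balance_by_b)
    else:
        bs = list(range(b_range[0], b_range[1] + 1))
    if not bs:
        raise ArgumentError("empty boundary range")

    y = table.data["round_score"].to_numpy(dtype=np.float64)
    best: FitResult | None = None
    r2_by_b: dict[int, float] = {}
    for b in bs:
        X = _predictor_frame(ordered, b, use_continuity)
        coefficients, r2, t, p, fitted = fit_linear(X, y)
        r2_by_b[b] = r2
        if best is None or r2 > best.r2:
            best = FitResult(
                b_star=b,
                coefficients=coefficients,
                r2=r2,
                t_stat=t,
                p_value=p,
                predictions={
                    label: float(v)
                    for label, v in zip(table.data["stimulus"], fitted)
                },
                continuity_used=use_continuity,
            )
    assert best is not None
    return FitResult(**{**best.__dict__, "r2_by_b": r2_by_b})


def predict(fit: FitResult, indices: list[IndexResult]) -> dict[str, float]:
    """Apply a fitted model to new stimuli at the fit's selected boundary."""
    out: dict[str, float] = {}
    for ix in indices:
        if fit.continuity_used and ix.continuity is None:
            raise ArgumentError(
                f"fit uses continuity but stimulus {ix.label!r} has none"
            )
        value = fit.coefficients["intercept"] + fit.coefficients["balance"] * ix.balance(
            fit.b_star
        )
        if fit.continuity_used:
            value += fit.coefficients["continuity"] * ix.continuity
        if not np.isfinite(value):
            raise ArgumentError(f"non-finite prediction for {ix.label!r}")
        out[ix.label] = float(value)
    return out
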