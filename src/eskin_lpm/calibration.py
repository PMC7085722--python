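"""Linear calibration of E-Skin resistance change against the reference angle.

The mapping is the simple least-squares line Y = mX + c (angle in degrees
as a function of resistance change in ohms), with the slope
m = Σ(xᵢ−x̄)(yᵢ−ȳ)/Σ(xᵢ−x̄)² and intercept c = ȳ − m·x̄ minimising the
quadratic loss L = Σ(yᵢ−pᵢ)².  Fit quality is reported as R², adjusted
R² = 1 − (1−R²)(n−1)/(n−k−1), and a two-tailed p-value (slope t-test for
one predictor, overall F-test for two).  Per-second samples are treated
as independent observations when computing p — the convention of the
original analysis — even though consecutive seconds are autocorrelated.

The protocol fits on the first 10 repetitions of a movement and scores
the mean absolute error (MAE, degrees) on the remaining 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .core import (
    CollinearityError,
    DegenerateFitError,
    Movement,
    ParameterError,
    SplitError,
    TimeSeries,
)
from .preprocessing import AlignedPair
from .synthetic import RepetitionTruth

__all__ = [
    "LinearModel",
    "FitStats",
    "EvaluationReport",
    "TrainTestSplit",
    "fit_linear",
    "fit_linear_multi",
    "split_by_repetition",
    "predict_and_score",
    "calibrate_movement",
]


@dataclass
class LinearModel:
    """Fitted linear map from resistance change (ohms) to angle (degrees)."""

    predictors: tuple[str, ...]
    coef: tuple[float, ...]
    intercept: float

    def __post_init__(self) -> None:
        if len(self.predictors) not in (1, 2):
            raise ParameterError("LinearModel supports 1 or 2 predictors")
        if len(self.coef) != len(self.predictors):
            raise ParameterError("one coefficient per predictor required")
        if not all(np.isfinite(c) for c in (*self.coef, self.intercept)):
            raise ParameterError("coefficients must be finite")

    @property
    def m(self) -> float:
        """Slope of the single-predictor model, degrees per ohm."""
        return self.coef[0]

    @property
    def c(self) -> float:
        """Intercept, degrees."""
        return self.intercept

    def predict(self, *xs: np.ndarray) -> np.ndarray:
        if len(xs) != len(self.predictors):
            raise ParameterError(
                f"model expects {len(self.predictors)} predictor arrays, got {len(xs)}"
            )
        out = np.full_like(np.asarray(xs[0], dtype=float), self.intercept)
        for coef, x in zip(self.coef, xs):
            out = out + coef * np.asarray(x, dtype=float)
        return out


@dataclass
class FitStats:
    """Goodness-of-fit summary for a calibration model."""

    r: float
    r2: float
    adj_r2: float
    p_value: float
    n: int
    loss: float  # quadratic loss: sum of squared residuals, degrees^2


def _as_1d(x) -> np.ndarray:
    arr = np.asarray(x.values if isinstance(x, TimeSeries) else x, dtype=float)
    if arr.ndim != 1:
        raise ParameterError("expected a 1-D array of aligned values")
    return arr


def fit_linear(x, y) -> tuple[LinearModel, FitStats]:
    """Least-squares line y = m·x + c with fit statistics.

    ``p_value`` is the two-tailed t-test on the slope with n−2 degrees of
    freedom.  Raises :class:`DegenerateFitError` if x has zero variance.
    """
    xa, ya = _as_1d(x), _as_1d(y)
    if len(xa) != len(ya):
        raise ParameterError("x and y must have equal length")
    if len(xa) < 3:
        raise ParameterError("need at least 3 points for a linear fit")
    if np.ptp(xa) == 0:
        raise DegenerateFitError("predictor has zero variance")
    res = sm.OLS(ya, sm.add_constant(xa)).fit()
    m = float(res.params[1])
    c = float(res.params[0])
    r2 = float(res.rsquared)
    stats = FitStats(
        r=float(np.sign(m) * np.sqrt(max(r2, 0.0))),
        r2=r2,
        adj_r2=float(res.rsquared_adj),
        p_value=float(res.pvalues[1]),
        n=len(xa),
        loss=float(res.ssr),
    )
    return LinearModel(predictors=("x",), coef=(m,), intercept=c), stats


def fit_linear_multi(x1, x2, y, names: tuple[str, str] = ("x1", "x2")) -> tuple[LinearModel, FitStats]:
    """Two-predictor ordinary least squares with intercept.

    ``p_value`` is the overall F-test.  Raises :class:`CollinearityError`
    when the design matrix [1, x1, x2] is rank deficient.
    """
    a1, a2, ya = _as_1d(x1), _as_1d(x2), _as_1d(y)
    if not (len(a1) == len(a2) == len(ya)):
        raise ParameterError("x1, x2 and y must have equal length")
    if len(ya) < 4:
        raise ParameterError("need at least 4 points for a two-predictor fit")
    design = sm.add_constant(np.column_stack([a1, a2]))
    if np.linalg.matrix_rank(design) < 3:
        raise CollinearityError("design matrix is rank deficient (collinear predictors)")
    res = sm.OLS(ya, design).fit()
    r2 = float(res.rsquared)
    stats = FitStats(
        r=float(np.sqrt(max(r2, 0.0))),
        r2=r2,
        adj_r2=float(res.rsquared_adj),
        p_value=float(res.f_pvalue),
        n=len(ya),
        loss=float(res.ssr),
    )
    model = LinearModel(
        predictors=names,
        coef=(float(res.params[1]), float(res.params[2])),
        intercept=float(res.params[0]),
    )
    return model, stats


@dataclass
class TrainTestSplit:
    """Row-level train/test assignment of aligned seconds to repetitions."""

    train_mask: np.ndarray
    test_mask: np.ndarray
    train_reps: list[int]
    test_reps: list[int]
    rep_of_row: np.ndarray  # repetition id per aligned row, -1 outside any window

    def __post_init__(self) -> None:
        if np.any(self.train_mask & self.test_mask):
            raise SplitError("train and test seconds overlap")


def split_by_repetition(
    aligned: AlignedPair,
    truth: list[RepetitionTruth],
    n_train: int = 10,
    n_test: int = 5,
    movement: Movement | None = None,
    include_rest: bool = True,
) -> TrainTestSplit:
    """Chronological 10/5 train/test split of aligned seconds.

    Each aligned second is assigned to the repetition whose ground-truth
    window [start, end) contains it; the first ``n_train`` repetitions
    (chronological) form the training rows and the last ``n_test`` the
    test rows.  ``include_rest=False`` drops the rest seconds preceding
    each ramp (the window's leading rest).
    """
    reps = sorted(
        (r for r in truth if movement is None or r.movement == movement),
        key=lambda r: r.start_ms,
    )
    if len(reps) < n_train + n_test:
        raise SplitError(
            f"need {n_train + n_test} repetitions for a {n_train}/{n_test} split, "
            f"got {len(reps)}"
        )
    reps = reps[: n_train + n_test]
    t_ms = aligned.seconds.astype(float) * 1000.0
    rep_of_row = np.full(len(aligned), -1, dtype=int)
    for r in reps:
        start = r.angle_onset_ms if not include_rest else r.start_ms
        rep_of_row[(t_ms >= start) & (t_ms < r.end_ms)] = r.rep_id
    train_ids = [r.rep_id for r in reps[:n_train]]
    test_ids = [r.rep_id for r in reps[n_train:]]
    train_mask = np.isin(rep_of_row, train_ids)
    test_mask = np.isin(rep_of_row, test_ids)
    return TrainTestSplit(
        train_mask=train_mask,
        test_mask=test_mask,
        train_reps=train_ids,
        test_reps=test_ids,
        rep_of_row=rep_of_row,
    )


@dataclass
class EvaluationReport:
    """Held-out evaluation of a calibration model."""

    mae: float  # degrees
    n_test: int
    per_rep_mae: dict[int, float] = field(default_factory=dict)
    train_reps: list[int] = field(default_factory=list)
    test_reps: list[int] = field(default_factory=list)


def predict_and_score(
    model: LinearModel,
    xs: tuple[np.ndarray, ...] | np.ndarray,
    y: np.ndarray,
    rep_of_row: np.ndarray | None = None,
    train_reps: list[int] | None = None,
    test_reps: list[int] | None = None,
) -> EvaluationReport:
    """Predict angles on test rows and report the MAE in degrees."""
    if isinstance(xs, np.ndarray):
        xs = (xs,)
    ya = _as_1d(y)
    if len(ya) == 0:
        raise ParameterError("test set is empty")
    pred = model.predict(*xs)
    abs_err = np.abs(pred - ya)
    per_rep: dict[int, float] = {}
    if rep_of_row is not None:
        for rid in np.unique(rep_of_row):
            if rid >= 0:
                per_rep[int(rid)] = float(abs_err[rep_of_row == rid].mean())
    return EvaluationReport(
        mae=float(abs_err.mean()),
        n_test=len(ya),
        per_rep_mae=per_rep,
        train_reps=train_reps or [],
        test_reps=test_reps or [],
    )


def calibrate_movement(
    aligned: AlignedPair,
    truth: list[RepetitionTruth],
    movement: Movement,
    predictors: tuple[str, ...],
    n_train: int = 10,
    n_test: int = 5,
    include_rest: bool = True,
) -> tuple[LinearModel, FitStats, EvaluationReport]:
    """Fit the train reps of one movement and score MAE on the test reps."""
    split = split_by_repetition(
        aligned, truth, n_train=n_train, n_test=n_test, movement=movement,
        include_rest=include_rest,
    )
    y = aligned.angle_values
    cols = [aligned.eskin_values[p] for p in predictors]
    if len(predictors) == 1:
        model, stats = fit_linear(cols[0][split.train_mask], y[split.train_mask])
    else:
        model, stats = fit_linear_multi(
            cols[0][split.train_mask], cols[1][split.train_mask], y[split.train_mask],
            names=tuple(predictors),
        )
    report = predict_and_score(
        model,
        tuple(c[split.test_mask] for c in cols),
        y[split.test_mask],
        rep_of_row=split.rep_of_row[split.test_mask],
        train_reps=split.train_reps,
        test_reps=split.test_reps,
    )
    return model, stats, report
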