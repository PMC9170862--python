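"""The depth-of-anaesthesia regression index.

:class:`DoAIndexModel` maps the per-window feature triplet
(median coefficient, mean spectral entropy, mean SODP) to a 0-100 depth
index, supervised by the reference (BIS-like) index aligned to each
window's end time.  Two estimators are supported:

* ``svm_linear`` — epsilon-insensitive support vector regression with a
  linear kernel: residuals smaller than ``epsilon`` cost nothing, larger
  ones a linear penalty scaled by ``cost``, plus an L2 penalty on the
  weights.  This is the index proper.
* ``linear`` — ordinary least squares, the baseline.

Features are z-scored on the training set before fitting (the median
coefficient lives on a uV scale, the entropies on bit/log scales; a linear
kernel needs them commensurate).  Predictions are clipped to [0, 100] and
optionally stabilised with a trailing 6-s moving average.

Usage follows the model/results convention::

    model = DoAIndexModel(features, kind="svm_linear")
    res = model.fit()
    trace = res.predict(test_features, smooth=True)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.svm import SVR

__all__ = [
    "FEATURE_COLUMNS",
    "IndexTrace",
    "DoAIndexModel",
    "DoAIndexResults",
    "train_index",
    "predict_index",
    "smooth_index",
]

FEATURE_COLUMNS = ("median_coeff", "se_mean", "sodp_mean")
_FORMAT_VERSION = 1


@dataclass(frozen=True)
class IndexTrace:
    """Depth-index time series at the windows' end times (1 Hz for 1-s stride)."""

    t: np.ndarray
    value: np.ndarray
    smoothed: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "value", np.asarray(self.value, dtype=float))
        if self.t.shape != self.value.shape:
            raise ValueError("t and value must have the same length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "value": self.value})


def smooth_index(trace: IndexTrace, window_n: int = 6) -> IndexTrace:
    """Trailing moving average over ``window_n`` seconds.

    value(t) = mean of the trace at t-window_n+1 .. t; the first
    ``window_n - 1`` points average whatever is available.  Missing (NaN)
    points are excluded from the local mean.
    """
    v = trace.value
    out = np.empty_like(v)
    for i in range(v.size):
        chunk = v[max(0, i - window_n + 1) : i + 1]
        good = chunk[np.isfinite(chunk)]
        out[i] = good.mean() if good.size else np.nan
    return IndexTrace(t=trace.t.copy(), value=out, smoothed=True)


class DoAIndexModel:
    """Regression index from window features to the 0-100 depth scale.

    Parameters
    ----------
    features : DataFrame
        Must carry the columns ``median_coeff, se_mean, sodp_mean`` and,
        for fitting, a finite ``ref_value`` target per row (>= 30 rows).
    kind : {"svm_linear", "linear"}
    cost : float
        SVM penalty on residuals beyond epsilon (C).
    epsilon : float
        Half-width of the SVM's zero-cost residual tube, in index units.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        kind: str = "svm_linear",
        cost: float = 1.0,
        epsilon: float = 0.1,
    ):
        if kind not in ("svm_linear", "linear"):
            raise ValueError(f"unknown model kind {kind!r}")
        missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
        if missing:
            raise ValueError(f"feature table lacks columns {missing}")
        if "ref_value" not in features.columns or features["ref_value"].isna().any():
            raise ValueError("every training row needs a finite ref_value target")
        if len(features) < 30:
            raise ValueError(
                f"need at least 30 training rows, got {len(features)}"
            )
        self.features = features.reset_index(drop=True)
        self.kind = kind
        self.cost = float(cost)
        self.epsilon = float(epsilon)

        X = self.features[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        sd = X.std(axis=0, ddof=0)
        flat = [c for c, s in zip(FEATURE_COLUMNS, sd) if s == 0]
        if flat:
            raise ValueError(f"zero-variance feature(s): {flat}")
        self._X = X
        self._y = self.features["ref_value"].to_numpy(dtype=float)

    @classmethod
    def from_recordings(
        cls,
        recordings,
        window_s: float = 56.0,
        overlap_s: float = 55.0,
        n_bands: int = 15,
        band: tuple[float, float] = (0.1, 64.0),
        **kwargs,
    ) -> "DoAIndexModel":
        """Build the model straight from recordings (filter, window, featurise)."""
        from .pipeline import extract_features

        tables = [
            extract_features(
                rec,
                window_s=window_s,
                overlap_s=overlap_s,
                n_bands=n_bands,
                band=band,
            )
            for rec in recordings
        ]
        feats = pd.concat(tables, ignore_index=True).dropna(subset=["ref_value"])
        return cls(feats, **kwargs)

    def fit(self) -> "DoAIndexResults":
        mean = self._X.mean(axis=0)
        scale = self._X.std(axis=0, ddof=0)
        Z = (self._X - mean) / scale
        if self.kind == "svm_linear":
            est = SVR(kernel="linear", C=self.cost, epsilon=self.epsilon)
            est.fit(Z, self._y)
            coef = est.coef_.ravel().copy()
            intercept = float(est.intercept_[0])
        else:
            est = LinearRegression()
            est.fit(Z, self._y)
            coef = est.coef_.copy()
            intercept = float(est.intercept_)
        return DoAIndexResults(
            model=self,
            scaler_mean=mean,
            scaler_scale=scale,
            coef=coef,
            intercept=intercept,
        )


class DoAIndexResults:
    """Fitted index: standardiser, weights, diagnostics and prediction."""

    def __init__(
        self,
        model: DoAIndexModel,
        scaler_mean: np.ndarray,
        scaler_scale: np.ndarray,
        coef: np.ndarray,
        intercept: float,
    ):
        self.model = model
        self.scaler_mean = np.asarray(scaler_mean, dtype=float)
        self.scaler_scale = np.asarray(scaler_scale, dtype=float)
        self.coef = np.asarray(coef, dtype=float)
        self.intercept = float(intercept)

    @property
    def params(self) -> pd.Series:
        """Intercept and weights on the standardised features."""
        return pd.Series(
            np.concatenate([[self.intercept], self.coef]),
            index=["const", *FEATURE_COLUMNS],
        )

    @property
    def fittedvalues(self) -> IndexTrace:
        return self.predict(self.model.features)

    def predict(
        self,
        features: pd.DataFrame,
        smooth: bool = False,
        smooth_n: int = 6,
    ) -> IndexTrace:
        """Index trace for a feature table, clipped to [0, 100].

        Rows with a non-finite feature are flagged missing (NaN) in the
        trace rather than extrapolated.
        """
        if len(features) == 0:
            return IndexTrace(t=np.empty(0), value=np.empty(0))
        X = features[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        ok = np.isfinite(X).all(axis=1)
        Z = (X[ok] - self.scaler_mean) / self.scaler_scale
        raw = np.full(len(features), np.nan)
        raw[ok] = np.clip(Z @ self.coef + self.intercept, 0.0, 100.0)
        t = (
            features["t_end"].to_numpy(dtype=float)
            if "t_end" in features.columns
            else np.arange(len(features), dtype=float)
        )
        trace = IndexTrace(t=t, value=raw)
        return smooth_index(trace, smooth_n) if smooth else trace

    def save(self, path) -> None:
        """Serialise the fitted index to one portable file."""
        joblib.dump(
            {
                "format_version": _FORMAT_VERSION,
                "kind": self.model.kind,
                "cost": self.model.cost,
                "epsilon": self.model.epsilon,
                "scaler_mean": self.scaler_mean,
                "scaler_scale": self.scaler_scale,
                "coef": self.coef,
                "intercept": self.intercept,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "DoAIndexResults":
        blob = joblib.load(path)
        if blob.get("format_version") != _FORMAT_VERSION:
            raise ValueError("unrecognised model file version")
        dummy = _UnboundModel(blob["kind"], blob["cost"], blob["epsilon"])
        return cls(
            model=dummy,
            scaler_mean=blob["scaler_mean"],
            scaler_scale=blob["scaler_scale"],
            coef=blob["coef"],
            intercept=blob["intercept"],
        )

    def summary(self) -> str:
        lines = [
            "Depth-of-anaesthesia index",
            "=" * 42,
            f"estimator      {self.model.kind}",
        ]
        if self.model.kind == "svm_linear":
            lines.append(
                f"cost / epsilon {self.model.cost:g} / {self.model.epsilon:g}"
            )
        lines.append("coefficients (standardised features):")
        for name, val in self.params.items():
            lines.append(f"  {name:<14}{val: .4f}")
        feats = getattr(self.model, "features", None)
        if feats is not None:
            pred = self.predict(self.model.features).value
            y = self.model.features["ref_value"].to_numpy(dtype=float)
            resid = pred - y
            mse = float(np.mean(resid**2))
            r = float(np.corrcoef(pred, y)[0, 1])
            lines += [
                f"n windows      {len(y)}",
                f"training r     {r:.4f}",
                f"training MSE   {mse:.2f}  (RMSE {np.sqrt(mse):.2f})",
            ]
        return "\n".join(lines)


class _UnboundModel:
    """Stand-in model for results loaded from disk (no training features)."""

    features = None

    def __init__(self, kind: str, cost: float, epsilon: float):
        self.kind = kind
        self.cost = cost
        self.epsilon = epsilon


def train_index(
    features: pd.DataFrame,
    kind: str = "svm_linear",
    cost: float = 1.0,
    epsilon: float = 0.1,
) -> DoAIndexResults:
    """Fit the index on a feature table; functional spelling of the model API."""
    return DoAIndexModel(features, kind=kind, cost=cost, epsilon=epsilon).fit()


def predict_index(results: DoAIndexResults, features: pd.DataFrame) -> IndexTrace:
    """Raw (unsmoothed) index trace for a feature table."""
    return results.predict(features)
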