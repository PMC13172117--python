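"""The single-feature logistic cribriform model.

The deployed classifier uses one radiomic feature: the 90th percentile of
ADC values inside a region (low ADC reflects the dense cellular architecture
of cribriform growth, so the fitted slope on this feature is negative).
This module provides feature extraction, model fitting on region-level
samples, prediction, and JSON (de)serialisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "LogisticCribModel",
    "RegionSample",
    "extract_p90",
    "fit_crib_model",
    "predict_prob",
    "default_model",
]

#: Canonical feature tag carried by every model.
FEATURE_NAME = "adc_p90"


def extract_p90(values) -> float:
    """90th percentile of a collection of ADC samples.

    Uses the linear-interpolation convention: with ``n`` sorted values the
    percentile sits at fractional position ``0.9 * (n - 1)``.

    Raises
    ------
    ValueError
        If the input is empty or contains no finite value.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("cannot take a percentile of an empty collection")
    if not np.all(np.isfinite(arr)):
        raise ValueError("ADC samples must be finite")
    return float(np.percentile(arr, 90.0, method="linear"))


@dataclass
class RegionSample:
    """A histology-proven region: its p90-ADC feature and its label.

    ``label`` is 1 for cribriform (GP4Crib+), 0 for other Gleason patterns
    (GP3 or non-cribriform GP4).
    """

    p90_adc: float
    label: int

    def __post_init__(self) -> None:
        if self.p90_adc < 0:
            raise ValueError("p90 ADC must be nonnegative")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (other GP) or 1 (cribriform)")


@dataclass
class LogisticCribModel:
    """Logistic model ``P(crib) = expit(intercept + slope * x)``.

    ``x`` is the p90-ADC feature, optionally standardised as
    ``(p90 - standardize[0]) / standardize[1]`` before the linear term.
    The slope is per 1e-6 mm^2/s of the (possibly standardised) feature.
    """

    intercept: float
    slope: float
    standardize: tuple[float, float] | None = None
    feature_name: str = FEATURE_NAME

    def __post_init__(self) -> None:
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise ValueError("model coefficients must be finite")
        if self.standardize is not None:
            mean, sd = self.standardize
            if sd <= 0:
                raise ValueError("standardisation SD must be positive")
            self.standardize = (float(mean), float(sd))

    # -- prediction ------------------------------------------------------
    def _linear(self, p90):
        x = np.asarray(p90, dtype=float)
        if self.standardize is not None:
            mean, sd = self.standardize
            x = (x - mean) / sd
        return self.intercept + self.slope * x

    def predict(self, p90):
        """Probability of cribriform growth for one or many p90 values."""
        z = self._linear(p90)
        with np.errstate(over="ignore"):
            out = 1.0 / (1.0 + np.exp(-z))
        return float(out) if np.isscalar(p90) else out

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "feature": self.feature_name,
            "standardize": (
                None
                if self.standardize is None
                else {"mean": self.standardize[0], "sd": self.standardize[1]}
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticCribModel":
        std = d.get("standardize")
        return cls(
            intercept=float(d["intercept"]),
            slope=float(d["slope"]),
            standardize=None if std is None else (std["mean"], std["sd"]),
            feature_name=d.get("feature", FEATURE_NAME),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LogisticCribModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def predict_prob(model: LogisticCribModel, p90) -> float:
    """Functional form of :meth:`LogisticCribModel.predict`."""
    return model.predict(p90)


def default_model() -> LogisticCribModel:
    """Demonstration coefficients (synthetic; no published model exists).

    ``intercept=9, slope=-0.01`` on unstandardised ADC in 1e-6 mm^2/s puts
    the 0.5 crossing at 900, near the boundary between cribriform and
    non-cribriform tumour ADC in the synthetic phantoms.
    """
    return LogisticCribModel(intercept=9.0, slope=-0.01)


def _is_separated(x: np.ndarray, y: np.ndarray) -> bool:
    """True when a threshold on x classifies y perfectly (complete separation)."""
    lo1, hi1 = x[y == 1].min(), x[y == 1].max()
    lo0, hi0 = x[y == 0].min(), x[y == 0].max()
    return hi1 < lo0 or hi0 < lo1


def fit_crib_model(
    samples,
    regularization: float = 0.0,
    standardize: bool = False,
) -> LogisticCribModel:
    """Fit the single-feature logistic model on region samples.

    Maximises the binomial log-likelihood, optionally with an L2 penalty
    ``regularization / 2 * (b0^2 + b1^2)``, to a gradient norm of 1e-8.

    Parameters
    ----------
    samples
        Iterable of :class:`RegionSample` (or ``(p90, label)`` pairs).
    regularization
        L2 strength (>= 0).  Required to be positive when the two classes
        are completely separated in the feature.
    standardize
        If True, the feature is centred/scaled before fitting and the
        transform is stored on the returned model.
    """
    pairs = [
        (s.p90_adc, s.label) if isinstance(s, RegionSample) else (s[0], s[1])
        for s in samples
    ]
    x = np.array([p for p, _ in pairs], dtype=float)
    y = np.array([l for _, l in pairs], dtype=float)
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    if len(np.unique(y)) < 2:
        raise ValueError("both labels must be present to fit the model")
    if regularization == 0 and _is_separated(x, y):
        raise ValueError(
            "classes are completely separated in p90-ADC; the unpenalised "
            "MLE diverges — pass regularization > 0"
        )

    std = None
    xs = x
    if standardize:
        std = (float(x.mean()), float(x.std(ddof=0)) or 1.0)
        xs = (x - std[0]) / std[1]

    def nll_grad(beta):
        b0, b1 = beta
        z = b0 + b1 * xs
        # stable log(1 + exp(z))
        log1pexp = np.where(z > 30, z, np.log1p(np.exp(np.minimum(z, 30))))
        nll = float(np.sum(log1pexp - y * z)) + 0.5 * regularization * (b0**2 + b1**2)
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
        r = p - y
        grad = np.array([r.sum() + regularization * b0, (r * xs).sum() + regularization * b1])
        return nll, grad

    res = minimize(
        nll_grad,
        x0=np.zeros(2),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-9, "maxiter": 1000},
    )
    if np.linalg.norm(res.jac) > 1e-8:
        # BFGS can stall on badly scaled features; polish with Newton steps
        beta = res.x.copy()
        for _ in range(200):
            b0, b1 = beta
            z = b0 + b1 * xs
            p = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
            w = p * (1 - p)
            g = np.array(
                [
                    (p - y).sum() + regularization * b0,
                    ((p - y) * xs).sum() + regularization * b1,
                ]
            )
            if np.linalg.norm(g) <= 1e-8:
                break
            H = np.array(
                [
                    [w.sum() + regularization, (w * xs).sum()],
                    [(w * xs).sum(), (w * xs * xs).sum() + regularization],
                ]
            )
            beta = beta - np.linalg.solve(H, g)
        else:
            raise RuntimeError("logistic fit did not reach gradient norm 1e-8")
        res.x = beta
    return LogisticCribModel(intercept=float(res.x[0]), slope=float(res.x[1]), standardize=std)
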