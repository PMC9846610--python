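"""Calibration fits for the nondestructive pull test.

Three ordinary-least-squares fits make the pull tester usable without
destroying plants:

* the mean force-angle trajectory ``F(theta) = a*theta^2 + b*theta + c``
  pooled over all pre-break samples of a population;
* the inference line ``Fmax = a*F45 + b`` relating the 45-degree pull
  force of plants that survived 45 degrees to their eventual maximum;
* piecewise survival slopes (percent per degree) of the survival curve
  below and above the 45 degree critical angle.

Plain OLS is used throughout — no weights, no robust loss — matching
standard spreadsheet/statistics-package practice for this kind of
phenotyping data.  The published calibration of the 2023 field study
(1,172 plants, 113 varieties) ships as the named model ``"paper2023"``.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence, Tuple

import numpy as np
import yaml
from scipy import stats

from .features import DEFAULT_DROP_FRAC, SurvivalCurve, pre_break_samples
from .trace_io import PullTrace

__all__ = [
    "TrajectoryModel",
    "InferenceModel",
    "SurvivalSlopes",
    "fit_mean_trajectory",
    "fit_inference_line",
    "predict_fmax",
    "fit_survival_slopes",
    "PAPER2023_TRAJECTORY",
    "PAPER2023_INFERENCE",
    "get_model",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class TrajectoryModel:
    """Quadratic mean pull trajectory: force = a*theta^2 + b*theta + c."""

    a: float  # N / deg^2
    b: float  # N / deg
    c: float  # N
    r2: float
    n: int

    def predict(self, theta):
        theta = np.asarray(theta, dtype=float)
        return self.a * theta**2 + self.b * theta + self.c


@dataclass(frozen=True)
class InferenceModel:
    """Affine F45 -> Fmax inference line: Fmax = a*F45 + b."""

    a: float  # dimensionless slope
    b: float  # N intercept
    r2: float
    n: int


@dataclass(frozen=True)
class SurvivalSlopes:
    """Piecewise-linear survival slopes (%/degree) split at the knot."""

    slope_below: float
    slope_above: float
    knot: float = 45.0


# Published 2023 field calibration (n = 1,172 plants; inference on the
# 1,000 plants unbroken at 45 degrees).
PAPER2023_TRAJECTORY = TrajectoryModel(a=-0.0028, b=0.3989, c=2.4187, r2=0.9991, n=1172)
PAPER2023_INFERENCE = InferenceModel(a=1.1354, b=-0.3358, r2=0.9112, n=1000)


def _r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    sse = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - np.mean(y)) ** 2))
    if sst == 0.0:
        return 1.0 if sse == 0.0 else 0.0
    return 1.0 - sse / sst


def fit_mean_trajectory(
    traces: Iterable[PullTrace], drop_frac: float = DEFAULT_DROP_FRAC
) -> TrajectoryModel:
    """OLS quadratic of force on angle over all pooled pre-break samples.

    Every sample of every trace is weighted equally; post-break samples
    are excluded.  Requires at least three distinct pooled angles.
    """
    angle_parts, force_parts = [], []
    n_traces = 0
    for trace in traces:
        a, f = pre_break_samples(trace, drop_frac)
        angle_parts.append(a)
        force_parts.append(f)
        n_traces += 1
    if n_traces == 0:
        raise ValueError("fit_mean_trajectory requires at least one trace")
    x = np.concatenate(angle_parts)
    y = np.concatenate(force_parts)
    if np.unique(x).size < 3:
        raise ValueError(
            "fit_mean_trajectory needs >= 3 distinct angles, "
            f"got {np.unique(x).size}"
        )
    coeffs = np.polyfit(x, y, 2)
    fitted = np.polyval(coeffs, x)
    return TrajectoryModel(
        a=float(coeffs[0]),
        b=float(coeffs[1]),
        c=float(coeffs[2]),
        r2=_r_squared(y, fitted),
        n=n_traces,
    )


def fit_inference_line(pairs: Iterable[Tuple[float, float]]) -> InferenceModel:
    """OLS of Fmax on F45 with intercept.

    ``pairs`` are (F45, Fmax) for plants that survived the 45 degree
    tilt; plants broken earlier must be excluded upstream.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("fit_inference_line requires >= 2 (F45, Fmax) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0.0:
        raise ValueError("fit_inference_line: zero variance in F45")
    res = stats.linregress(x, y)
    fitted = res.slope * x + res.intercept
    return InferenceModel(
        a=float(res.slope),
        b=float(res.intercept),
        r2=_r_squared(y, fitted),
        n=arr.shape[0],
    )


def predict_fmax(model: InferenceModel, F45: float) -> float:
    """Expected Fmax of a plant from its nondestructive F45 reading.

    The raw affine value ``a*F45 + b`` is returned; a negative
    prediction (possible for very small F45) triggers a warning but is
    not clamped, so downstream consumers see the model as fitted.
    """
    if F45 < 0:
        raise ValueError(f"F45 must be >= 0, got {F45!r}")
    value = model.a * F45 + model.b
    if value < 0:
        warnings.warn(
            f"predicted Fmax is negative ({value:.4f} N) for F45={F45} N; "
            "reading is below the calibrated range",
            stacklevel=2,
        )
    return float(value)


def fit_survival_slopes(curve: SurvivalCurve, knot: float = 45.0) -> SurvivalSlopes:
    """Two OLS lines of survival %% on angle, split at the knot.

    The lower segment uses bins in ``[bin_step, knot]`` (the knot bin
    belongs below, since 45 degrees is the critical point at which the
    breaking regime changes); the upper segment uses bins strictly
    above the knot.  Slopes are in percent per degree.
    """
    angles, surv = curve.angles, curve.survival
    lower = (angles > 0) & (angles <= knot)
    upper = angles > knot
    if lower.sum() < 2 or upper.sum() < 2:
        raise ValueError("fit_survival_slopes needs >= 2 bins on each side of the knot")
    slope_below = float(np.polyfit(angles[lower], surv[lower], 1)[0])
    slope_above = float(np.polyfit(angles[upper], surv[upper], 1)[0])
    return SurvivalSlopes(slope_below=slope_below, slope_above=slope_above, knot=knot)


# --- named-model registry and flat key-value serialization ------------------

_BUILTIN_MODELS = {
    ("paper2023", "trajectory"): PAPER2023_TRAJECTORY,
    ("paper2023", "inference"): PAPER2023_INFERENCE,
}

_KIND_TO_CLS = {"trajectory": TrajectoryModel, "inference": InferenceModel}


def get_model(name: str, kind: str):
    """Look up a built-in named model, e.g. ``get_model("paper2023", "inference")``."""
    try:
        return _BUILTIN_MODELS[(name, kind)]
    except KeyError:
        raise KeyError(f"no built-in {kind!r} model named {name!r}") from None


def save_model(model, path: str | Path) -> Path:
    """Serialize a fitted model as a flat key-value YAML file."""
    kind = {TrajectoryModel: "trajectory", InferenceModel: "inference"}.get(type(model))
    if kind is None:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    payload = {"kind": kind, **asdict(model)}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def load_model(source: str | Path, kind: str | None = None):
    """Load a model by built-in name or from a key-value file.

    ``load_model("paper2023", kind="inference")`` resolves the shipped
    calibration; any other string/path is read as a YAML file written by
    :func:`save_model`.
    """
    if isinstance(source, str) and (source, kind) in _BUILTIN_MODELS:
        return _BUILTIN_MODELS[(source, kind)]
    data = yaml.safe_load(Path(source).read_text())
    file_kind = data.pop("kind")
    if kind is not None and kind != file_kind:
        raise ValueError(f"expected a {kind!r} model, file contains {file_kind!r}")
    return _KIND_TO_CLS[file_kind](**data)
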