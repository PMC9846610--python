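"""Per-plant pull-curve features and population survival statistics.

From each trace we extract the nondestructive proxy ``F45`` (pull force
at a 45 degree tilt, linearly interpolated), the destructive reference
``Fmax`` (largest force sustained before the stalk broke, or up to 90
degrees for unbroken plants) and the breaking angle.  Breakage is
detected as a relative force drop from the running maximum, since the
instrument records straight through the snap.

Population-level summaries follow the field convention of 5 degree
angle bins: the survival curve (percentage of plants still unbroken at
each tilt angle), its complement the cumulative breaking proportion,
and the mean ``F_theta / Fmax`` ratio curve.  A plant breaking exactly
at a bin angle counts as broken at that angle (bins are ``(a-step, a]``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .trace_io import PullTrace

__all__ = [
    "PlantFeatures",
    "SurvivalCurve",
    "detect_break",
    "force_at_angle",
    "extract_features",
    "survival_curve",
    "cumulative_break_proportion",
    "ratio_curve",
    "features_to_frame",
]

DEFAULT_DROP_FRAC = 0.30


@dataclass(frozen=True)
class PlantFeatures:
    """Extracted features of one plant's pull test.

    ``F45`` is absent (None) when the stalk broke at or before 45
    degrees, or when the trace never reached 45 degrees.
    """

    plant_id: str
    Fmax: float
    F45: Optional[float] = None
    break_angle: Optional[float] = None
    survived_45: bool = True
    survived_90: bool = True
    metadata: dict[str, Any] | None = None


@dataclass(frozen=True)
class SurvivalCurve:
    """Percentage of plants unbroken at each bin angle (starts at 100)."""

    angles: np.ndarray          # degrees
    survival: np.ndarray        # %
    cumulative_break: np.ndarray  # %, = 100 - survival
    n: int


def _break_index(trace: PullTrace, drop_frac: float) -> Optional[int]:
    if not (0.0 < drop_frac <= 1.0):
        raise ValueError(f"drop_frac must lie in (0, 1], got {drop_frac!r}")
    f = trace.force_N
    running_max = np.maximum.accumulate(f)
    dropped = f < (1.0 - drop_frac) * running_max
    if not dropped.any():
        return None
    return int(np.argmax(dropped))


def detect_break(trace: PullTrace, drop_frac: float = DEFAULT_DROP_FRAC) -> Optional[float]:
    """Breaking angle of a trace, or None if the plant never broke.

    The break is located at the first sample whose force falls below
    ``(1 - drop_frac)`` of the running maximum force.
    """
    idx = _break_index(trace, drop_frac)
    return None if idx is None else float(trace.angle_deg[idx])


def pre_break_samples(
    trace: PullTrace, drop_frac: float = DEFAULT_DROP_FRAC
) -> tuple[np.ndarray, np.ndarray]:
    """(angles, forces) of the regular samples before the force-drop region."""
    idx = _break_index(trace, drop_frac)
    if idx is None:
        return trace.angle_deg, trace.force_N
    return trace.angle_deg[:idx], trace.force_N[:idx]


def force_at_angle(
    trace: PullTrace, theta: float, drop_frac: float = DEFAULT_DROP_FRAC
) -> float:
    """Pull force at tilt ``theta`` (degrees), linearly interpolated.

    Only the pre-break part of the trace is used; ``theta`` outside the
    achieved pre-break angle range is an error.
    """
    angles, forces = pre_break_samples(trace, drop_frac)
    if len(angles) == 0 or theta < angles[0] or theta > angles[-1]:
        lo = angles[0] if len(angles) else float("nan")
        hi = angles[-1] if len(angles) else float("nan")
        raise ValueError(
            f"trace {trace.plant_id!r}: angle {theta} outside the pre-break "
            f"range [{lo}, {hi}]"
        )
    return float(np.interp(theta, angles, forces))


def extract_features(
    trace: PullTrace, drop_frac: float = DEFAULT_DROP_FRAC
) -> PlantFeatures:
    """Extract ``F45``, ``Fmax``, break angle and survival flags."""
    idx = _break_index(trace, drop_frac)
    angles, forces = pre_break_samples(trace, drop_frac)
    if len(forces) == 0:
        raise ValueError(f"trace {trace.plant_id!r}: no pre-break samples")
    fmax = float(np.max(forces))
    break_angle = None if idx is None else float(trace.angle_deg[idx])
    # tie convention: breaking exactly at 45 counts as broken at 45
    survived_45 = break_angle is None or break_angle > 45.0
    survived_90 = break_angle is None
    f45 = None
    if survived_45 and angles[0] <= 45.0 <= angles[-1]:
        f45 = force_at_angle(trace, 45.0, drop_frac)
    return PlantFeatures(
        plant_id=trace.plant_id,
        Fmax=fmax,
        F45=f45,
        break_angle=break_angle,
        survived_45=survived_45,
        survived_90=survived_90,
        metadata=dict(trace.metadata),
    )


def survival_curve(
    features: Sequence[PlantFeatures], bin_step: float = 5.0
) -> SurvivalCurve:
    """Population survival percentage versus tilt angle.

    ``survival(theta) = 100 * #(break_angle > theta or unbroken) / n``
    evaluated at ``0, bin_step, 2*bin_step, ..., 90``.
    """
    features = list(features)
    if not features:
        raise ValueError("survival_curve requires a nonempty feature collection")
    if bin_step <= 0:
        raise ValueError("bin_step must be positive")
    angles = np.arange(0.0, 90.0 + 0.5 * bin_step, bin_step)
    breaks = np.array(
        [np.inf if f.break_angle is None else f.break_angle for f in features]
    )
    n = len(breaks)
    survival = np.array([100.0 * np.count_nonzero(breaks > a) / n for a in angles])
    return SurvivalCurve(
        angles=angles, survival=survival, cumulative_break=100.0 - survival, n=n
    )


def cumulative_break_proportion(
    features: Sequence[PlantFeatures], upto: float
) -> float:
    """Percentage of plants broken at angles <= ``upto`` (same tie rule)."""
    features = list(features)
    if not features:
        raise ValueError("cumulative_break_proportion requires a nonempty collection")
    broken = sum(
        1 for f in features if f.break_angle is not None and f.break_angle <= upto
    )
    return 100.0 * broken / len(features)


def ratio_curve(
    traces: Iterable[PullTrace],
    bin_step: float = 5.0,
    drop_frac: float = DEFAULT_DROP_FRAC,
) -> pd.Series:
    """Mean ``F_theta / Fmax`` per bin angle over plants unbroken there.

    Plants with nonpositive ``Fmax`` are excluded with a warning.  Bins
    where no plant is still unbroken are NaN.
    """
    angles = np.arange(0.0, 90.0 + 0.5 * bin_step, bin_step)
    sums = np.zeros_like(angles)
    counts = np.zeros_like(angles)
    for trace in traces:
        feats = extract_features(trace, drop_frac)
        if feats.Fmax <= 0:
            warnings.warn(
                f"trace {trace.plant_id!r}: Fmax <= 0, excluded from ratio curve",
                stacklevel=2,
            )
            continue
        pre_angles, _ = pre_break_samples(trace, drop_frac)
        break_angle = np.inf if feats.break_angle is None else feats.break_angle
        for i, a in enumerate(angles):
            if a < break_angle and pre_angles[0] <= a <= pre_angles[-1]:
                sums[i] += force_at_angle(trace, a, drop_frac) / feats.Fmax
                counts[i] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.Series(means, index=pd.Index(angles, name="angle_deg"), name="mean_ratio")


def features_to_frame(features: Sequence[PlantFeatures]) -> pd.DataFrame:
    """Tabulate features (one row per plant) for CSV export."""
    rows = []
    for f in features:
        row = {
            "plant_id": f.plant_id,
            "F45_N": f.F45,
            "Fmax_N": f.Fmax,
            "break_angle_deg": f.break_angle,
            "survived_45": f.survived_45,
            "survived_90": f.survived_90,
        }
        row.update(f.metadata or {})
        rows.append(row)
    return pd.DataFrame(rows)
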