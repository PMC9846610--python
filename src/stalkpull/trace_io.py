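"""Reading, validating and writing instrument pull-trace exports.

A field pull tester records, for every plant, an ordered series of
(tilt angle, pull force, displacement) samples.  The canonical on-disk
form is a single tidy CSV with one row per sample::

    plant_id,angle_deg,force_N,displacement_cm[,<metadata columns...>]

The instrument itself exports XLS workbooks with the same three value
columns; those are accepted read-only through the ``xls`` dialect.
Metadata columns (variety, planting density, growth stage, ...) are
constant within a plant and carried through as opaque key-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PullTrace",
    "TraceIssue",
    "TraceValidationError",
    "read_traces",
    "write_traces",
    "validate_trace",
]

CANONICAL_COLUMNS = ("plant_id", "angle_deg", "force_N", "displacement_cm")

# header aliases accepted on input, lower-cased
_ANGLE_ALIASES = {"angle", "angle_deg", "angle_degree", "tilt_angle"}
_FORCE_ALIASES = {"force", "force_n", "tension", "pull_force"}
_DISP_ALIASES = {"displacement", "displacement_cm", "height", "distance"}


@dataclass(frozen=True)
class TraceIssue:
    """One validation finding; ``code`` is machine-readable."""

    code: str
    message: str


class TraceValidationError(ValueError):
    """Raised when a file or trace violates the pull-trace contract."""

    def __init__(self, message: str, issues: Sequence[TraceIssue] = ()):
        super().__init__(message)
        self.issues = list(issues)


@dataclass
class PullTrace:
    """One plant's ordered (angle, force, displacement) samples.

    The constructor only coerces shapes; use :func:`validate_trace` for
    the full contract (sample count, angle monotonicity, ranges, single
    terminal break region).
    """

    plant_id: str
    angle_deg: np.ndarray
    force_N: np.ndarray
    displacement_cm: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        self.force_N = np.asarray(self.force_N, dtype=float)
        self.displacement_cm = np.asarray(self.displacement_cm, dtype=float)
        n = len(self.angle_deg)
        if len(self.force_N) != n or len(self.displacement_cm) != n:
            raise TraceValidationError(
                f"trace {self.plant_id!r}: angle/force/displacement lengths differ"
            )

    def __len__(self) -> int:
        return len(self.angle_deg)


def validate_trace(trace: PullTrace, drop_frac: float = 0.30) -> list[TraceIssue]:
    """Check a trace against the pull-trace contract; never raises.

    Returns an empty list iff the trace is valid.  ``drop_frac`` is the
    relative force drop (from the running maximum) treated as evidence
    of stalk breakage when locating post-break samples.
    """
    issues: list[TraceIssue] = []
    pid = trace.plant_id
    a, f, d = trace.angle_deg, trace.force_N, trace.displacement_cm

    if len(a) < 2:
        issues.append(TraceIssue("too_few_samples", f"{pid}: {len(a)} sample(s), need >= 2"))
    for name, arr in (("angle", a), ("force", f), ("displacement", d)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            issues.append(
                TraceIssue("nonfinite", f"{pid}: non-finite {name} at sample(s) {bad.tolist()}")
            )
            return issues  # further checks meaningless
    out = np.flatnonzero((a < 0) | (a > 90))
    if out.size:
        issues.append(
            TraceIssue("angle_out_of_range", f"{pid}: angle outside [0, 90] at {out.tolist()}")
        )
    if np.any(np.diff(a) < 0):
        idx = int(np.flatnonzero(np.diff(a) < 0)[0]) + 1
        issues.append(
            TraceIssue("angles_not_sorted", f"{pid}: angles decrease at sample {idx}")
        )
    neg = np.flatnonzero(f < 0)
    if neg.size:
        issues.append(TraceIssue("negative_force", f"{pid}: negative force at {neg.tolist()}"))
    neg = np.flatnonzero(d < 0)
    if neg.size:
        issues.append(
            TraceIssue("negative_displacement", f"{pid}: negative displacement at {neg.tolist()}")
        )

    if len(f) >= 2 and not issues:
        running_max = np.maximum.accumulate(f)
        dropped = f < (1.0 - drop_frac) * running_max
        if dropped.any():
            first = int(np.argmax(dropped))
            tail = dropped[first:]
            if not tail.all():
                issues.append(
                    TraceIssue(
                        "break_region_not_terminal",
                        f"{pid}: force recovers after the drop at sample {first}; "
                        "a trace may contain at most one terminal force-drop region",
                    )
                )
    return issues


def _raise_if_invalid(traces: Iterable[PullTrace]) -> None:
    issues: list[TraceIssue] = []
    for t in traces:
        issues.extend(validate_trace(t))
    if issues:
        detail = "; ".join(i.message for i in issues[:5])
        raise TraceValidationError(
            f"{len(issues)} trace validation issue(s): {detail}", issues
        )


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    lower = {str(c).strip().lower(): c for c in columns}
    mapping: dict[str, str] = {}
    for target, aliases in (
        ("angle_deg", _ANGLE_ALIASES),
        ("force_N", _FORCE_ALIASES),
        ("displacement_cm", _DISP_ALIASES),
    ):
        hit = [lower[a] for a in aliases if a in lower]
        if not hit:
            raise TraceValidationError(
                f"missing required column for {target!r}; accepted headers: {sorted(aliases)}"
            )
        mapping[target] = hit[0]
    if "plant_id" in lower:
        mapping["plant_id"] = lower["plant_id"]
    return mapping


def _frame_to_traces(df: pd.DataFrame, source: str) -> list[PullTrace]:
    mapping = _resolve_columns(df.columns)
    df = df.rename(columns={v: k for k, v in mapping.items()})
    if "plant_id" not in df.columns:
        df["plant_id"] = "P1"
    df["plant_id"] = df["plant_id"].astype(str)

    for col in ("angle_deg", "force_N", "displacement_cm"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            row = int(bad[0])
            raise TraceValidationError(
                f"{source}: non-numeric value {df.loc[row, col]!r} "
                f"in column {col!r} at row {row}"
            )
        df[col] = coerced
    if df[["angle_deg", "force_N", "displacement_cm"]].isna().any().any():
        raise TraceValidationError(f"{source}: empty numeric cells present")

    meta_cols = [c for c in df.columns if c not in CANONICAL_COLUMNS]
    traces = []
    for pid, sub in df.groupby("plant_id", sort=True):
        metadata = {c: sub[c].iloc[0] for c in meta_cols}
        traces.append(
            PullTrace(
                plant_id=str(pid),
                angle_deg=sub["angle_deg"].to_numpy(),
                force_N=sub["force_N"].to_numpy(),
                displacement_cm=sub["displacement_cm"].to_numpy(),
                metadata=metadata,
            )
        )
    return traces


def read_traces(path: str | Path, dialect: str = "csv") -> list[PullTrace]:
    """Read pull traces from ``path``.

    ``dialect`` is ``"csv"`` (canonical) or ``"xls"`` (instrument
    export; also reads .xlsx).  Headers are matched case-insensitively.
    Every row is either returned inside a trace or named in the raised
    error — rows are never dropped silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        # round_trip parsing keeps write -> read -> write byte-identical
        df = pd.read_csv(path, float_precision="round_trip")
    elif dialect == "xls":
        df = pd.read_excel(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'xls'")
    if df.empty:
        raise TraceValidationError(f"{path}: file contains no data rows")
    traces = _frame_to_traces(df, str(path))
    _raise_if_invalid(traces)
    return traces


def traces_to_frame(traces: Iterable[PullTrace]) -> pd.DataFrame:
    """Tidy long-format DataFrame (canonical columns, then sorted metadata)."""
    parts = []
    meta_keys: set[str] = set()
    for t in traces:
        meta_keys.update(t.metadata)
    meta_cols = sorted(meta_keys)
    for t in sorted(traces, key=lambda t: t.plant_id):
        part = pd.DataFrame(
            {
                "plant_id": t.plant_id,
                "angle_deg": t.angle_deg,
                "force_N": t.force_N,
                "displacement_cm": t.displacement_cm,
            }
        )
        for c in meta_cols:
            part[c] = t.metadata.get(c)
        parts.append(part)
    if not parts:
        return pd.DataFrame(columns=list(CANONICAL_COLUMNS) + meta_cols)
    return pd.concat(parts, ignore_index=True)


def write_traces(traces: Iterable[PullTrace], path: str | Path) -> Path:
    """Write traces to canonical CSV (deterministic row order).

    Traces are validated first; an empty collection yields a header-only
    file.
    """
    traces = list(traces)
    _raise_if_invalid(traces)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    traces_to_frame(traces).to_csv(path, index=False)
    return path
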