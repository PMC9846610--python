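"""Four-level lodging-resistance classification from Fmax.

The resistance scale is derived empirically: the population's Fmax
values are clustered into four groups by agglomerative hierarchical
clustering (squared-Euclidean distance, Ward linkage — the standard
SPSS pairing).  Because the feature is one-dimensional, each cluster is
a contiguous force interval, so the three boundaries between adjacent
clusters define the class scheme

    poor (-inf, b1] < low (b1, b2] < moderate (b2, b3] < high (b3, inf)

with boundary values belonging to the lower (weaker) level.  The 2023
field calibration (boundaries 11.8 / 17.5 / 25.8 N) ships as the named
scheme ``"paper2023"``.

Populations can be classified from measured Fmax or, nondestructively,
from Fmax inferred out of F45; per-level agreement between the two
labelings and grade proportions per variety/density/stage group are the
standard reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .calibration import InferenceModel, predict_fmax
from .features import PlantFeatures

__all__ = [
    "LEVELS",
    "ClassScheme",
    "ClusterSummary",
    "PAPER2023_SCHEME",
    "cluster_fmax",
    "scheme_from_clusters",
    "classify_fmax",
    "classify_population",
    "accuracy_table",
    "grade_proportions",
]

LEVELS = ("poor", "low", "moderate", "high")


@dataclass(frozen=True)
class ClassScheme:
    """Three ordered force boundaries splitting Fmax into four levels."""

    boundaries: tuple[float, float, float]
    labels: tuple[str, str, str, str] = LEVELS

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) != 3 or not (b[0] < b[1] < b[2]):
            raise ValueError(f"boundaries must be 3 strictly increasing values, got {b!r}")
        if len(self.labels) != 4:
            raise ValueError("exactly 4 level labels required")


PAPER2023_SCHEME = ClassScheme(boundaries=(11.8, 17.5, 25.8))


@dataclass(frozen=True)
class ClusterSummary:
    """Per-cluster Fmax statistics, ordered by ascending cluster mean."""

    means: np.ndarray
    mins: np.ndarray
    maxs: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_N": self.means,
                "min_N": self.mins,
                "max_N": self.maxs,
                "count": self.counts,
            },
            index=pd.RangeIndex(1, len(self.means) + 1, name="cluster"),
        )


def _optimal_1d_labels(x: np.ndarray, k: int) -> np.ndarray:
    """Exact minimum within-cluster-SSE contiguous partition of 1-D data.

    Dynamic programming over the sorted values with prefix-sum segment
    costs; O(k n^2) time, O(n) extra memory per stage.
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    c1 = np.concatenate(([0.0], np.cumsum(xs)))
    c2 = np.concatenate(([0.0], np.cumsum(xs * xs)))

    def seg_cost(j: np.ndarray, i: int) -> np.ndarray:
        # SSE of xs[j:i] for a vector of starts j
        m = i - j
        s = c1[i] - c1[j]
        return (c2[i] - c2[j]) - s * s / m

    m = np.arange(1, n + 1)
    cost = np.concatenate(([0.0], c2[1:] - c1[1:] ** 2 / m))  # SSE of xs[0:i]
    cuts = np.zeros((k + 1, n + 1), dtype=int)
    for kk in range(2, k + 1):
        new = np.full(n + 1, np.inf)
        for i in range(kk, n + 1):
            j = np.arange(kk - 1, i)
            total = cost[j] + seg_cost(j, i)
            best = int(np.argmin(total))
            new[i] = total[best]
            cuts[kk, i] = j[best]
        cost = new
    # backtrack boundaries
    bounds = [n]
    for kk in range(k, 1, -1):
        bounds.append(cuts[kk, bounds[-1]])
    bounds.append(0)
    bounds = bounds[::-1]
    labels_sorted = np.empty(n, dtype=int)
    for i, (a, b) in enumerate(zip(bounds, bounds[1:])):
        labels_sorted[a:b] = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def cluster_fmax(
    values: Sequence[float], k: int = 4, method: str = "exact"
) -> tuple[np.ndarray, ClusterSummary]:
    """Cluster 1-D Fmax values into ``k`` groups.

    The default solves the squared-Euclidean (Ward) within-cluster
    sum-of-squares criterion exactly: in one dimension the optimal
    clusters are contiguous value intervals, found by dynamic
    programming (greedy agglomerative merging can miss the optimum).
    Agglomerative ``ward``, ``complete`` and ``average`` linkages are
    offered as alternatives.  Returns integer labels (0-based, ordered
    so label i has the i-th smallest cluster mean) and the per-cluster
    summary.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < k:
        raise ValueError(f"need >= k={k} one-dimensional values, got shape {x.shape}")
    if not np.all(np.isfinite(x)) or np.any(x < 0):
        raise ValueError("Fmax values must be finite and nonnegative")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate input: all Fmax values identical")
    if method == "exact":
        labels = _optimal_1d_labels(x, k)
        if np.unique(labels).size != k:
            raise ValueError(f"could not form {k} distinct clusters (ties in the data)")
    elif method in ("ward", "complete", "average"):
        Z = linkage(x[:, None], method=method)
        raw = fcluster(Z, t=k, criterion="maxclust")
        if np.unique(raw).size != k:
            raise ValueError(f"could not form {k} distinct clusters (ties in the data)")
        # reorder labels by ascending cluster mean
        order = np.argsort([x[raw == c].mean() for c in np.unique(raw)])
        remap = {int(np.unique(raw)[orig]): rank for rank, orig in enumerate(order)}
        labels = np.array([remap[int(c)] for c in raw])
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    means = np.array([x[labels == i].mean() for i in range(k)])
    mins = np.array([x[labels == i].min() for i in range(k)])
    maxs = np.array([x[labels == i].max() for i in range(k)])
    counts = np.array([np.count_nonzero(labels == i) for i in range(k)])
    return labels, ClusterSummary(means=means, mins=mins, maxs=maxs, counts=counts)


def scheme_from_clusters(summary: ClusterSummary) -> ClassScheme:
    """Class boundaries = maxima of the three weakest clusters.

    Requires exactly four clusters with non-overlapping value ranges.
    """
    if len(summary.means) != 4:
        raise ValueError("scheme_from_clusters requires exactly 4 clusters")
    for i in range(3):
        if summary.maxs[i] >= summary.mins[i + 1]:
            raise ValueError(
                f"cluster value ranges overlap between clusters {i + 1} and {i + 2}"
            )
    return ClassScheme(boundaries=tuple(float(m) for m in summary.maxs[:3]))


def classify_fmax(scheme: ClassScheme, value: float) -> str:
    """Map one Fmax value to its resistance level (boundaries inclusive below)."""
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"Fmax must be finite and >= 0, got {value!r}")
    b1, b2, b3 = scheme.boundaries
    if value <= b1:
        return scheme.labels[0]
    if value <= b2:
        return scheme.labels[1]
    if value <= b3:
        return scheme.labels[2]
    return scheme.labels[3]


def classify_population(
    features: Sequence[PlantFeatures],
    scheme: ClassScheme,
    model: Optional[InferenceModel] = None,
    mode: str = "measured",
) -> pd.Series:
    """Per-plant resistance levels from measured or inferred Fmax.

    ``measured`` classifies the recorded Fmax.  ``inferred`` classifies
    ``predict_fmax(model, F45)``; plants without an F45 reading (broken
    at or before 45 degrees) are unclassifiable and get ``None``.
    Negative predictions fall into the weakest level.
    """
    if mode not in ("measured", "inferred"):
        raise ValueError(f"mode must be 'measured' or 'inferred', got {mode!r}")
    if mode == "inferred" and model is None:
        raise ValueError("inferred mode requires an InferenceModel")
    levels: list[Optional[str]] = []
    ids = []
    for f in features:
        ids.append(f.plant_id)
        if mode == "measured":
            levels.append(classify_fmax(scheme, f.Fmax))
        elif f.F45 is None:
            levels.append(None)
        else:
            pred = predict_fmax(model, f.F45)
            levels.append(classify_fmax(scheme, max(pred, 0.0)))
    return pd.Series(levels, index=pd.Index(ids, name="plant_id"), name=mode)


def accuracy_table(
    measured_levels: pd.Series, inferred_levels: pd.Series, labels: Sequence[str] = LEVELS
) -> pd.DataFrame:
    """Per-level agreement between measured and inferred classifications.

    For each level the table reports the marginal counts of both
    labelings, the number of plants assigned that level by both, and
    ``accuracy = 100 * agreement / measured count``.  Plants lacking
    either label (e.g. unclassifiable in inferred mode) are dropped
    before comparison.
    """
    common = measured_levels.index.intersection(inferred_levels.index)
    if len(common) == 0:
        raise ValueError("measured and inferred labelings share no plants")
    m = measured_levels.loc[common]
    p = inferred_levels.loc[common]
    keep = m.notna() & p.notna()
    m, p = m[keep], p[keep]
    rows = []
    for level in labels:
        measured_n = int((m == level).sum())
        inferred_n = int((p == level).sum())
        agree = int(((m == level) & (p == level)).sum())
        accuracy = 100.0 * agree / measured_n if measured_n else float("nan")
        rows.append(
            {
                "measured_count": measured_n,
                "inferred_count": inferred_n,
                "agreement": agree,
                "accuracy_pct": accuracy,
            }
        )
    return pd.DataFrame(rows, index=pd.Index(labels, name="level"))


def grade_proportions(
    levels: pd.Series,
    groups: pd.DataFrame,
    labels: Sequence[str] = LEVELS,
) -> pd.DataFrame:
    """Percentage of each resistance level within metadata groups.

    ``groups`` holds one row per plant (indexed like ``levels``) with
    the grouping keys, e.g. variety / planting density / growth stage.
    Returns a long table (group keys, level, percent); percentages sum
    to 100 within each group.
    """
    if groups.empty or len(levels) == 0:
        raise ValueError("grade_proportions requires nonempty levels and groups")
    df = groups.loc[levels.index].copy()
    df["level"] = levels
    df = df[df["level"].notna()]
    keys = list(groups.columns)
    rows = []
    for group_vals, sub in df.groupby(keys, sort=True):
        if not isinstance(group_vals, tuple):
            group_vals = (group_vals,)
        total = len(sub)
        for level in labels:
            rows.append(
                dict(zip(keys, group_vals))
                | {"level": level, "percent": 100.0 * (sub["level"] == level).sum() / total}
            )
    return pd.DataFrame(rows)
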