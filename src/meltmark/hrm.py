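"""HRM post-processing: normalization, difference curves, clustering, calls.

The commercial melt-analysis software behind HRM genotyping documents two
knobs — a curve-shape sensitivity percentage and a Tm difference threshold —
but not its algorithm.  This module is an explicit, deterministic
reconstruction of those two knobs:

* stage 1: single-linkage grouping on estimated Tm; samples whose Tm gap is
  at least ``tm_diff_threshold`` end up in different clusters;
* stage 2: within each Tm group, average-linkage hierarchical clustering on
  the root-mean-square distance between normalized curves, cut at
  ``d_cut = (1 − shape_sensitivity/100) · d_scale`` where ``d_scale`` is the
  largest pairwise RMS distance in the dataset.

Per-sample confidence is a Gaussian-kernel softmax over clusters of the RMS
distance to each cluster's mean curve, scaled by the pooled within-cluster
RMS deviation — reported in percent, summing to 100 across clusters.

No randomness anywhere; ties break on sorted sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .thermo import DEFAULT_GRID, MeltCurve

__all__ = ["HRMConfig", "NormalizedCurve", "ClusterResult", "SpeciesCall",
           "normalize_curve", "difference_curves", "cluster_curves",
           "assign_unknown", "UNASSIGNED"]

UNASSIGNED = "unassigned — possible new variant"

_SIGMA_FLOOR = 1e-3


@dataclass
class HRMConfig:
    """Analysis settings for one HRM assay.

    ``pre_melt_window`` and ``post_melt_window`` are the °C ranges used to
    fit the 100% and 0% fluorescence baselines; they must not overlap and
    pre must precede post.  ``shape_sensitivity`` (percent) and
    ``tm_diff_threshold`` (°C) are the two clustering knobs;
    ``confidence_floor`` (percent) is the minimum confidence for a species
    call.  ``shift_curves`` enables optional temperature superimposition
    before shape comparison (off by default).
    """

    pre_melt_window: tuple[float, float] = (65.0, 67.0)
    post_melt_window: tuple[float, float] = (93.0, 95.0)
    shape_sensitivity: float = 75.0
    tm_diff_threshold: float = 0.2
    confidence_floor: float = 95.0
    grid: tuple[float, float, float] = DEFAULT_GRID
    shift_curves: bool = False

    def __post_init__(self) -> None:
        pre, post = self.pre_melt_window, self.post_melt_window
        if not (pre[0] < pre[1] <= post[0] < post[1]):
            raise ValueError("windows must satisfy pre_start < pre_end <= post_start < post_end")
        if not (0 <= self.shape_sensitivity <= 100):
            raise ValueError("shape_sensitivity must be in [0, 100]")
        if self.tm_diff_threshold < 0:
            raise ValueError("tm_diff_threshold must be >= 0")
        if self.grid[2] <= 0:
            raise ValueError("grid step must be positive")


@dataclass
class NormalizedCurve:
    """A melt curve rescaled to ~100% (pre-melt) .. ~0% (post-melt).

    ``tm_est`` is the temperature of the 50% crossing (linear
    interpolation), or None when the curve never crosses 50%
    (``no_crossing`` is then set).
    """

    sample_id: str
    temperatures: np.ndarray
    values: np.ndarray
    tm_est: float | None
    group_label: str | None = None
    no_crossing: bool = False


@dataclass
class ClusterResult:
    """Cluster memberships with per-sample confidence percentages."""

    labels: dict[str, int]                      # sample -> cluster id
    confidence: dict[str, float]                # sample -> % in own cluster
    confidence_matrix: dict[str, np.ndarray]    # sample -> % over all clusters
    cluster_tm: dict[int, float | None]         # cluster -> mean Tm estimate
    cluster_labels: dict[int, str | None]       # cluster -> inherited group label
    reference_cluster: int | None = None
    shape_only_samples: tuple[str, ...] = ()    # curves clustered without a Tm

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_tm)

    def summary(self):
        import pandas as pd

        rows = [
            {
                "sample_id": s,
                "cluster": c,
                "cluster_label": self.cluster_labels.get(c),
                "confidence_pct": self.confidence[s],
                "cluster_tm": self.cluster_tm.get(c),
            }
            for s, c in sorted(self.labels.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class SpeciesCall:
    """A per-sample identification with its evidence."""

    sample_id: str
    method: str                   # hrm | rflp | multiplex | combined
    call: str                     # group/species label, UNASSIGNED or "no product"
    confidence: float             # percent (hrm) or match score (rflp/multiplex)
    evidence: dict = field(default_factory=dict)
    mislabel_flag: bool = False


# ---------------------------------------------------------------------------
# Normalization

def _window_mask(temps: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (temps >= lo - 1e-9) & (temps <= hi + 1e-9)


def _fit_line(temps: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(temps, values, 1)
    return float(slope), float(intercept)


def _estimate_tm(temps: np.ndarray, values: np.ndarray) -> float | None:
    """Temperature of the 50% crossing; among multiple descending crossings
    the one at the steepest local descent wins (deterministic)."""
    v = values - 50.0
    crossings = []
    for i in range(len(v) - 1):
        if v[i] >= 0 >= v[i + 1] and (v[i] > 0 or v[i + 1] < 0):
            slope = v[i + 1] - v[i]
            if slope == 0:
                t = temps[i]
            else:
                t = temps[i] + (0 - v[i]) / slope * (temps[i + 1] - temps[i])
            crossings.append((slope, float(t)))
    if not crossings:
        return None
    steepest = min(crossings, key=lambda c: c[0])  # most negative slope
    return steepest[1]


def normalize_curve(curve: MeltCurve, config: HRMConfig) -> NormalizedCurve:
    """Baseline-normalize one melt curve between the pre/post-melt windows.

    Straight baselines are least-squares fits to the raw fluorescence inside
    each window; the normalized value is
    ``100·(F(T) − lower(T)) / (upper(T) − lower(T))`` over the grid
    restricted to [pre-window start, post-window end].
    """
    temps = curve.temperatures
    pre_mask = _window_mask(temps, config.pre_melt_window)
    post_mask = _window_mask(temps, config.post_melt_window)
    if pre_mask.sum() < 2 or post_mask.sum() < 2:
        raise ValueError("each normalization window needs at least two grid points")

    upper = _fit_line(temps[pre_mask], curve.fluorescence[pre_mask])
    lower = _fit_line(temps[post_mask], curve.fluorescence[post_mask])

    keep = (temps >= config.pre_melt_window[0] - 1e-9) & (temps <= config.post_melt_window[1] + 1e-9)
    t = temps[keep]
    up = upper[0] * t + upper[1]
    low = lower[0] * t + lower[1]
    span = up - low
    if np.any(span <= 0):
        raise ValueError("degenerate baselines: upper(T) <= lower(T) inside the analyzed range")
    values = 100.0 * (curve.fluorescence[keep] - low) / span
    tm = _estimate_tm(t, values)
    return NormalizedCurve(
        sample_id=curve.sample_id,
        temperatures=t,
        values=values,
        tm_est=tm,
        group_label=curve.group_label,
        no_crossing=tm is None,
    )


def difference_curves(
    curves: list[NormalizedCurve], reference_id: str
) -> dict[str, np.ndarray]:
    """Per-sample difference vectors against one reference curve."""
    ref = next((c for c in curves if c.sample_id == reference_id), None)
    if ref is None:
        raise KeyError(f"reference sample {reference_id!r} not among curves")
    _check_common_grid(curves)
    return {c.sample_id: c.values - ref.values for c in curves}


# ---------------------------------------------------------------------------
# Clustering

def _check_common_grid(curves: list[NormalizedCurve]) -> None:
    t0 = curves[0].temperatures
    for c in curves[1:]:
        if len(c.temperatures) != len(t0) or np.max(np.abs(c.temperatures - t0)) > 1e-9:
            raise ValueError("curves must share one temperature grid")


def _rms_matrix(values: np.ndarray) -> np.ndarray:
    m = values.shape[1]
    return squareform(pdist(values) / np.sqrt(m))


def _stage1_groups(order: list[int], tms: list[float | None], threshold: float) -> list[list[int]]:
    """Single-linkage 1-D grouping on Tm; no-Tm curves form one shape-only group."""
    with_tm = [i for i in order if tms[i] is not None]
    without = [i for i in order if tms[i] is None]
    groups: list[list[int]] = []
    if with_tm:
        ranked = sorted(with_tm, key=lambda i: (tms[i], i))
        current = [ranked[0]]
        for prev, nxt in zip(ranked, ranked[1:]):
            if tms[nxt] - tms[prev] >= threshold:
                groups.append(current)
                current = [nxt]
            else:
                current.append(nxt)
        groups.append(current)
    if without:
        groups.append(without)
    return groups


def cluster_curves(
    curves: list[NormalizedCurve],
    config: HRMConfig,
    reference_labels: dict[str, str] | None = None,
    reference_group: str | None = None,
) -> ClusterResult:
    """Two-stage (Tm, then shape) clustering of normalized melt curves.

    When ``reference_labels`` maps sample ids to group names, each cluster
    inherits the majority label of its labeled members.  Cluster ids are
    assigned 0..K−1 in order of increasing mean Tm (shape-only clusters
    last), ties broken by smallest sample id, so memberships are invariant
    to input order.
    """
    if len(curves) < 2:
        raise ValueError("clustering needs at least two curves")
    curves = sorted(curves, key=lambda c: c.sample_id)
    _check_common_grid(curves)

    ids = [c.sample_id for c in curves]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    values = np.vstack([c.values for c in curves])
    if config.shift_curves:
        # superimpose on the 5% crossing before shape comparison
        values = _shift_to_common_crossing(values)
    tms = [c.tm_est for c in curves]

    dist = _rms_matrix(values)
    d_scale = float(dist.max())
    d_cut = (1.0 - config.shape_sensitivity / 100.0) * d_scale

    clusters: list[list[int]] = []
    for group in _stage1_groups(list(range(len(curves))), tms, config.tm_diff_threshold):
        if len(group) == 1 or d_scale == 0.0:
            clusters.append(group)
            continue
        sub = dist[np.ix_(group, group)]
        link = linkage(squareform(sub, checks=False), method="average")
        assignment = fcluster(link, t=d_cut, criterion="distance")
        for k in sorted(set(assignment)):
            clusters.append([group[j] for j in range(len(group)) if assignment[j] == k])

    # deterministic cluster ordering: by mean Tm (shape-only last), then id
    def _order_key(members: list[int]):
        mtms = [tms[i] for i in members if tms[i] is not None]
        mean_tm = float(np.mean(mtms)) if mtms else float("inf")
        return (mean_tm, min(ids[i] for i in members))

    clusters.sort(key=_order_key)

    labels = {}
    for cid, members in enumerate(clusters):
        for i in members:
            labels[ids[i]] = cid

    means = np.vstack([values[members].mean(axis=0) for members in clusters])
    m = values.shape[1]
    d_ic = np.sqrt(((values[:, None, :] - means[None, :, :]) ** 2).mean(axis=2))
    own = np.array([d_ic[i, labels[ids[i]]] for i in range(len(curves))])
    sigma = max(float(np.sqrt(np.mean(own ** 2))), _SIGMA_FLOOR)

    log_w = -(d_ic ** 2) / (2.0 * sigma ** 2)
    log_w -= log_w.max(axis=1, keepdims=True)
    w = np.exp(log_w)
    conf = 100.0 * w / w.sum(axis=1, keepdims=True)

    confidence_matrix = {ids[i]: conf[i] for i in range(len(curves))}
    confidence = {ids[i]: float(conf[i, labels[ids[i]]]) for i in range(len(curves))}

    cluster_tm = {}
    cluster_label: dict[int, str | None] = {}
    for cid, members in enumerate(clusters):
        mtms = [tms[i] for i in members if tms[i] is not None]
        cluster_tm[cid] = float(np.mean(mtms)) if mtms else None
        if reference_labels:
            votes = [reference_labels[ids[i]] for i in members if ids[i] in reference_labels]
            cluster_label[cid] = (
                max(sorted(set(votes)), key=votes.count) if votes else None
            )
        else:
            cluster_label[cid] = None

    reference_cluster = None
    if reference_group is not None:
        for cid, lab in cluster_label.items():
            if lab == reference_group:
                reference_cluster = cid
                break

    return ClusterResult(
        labels=labels,
        confidence=confidence,
        confidence_matrix=confidence_matrix,
        cluster_tm=cluster_tm,
        cluster_labels=cluster_label,
        reference_cluster=reference_cluster,
        shape_only_samples=tuple(ids[i] for i in range(len(curves)) if tms[i] is None),
    )


def _shift_to_common_crossing(values: np.ndarray, level: float = 5.0) -> np.ndarray:
    """Shift each curve along the index axis so its ``level``% crossings align.

    Integer-index shifting with edge padding; used only when
    ``HRMConfig.shift_curves`` is enabled.
    """
    n, m = values.shape
    idx = []
    for row in values:
        below = np.nonzero(row <= level)[0]
        idx.append(int(below[0]) if len(below) else m - 1)
    target = int(round(float(np.median(idx))))
    out = np.empty_like(values)
    for r, (row, i) in enumerate(zip(values, idx)):
        shift = target - i
        out[r] = np.roll(row, shift)
        if shift > 0:
            out[r, :shift] = row[0]
        elif shift < 0:
            out[r, shift:] = row[-1]
    return out


def assign_unknown(
    unknown: NormalizedCurve,
    reference_curves: list[NormalizedCurve],
    reference: ClusterResult,
    config: HRMConfig,
) -> SpeciesCall:
    """Assign one unknown curve against a labeled reference clustering.

    The unknown is re-clustered together with the reference curves.  If it
    lands in a cluster containing labeled reference samples and its
    confidence reaches ``config.confidence_floor``, that label is returned;
    otherwise the call is ``UNASSIGNED`` with the nearest labeled cluster
    and the unknown's confidence for it as evidence.
    """
    if reference.n_clusters < 2:
        raise ValueError("reference clustering must have at least two clusters")
    if any(c.sample_id == unknown.sample_id for c in reference_curves):
        raise ValueError(f"unknown id {unknown.sample_id!r} collides with a reference sample")
    _check_common_grid([*reference_curves, unknown])

    sample_to_label = {
        s: reference.cluster_labels[c]
        for s, c in reference.labels.items()
        if reference.cluster_labels.get(c) is not None
    }
    joint = cluster_curves([*reference_curves, unknown], config,
                           reference_labels=sample_to_label)
    cid = joint.labels[unknown.sample_id]
    conf = joint.confidence[unknown.sample_id]
    label = joint.cluster_labels.get(cid)

    evidence = {
        "cluster": cid,
        "cluster_tm": joint.cluster_tm.get(cid),
        "tm_est": unknown.tm_est,
        "n_clusters": joint.n_clusters,
    }
    if label is not None and conf >= config.confidence_floor:
        return SpeciesCall(sample_id=unknown.sample_id, method="hrm", call=label,
                           confidence=conf, evidence=evidence)

    # nearest labeled cluster (deterministic: highest confidence, lowest id)
    conf_vec = joint.confidence_matrix[unknown.sample_id]
    labeled = [c for c, lab in joint.cluster_labels.items() if lab is not None]
    nearest = max(labeled, key=lambda c: (conf_vec[c], -c)) if labeled else None
    evidence["nearest_cluster"] = nearest
    evidence["nearest_label"] = joint.cluster_labels.get(nearest) if nearest is not None else None
    evidence["nearest_confidence"] = float(conf_vec[nearest]) if nearest is not None else None
    return SpeciesCall(sample_id=unknown.sample_id, method="hrm", call=UNASSIGNED,
                       confidence=conf, evidence=evidence)
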