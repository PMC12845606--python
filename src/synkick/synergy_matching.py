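"""Reference synergies, Pearson matching, and activation-timing features.

Subject-level synergy weight vectors (normalized W columns) are pooled per
group x session cell and clustered with Euclidean k-means; the cluster
count s is chosen by the SSE-trend rule (the smallest s whose relative SSE
drop to s+1 falls below a tolerance).  Each subject's synergies are then
matched to the cell's reference centroids by Pearson correlation (r > 0.6
is similar), uniquely and greedily in descending r; the matched temporal
coefficient rows inherit the assignment, and timing features (activation
duration T, peak moment Tmax, onset Tstart) are read off each matched H
row on the real-cycle-fraction axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .synergy import SynergySet

__all__ = [
    "ReferenceSynergySet",
    "MatchedSynergy",
    "ActivationTimingFeatures",
    "pool_weights",
    "kmeans_cluster",
    "select_cluster_count",
    "build_reference",
    "match_to_reference",
    "activation_features",
    "align_references",
]


@dataclass
class ReferenceSynergySet:
    """Group-level reference synergies for one group x session cell."""

    centroids: np.ndarray  # s x m, rows renormalized to max 1
    s: int
    sse_curve: dict[int, float]
    muscle_labels: list[str]
    group: str | None = None
    session: str | None = None
    assignments: list[dict] = field(default_factory=list)
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if np.any(self.centroids < 0):
            raise ValueError("centroids must be non-negative")
        if self.centroids.shape[0] != self.s or self.s < 1:
            raise ValueError("centroid count must equal s >= 1")
        if not self.names:
            self.names = [f"SYN{i + 1}" for i in range(self.s)]


@dataclass(frozen=True)
class MatchedSynergy:
    """One subject synergy assigned to a reference centroid."""

    subject: str
    column: int  # column index in the subject's W
    cluster: int  # row index in the reference centroids
    r: float


@dataclass(frozen=True)
class ActivationTimingFeatures:
    """Timing of one matched activation coefficient, as cycle fractions.

    ``T`` is the total measure of the active set (where h >= active_frac of
    its peak), ``t_start`` its first point, ``t_max`` the location of the
    global maximum (first index on ties).
    """

    T: float
    t_max: float
    t_start: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_start <= self.t_max <= 1.0):
            raise ValueError("need 0 <= Tstart <= Tmax <= 1")
        if not 0.0 <= self.T <= 1.0:
            raise ValueError("activation duration must lie in [0, 1]")


def pool_weights(
    sets: list[SynergySet],
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Stack every normalized W column of every subject as one row.

    Returns the rows (n_synergies_total x m) and their provenance as
    (subject, column-index) pairs.
    """
    if not sets:
        raise ValueError("no synergy sets to pool")
    labels = sets[0].muscle_labels
    rows, provenance = [], []
    for sset in sets:
        if sset.muscle_labels != labels:
            raise ValueError(
                f"inconsistent muscle labels for subject "
                f"{sset.meta.get('subject', '?')}"
            )
        if not sset.normalized:
            raise ValueError("pool_weights requires normalized synergy sets")
        for j in range(sset.k):
            rows.append(sset.W[:, j])
            provenance.append((str(sset.meta.get("subject", "?")), j))
    return np.vstack(rows), provenance


def kmeans_cluster(
    rows: np.ndarray, s: int, seed: int = 0, restarts: int = 50
) -> tuple[np.ndarray, np.ndarray, float]:
    """Euclidean k-means, careful (k-means++) seeding, best of ``restarts``.

    Returns (centroids, labels, sse).  Deterministic given the seed.
    """
    rows = np.asarray(rows, dtype=float)
    if s > rows.shape[0]:
        raise ValueError(f"s={s} exceeds the {rows.shape[0]} pooled synergies")
    km = KMeans(n_clusters=s, n_init=restarts, random_state=seed).fit(rows)
    return km.cluster_centers_, km.labels_, float(km.inertia_)


def select_cluster_count(
    rows: np.ndarray,
    s_min: int = 1,
    s_max: int = 8,
    drop_tol: float = 0.10,
    seed: int = 0,
    restarts: int = 50,
) -> tuple[int, dict[int, float]]:
    """SSE-trend (elbow) choice of the cluster count.

    Picks the smallest s whose relative SSE decrease going to s+1 is below
    ``drop_tol`` -- i.e. adding a cluster no longer buys much.  Ties go to
    the smaller s; if no s qualifies, the largest candidate is returned.
    Also returns the SSE curve (computed over s_min..s_max+1).
    """
    rows = np.asarray(rows, dtype=float)
    s_max = min(s_max, rows.shape[0] - 1 if rows.shape[0] > 1 else 1)
    if s_min > s_max:
        raise ValueError("empty s range")
    curve: dict[int, float] = {}
    for s in range(s_min, min(s_max + 1, rows.shape[0]) + 1):
        _, _, sse = kmeans_cluster(rows, s, seed=seed, restarts=restarts)
        curve[s] = sse
    for s in range(s_min, s_max + 1):
        if s + 1 not in curve:
            break
        prev = curve[s]
        if prev <= 0:  # perfect fit already: no decline possible
            return s, curve
        if (prev - curve[s + 1]) / prev < drop_tol:
            return s, curve
    return s_max, curve


def build_reference(
    sets: list[SynergySet],
    s: int | None = None,
    s_min: int = 1,
    s_max: int = 8,
    drop_tol: float = 0.10,
    seed: int = 0,
    restarts: int = 50,
    group: str | None = None,
    session: str | None = None,
) -> ReferenceSynergySet:
    """Pool a cell's synergy weights, choose s, cluster, and order centroids.

    Centroid rows are renormalized to max 1 and ordered by the mean peak
    time of their member synergies' activation rows (earliest first), so
    SYN1 is the earliest-acting reference pattern.
    """
    rows, provenance = pool_weights(sets)
    curve: dict[int, float]
    if s is None:
        s, curve = select_cluster_count(
            rows, s_min, s_max, drop_tol, seed=seed, restarts=restarts
        )
    else:
        curve = {}
    centroids, labels, sse = kmeans_cluster(rows, s, seed=seed, restarts=restarts)
    curve.setdefault(s, sse)

    # order clusters by mean peak fraction of member H rows (when known)
    by_subject = {str(x.meta.get("subject", "?")): x for x in sets}
    peak_fracs = [[] for _ in range(s)]
    for (subj, col), lab in zip(provenance, labels):
        sset = by_subject.get(subj)
        if sset is not None and sset.cycle_fraction_map is not None:
            h = sset.H[col]
            peak_fracs[lab].append(sset.cycle_fraction_map[int(np.argmax(h))])
    means = [np.mean(p) if p else np.inf for p in peak_fracs]
    order = np.argsort(means, kind="stable")
    relabel = {int(old): new for new, old in enumerate(order)}
    centroids = centroids[order]

    colmax = centroids.max(axis=1, keepdims=True)
    colmax[colmax <= 0] = 1.0
    centroids = centroids / colmax

    assignments = [
        {"subject": subj, "column": col, "cluster": relabel[int(lab)]}
        for (subj, col), lab in zip(provenance, labels)
    ]
    return ReferenceSynergySet(
        centroids=centroids,
        s=s,
        sse_curve=curve,
        muscle_labels=list(sets[0].muscle_labels),
        group=group,
        session=session,
        assignments=assignments,
    )


def _pearson_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson r between every row of A and every row of B."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    na[na == 0] = np.inf  # constant vector correlates with nothing
    nb[nb == 0] = np.inf
    return (A @ B.T) / np.outer(na, nb)


def match_to_reference(
    sset: SynergySet,
    ref: ReferenceSynergySet,
    r_threshold: float = 0.6,
    method: str = "greedy",
) -> list[MatchedSynergy]:
    """Assign subject synergies to reference centroids by Pearson r.

    ``greedy`` (default) takes pairs in descending r, each synergy and each
    centroid at most once, skipping pairs with r <= threshold; unmatched
    synergies are a valid outcome.  ``hungarian`` solves the global optimal
    assignment instead (threshold still applied afterwards), for
    sensitivity analysis.
    """
    if sset.muscle_labels != ref.muscle_labels:
        raise ValueError("subject and reference muscle labels differ")
    if not sset.normalized:
        raise ValueError("match_to_reference requires normalized weights")
    R = _pearson_matrix(sset.W.T, ref.centroids)  # k x s
    subject = str(sset.meta.get("subject", "?"))
    matches: list[MatchedSynergy] = []
    if method == "hungarian":
        cols, clus = linear_sum_assignment(-R)
        for c, z in zip(cols, clus):
            if R[c, z] > r_threshold:
                matches.append(MatchedSynergy(subject, int(c), int(z), float(R[c, z])))
        return sorted(matches, key=lambda m: m.cluster)
    if method != "greedy":
        raise ValueError(f"unknown matching method {method!r}")
    pairs = sorted(
        ((R[c, z], c, z) for c in range(R.shape[0]) for z in range(R.shape[1])),
        key=lambda t: (-t[0], t[2], t[1]),
    )
    used_cols: set[int] = set()
    used_clusters: set[int] = set()
    for r, c, z in pairs:
        if r <= r_threshold:
            break
        if c in used_cols or z in used_clusters:
            continue
        used_cols.add(c)
        used_clusters.add(z)
        matches.append(MatchedSynergy(subject, int(c), int(z), float(r)))
    return sorted(matches, key=lambda m: m.cluster)


def activation_features(
    h: np.ndarray,
    fractions: np.ndarray,
    active_frac: float = 0.2,
) -> ActivationTimingFeatures:
    """Timing features of one activation coefficient row.

    The active set is where ``h >= active_frac * max(h)``; its total
    measure on the cycle-fraction axis is the activation duration T,
    its first point the onset Tstart, and the global maximum (first index
    on ties) the peak moment Tmax.
    """
    h = np.asarray(h, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if h.shape != fractions.shape:
        raise ValueError("h and fractions must have the same length")
    peak = h.max()
    if peak <= 0:
        raise ValueError("all-zero activation row has no timing features")
    active = h >= active_frac * peak

    # each column covers half the gap to each neighbour on the fraction axis
    edges = np.empty(fractions.size + 1)
    edges[1:-1] = 0.5 * (fractions[1:] + fractions[:-1])
    edges[0] = fractions[0]
    edges[-1] = fractions[-1]
    widths = np.diff(edges)
    T = float(np.clip(widths[active].sum(), 0.0, 1.0))

    t_start = float(fractions[np.flatnonzero(active)[0]])
    t_max = float(fractions[int(np.argmax(h))])
    return ActivationTimingFeatures(T=T, t_max=t_max, t_start=t_start)


def align_references(
    refs: dict[tuple[str, str], ReferenceSynergySet],
    anchor: tuple[str, str] = ("control", "pre"),
) -> dict[tuple[str, str], ReferenceSynergySet]:
    """Relabel each cell's centroids to the anchor cell's SYN identities.

    Reference synergies are built per group x session cell, so SYN ids are
    cell-local; to compare a synergy measure across the 2x2 design the
    other cells' centroids are permuted to best Pearson-match the anchor
    cell (the control-group pre-intervention references).
    """
    if anchor not in refs:
        raise KeyError(f"anchor cell {anchor} missing from references")
    anchor_ref = refs[anchor]
    out = {anchor: anchor_ref}
    for cell, ref in refs.items():
        if cell == anchor:
            continue
        R = _pearson_matrix(ref.centroids, anchor_ref.centroids)
        rows, cols = linear_sum_assignment(-R)
        pos = {int(c): int(r) for r, c in zip(rows, cols)}
        new_rows = []
        taken = set()
        for target in range(ref.s):
            if target in pos:
                new_rows.append(pos[target])
                taken.add(pos[target])
        for z in range(ref.s):
            if z not in taken:
                new_rows.append(z)
        order = np.array(new_rows, dtype=int)
        remap = {int(old): new for new, old in enumerate(order)}
        out[cell] = ReferenceSynergySet(
            centroids=ref.centroids[order],
            s=ref.s,
            sse_curve=dict(ref.sse_curve),
            muscle_labels=list(ref.muscle_labels),
            group=ref.group,
            session=ref.session,
            assignments=[
                {**a, "cluster": remap[int(a["cluster"])]} for a in ref.assignments
            ],
        )
    return out
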