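"""Muscle-synergy extraction by non-negative matrix factorization.

The activation matrix ``V`` (muscles x time points) is decomposed as
``V ~ W H`` with ``W`` (muscles x k) the spatial synergy weights and ``H``
(k x time) the temporal activation coefficients, via classical
multiplicative updates for the squared Frobenius loss (Lee-Seung).  Because
NMF is non-unique and sensitive to initialization, every factorization is
the best of a configurable number of random restarts, and the full
reproducibility record (seed, restarts, iterations, VAF curve over k) is
kept on the result.

Model order k is the smallest value whose variance accounted for,
``VAF = 1 - SSE/SST``, first exceeds the threshold (default 0.9).  After
selection, each W column is rescaled to max 1 (with the inverse scale
absorbed into H, leaving the product unchanged) and muscles with
normalized weight >= 0.3 are flagged as major contributors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import EnvelopeMatrix

__all__ = [
    "SynergySet",
    "nmf",
    "vaf",
    "select_order",
    "normalize_weights",
    "major_contributors",
]

_EPS = 1e-12


@dataclass
class SynergySet:
    """One subject's factorization with its reproducibility record."""

    W: np.ndarray  # m x k
    H: np.ndarray  # k x n
    k: int
    vaf: float
    sse: float
    muscle_labels: list[str]
    cycle_fraction_map: np.ndarray | None = None
    vaf_curve: dict[int, float] = field(default_factory=dict)
    restarts_used: int = 0
    iterations: int = 0
    seed: int = 0
    threshold_met: bool = True
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if np.any(self.W < 0) or np.any(self.H < 0):
            raise ValueError("W and H must be elementwise non-negative")
        if self.k < 1 or self.W.shape[1] != self.k or self.H.shape[0] != self.k:
            raise ValueError("inconsistent model order k")

    @property
    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H


def _mu_run(
    V: np.ndarray,
    k: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    track_sse: bool = False,
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    """One multiplicative-update run from a random initialization.

    Init is uniform in (0, 1] scaled to V's mean; updates are the standard
    Frobenius-loss pair, which keep factors non-negative and never increase
    the loss.  Convergence: relative SSE decrease below ``tol``.
    """
    m, n = V.shape
    scale = np.sqrt(max(V.mean(), _EPS) / k)
    W = scale * (1.0 - rng.random((m, k)))  # in (0, scale]
    H = scale * (1.0 - rng.random((k, n)))
    sse_prev = np.inf
    history: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        # H <- H * (W^T V) / (W^T W H)
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        # W <- W * (V H^T) / (W H H^T)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        resid = V - W @ H
        sse = float(np.einsum("ij,ij->", resid, resid))
        if track_sse:
            history.append(sse)
        if sse_prev - sse < tol * max(sse_prev, _EPS):
            sse_prev = sse
            break
        sse_prev = sse
    return W, H, sse_prev, it, history


def nmf(
    V: np.ndarray,
    k: int,
    seed: int = 0,
    restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
    track_sse: bool = False,
) -> tuple[np.ndarray, np.ndarray, float, dict]:
    """Best-of-restarts multiplicative-update NMF.

    Returns ``(W, H, sse, info)`` where ``info`` records iterations of the
    winning run, restarts used, the seed, and (if ``track_sse``) the
    per-iteration SSE trace of the winning run.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be 2-D")
    if np.any(V < 0):
        raise ValueError("V must be elementwise non-negative")
    m, n = V.shape
    if not 1 <= k <= min(m, n):
        raise ValueError(f"k={k} out of range 1..min(m, n)={min(m, n)}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")

    ss = np.random.SeedSequence((seed, k))
    best = None
    for child in ss.spawn(restarts):
        rng = np.random.default_rng(child)
        W, H, sse, it, hist = _mu_run(V, k, rng, tol, max_iter, track_sse)
        if best is None or sse < best[2]:
            best = (W, H, sse, it, hist)
    W, H, sse, it, hist = best
    info = {"iterations": it, "restarts": restarts, "seed": seed}
    if track_sse:
        info["sse_history"] = hist
    return W, H, sse, info


def vaf(
    V: np.ndarray, W: np.ndarray, H: np.ndarray, centered: bool = True
) -> float:
    """Variance accounted for: ``1 - SSE/SST``.

    SST is the total variance of V about its grand mean by default; the
    uncentered variant (sum of squares of V itself) is available because
    the field is split on the convention.
    """
    V = np.asarray(V, dtype=float)
    resid = V - np.asarray(W) @ np.asarray(H)
    sse = float(np.sum(resid**2))
    if centered:
        sst = float(np.sum((V - V.mean()) ** 2))
    else:
        sst = float(np.sum(V**2))
    if sst <= 0:
        raise ValueError("SST is zero: V is constant, VAF undefined")
    return 1.0 - sse / sst


def select_order(
    V_in: EnvelopeMatrix | np.ndarray,
    k_min: int = 1,
    k_max: int = 8,
    vaf_threshold: float = 0.9,
    seed: int = 0,
    restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
    centered_sst: bool = True,
    muscle_labels: list[str] | None = None,
) -> SynergySet:
    """Sweep k upward and keep the first factorization whose VAF strictly
    exceeds the threshold.

    If no k in range qualifies, the largest k is returned with
    ``threshold_met=False``.  Restarts share a seed structure across k so
    the sweep is reproducible end to end.
    """
    if isinstance(V_in, EnvelopeMatrix):
        V = V_in.values
        labels = list(V_in.muscle_labels)
        frac_map = V_in.cycle_fraction_map
    else:
        V = np.asarray(V_in, dtype=float)
        labels = muscle_labels or [f"ch{i}" for i in range(V.shape[0])]
        frac_map = None
    k_max = min(k_max, *V.shape)
    if k_min > k_max:
        raise ValueError("empty k range")

    curve: dict[int, float] = {}
    chosen = None
    for k in range(k_min, k_max + 1):
        W, H, sse, info = nmf(V, k, seed=seed, restarts=restarts, tol=tol,
                              max_iter=max_iter)
        v = vaf(V, W, H, centered=centered_sst)
        curve[k] = v
        if v > vaf_threshold:
            chosen = (k, W, H, sse, v, info, True)
            break
    if chosen is None:
        chosen = (k, W, H, sse, v, info, False)  # last k swept

    k, W, H, sse, v, info, met = chosen
    W, H = _order_columns(W, H)
    out = SynergySet(
        W=W,
        H=H,
        k=k,
        vaf=v,
        sse=sse,
        muscle_labels=labels,
        cycle_fraction_map=frac_map,
        vaf_curve=curve,
        restarts_used=info["restarts"],
        iterations=info["iterations"],
        seed=seed,
        threshold_met=met,
    )
    return out


def _order_columns(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stable display order: columns sorted by the peak time of their H row
    (earliest first).  Semantic identity is established by matching, not by
    this ordering."""
    peaks = np.argmax(H, axis=1)
    order = np.argsort(peaks, kind="stable")
    return W[:, order], H[order, :]


def normalize_weights(sset: SynergySet, drop_zero: bool = True) -> SynergySet:
    """Rescale each W column to max 1, absorbing the scale into H.

    The product ``W H`` is unchanged.  All-zero synergy columns are dropped
    with a note in ``meta`` (or raise if ``drop_zero`` is false).
    """
    W, H = sset.W.copy(), sset.H.copy()
    colmax = W.max(axis=0)
    dead = np.flatnonzero(colmax <= 0)
    if dead.size:
        if not drop_zero:
            raise ValueError(f"all-zero synergy column(s) {dead.tolist()}")
        keep = colmax > 0
        W, H, colmax = W[:, keep], H[keep, :], colmax[keep]
    W = W / colmax
    H = H * colmax[:, None]
    out = SynergySet(
        W=W,
        H=H,
        k=W.shape[1],
        vaf=sset.vaf,
        sse=sset.sse,
        muscle_labels=list(sset.muscle_labels),
        cycle_fraction_map=sset.cycle_fraction_map,
        vaf_curve=dict(sset.vaf_curve),
        restarts_used=sset.restarts_used,
        iterations=sset.iterations,
        seed=sset.seed,
        threshold_met=sset.threshold_met,
        normalized=True,
        meta=dict(sset.meta),
    )
    if dead.size:
        out.meta["dropped_zero_columns"] = dead.tolist()
    return out


def major_contributors(
    sset: SynergySet, threshold: float = 0.3
) -> list[list[str]]:
    """Per synergy, the muscles whose normalized weight is >= threshold.

    Requires normalized weights; because each column peaks at 1, every
    synergy lists at least one contributor.
    """
    if not sset.normalized:
        raise ValueError("major_contributors requires normalized weights")
    out = []
    for j in range(sset.k):
        out.append(
            [
                sset.muscle_labels[i]
                for i in range(len(sset.muscle_labels))
                if sset.W[i, j] >= threshold
            ]
        )
    return out
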