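"""Marker ordering within linkage groups: scaffold, framework, bin-mapping.

Candidate orders are scored with a multipoint hidden-Markov likelihood under
the F2 intercross model.  The hidden state at each marker is the ordered pair
of strand alleles (four states); transitions factorize into two independent
crossover chains with per-interval recombination fraction r, so the
Baum-Welch M-step for r is closed form (expected strand switches over twice
the sample size).  Observed genotypes are emitted with a symmetric error rate
ε; missing calls emit uniformly.  The likelihood is identical to the usual
three-genotype-state formulation and is invariant to reversing the order.

Ordering follows a serial heuristic:

1. *scaffold* — from each of several randomly chosen seed markers, grow a
   sparse skeleton by repeatedly attaching the marker with the highest
   two-point LOD to either end, subject to an estimated distance of at least
   ``min_spacing_cM`` from every scaffold member; the replicate with the best
   mean per-marker multipoint log-likelihood is kept and replicate order
   concordance is reported.
2. *framework* — remaining markers are inserted one at a time at their
   maximum-likelihood interval; an insertion is kept only when the log10
   likelihood ratio of the best versus second-best placement exceeds
   ``order_lod`` (default 3.0), otherwise the marker is deferred.
3. *bin-mapping* — each deferred marker is placed at the position of the
   framework marker with the smallest two-point recombination estimate
   (ties: highest LOD, then lexicographic id); markers with no linkage to the
   framework are reported unplaced.

A window-3 permutation polish (accept when the likelihood improves) runs
after scaffold selection and after framework construction.  All recombination
fractions here are on the F2-assumed scale; the f3model module converts final
interval distances to the true F3 scale as a post-processing step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from . import f3model
from .io import GenotypeMatrix
from .linkage import PairwiseLinkage

__all__ = [
    "OrderedGroup",
    "multipoint_loglik",
    "fit_chain",
    "build_scaffold",
    "build_framework",
    "bin_map",
    "order_group",
]

_LN10 = np.log(10.0)
_STATE_GENO = np.array([0, 1, 1, 2])  # genotype carried by each strand-pair state
_SWITCHES = np.array(
    [[0, 1, 1, 2], [1, 0, 2, 1], [1, 2, 0, 1], [2, 1, 1, 0]], dtype=float
)
_EMIT_FLOOR = 1e-12
_R_CAP = 0.4999


def _emissions(calls: np.ndarray, epsilon: float) -> np.ndarray:
    """Emission probabilities, shape (n_markers, n_individuals, 4)."""
    m, n = calls.shape
    out = np.empty((m, n, 4))
    for s, g in enumerate(_STATE_GENO):
        out[:, :, s] = np.where(
            calls < 0, 1.0, np.where(calls == g, 1.0 - epsilon, epsilon / 2.0)
        )
    return np.maximum(out, _EMIT_FLOOR)


def _transition(r: float) -> np.ndarray:
    s = np.array([[1.0 - r, r], [r, 1.0 - r]])
    return np.kron(s, s)


def _forward(E: np.ndarray, A: list[np.ndarray]):
    m, n, _ = E.shape
    alpha = np.empty((m, n, 4))
    c = np.empty((m, n))
    a = 0.25 * E[0]
    c[0] = a.sum(axis=1)
    alpha[0] = a / c[0][:, None]
    for k in range(1, m):
        a = (alpha[k - 1] @ A[k - 1]) * E[k]
        c[k] = a.sum(axis=1)
        alpha[k] = a / c[k][:, None]
    return alpha, c


def _backward(E: np.ndarray, A: list[np.ndarray], c: np.ndarray) -> np.ndarray:
    m, n, _ = E.shape
    beta = np.empty((m, n, 4))
    beta[m - 1] = 1.0
    for k in range(m - 2, -1, -1):
        beta[k] = ((E[k + 1] * beta[k + 1]) @ A[k].T) / c[k + 1][:, None]
    return beta


def fit_chain(
    calls: np.ndarray,
    epsilon: float,
    r_init: np.ndarray | None = None,
    tol: float = 1e-4,
    max_iter: int = 40,
) -> tuple[float, np.ndarray]:
    """Baum-Welch fit of per-interval recombination fractions for one order.

    ``calls`` is the (n_markers, n_individuals) genotype slice in candidate
    order.  Returns (log-likelihood at the fitted r, fitted r vector).
    """
    m, n = calls.shape
    if m < 2:
        E = _emissions(calls, epsilon)
        return float(np.log(0.25 * E[0].sum(axis=1)).sum()), np.empty(0)
    E = _emissions(calls, epsilon)
    r = np.full(m - 1, 0.2) if r_init is None else np.clip(r_init, 1e-6, _R_CAP)
    r = r.astype(float).copy()
    for _ in range(max_iter):
        A = [_transition(rk) for rk in r]
        alpha, c = _forward(E, A)
        beta = _backward(E, A, c)
        r_new = np.empty_like(r)
        for k in range(m - 1):
            w = E[k + 1] * beta[k + 1] / c[k + 1][:, None]
            xi = (alpha[k].T @ w) * A[k]
            r_new[k] = (xi * _SWITCHES).sum() / (2.0 * n)
        np.clip(r_new, 1e-6, _R_CAP, out=r_new)
        done = np.max(np.abs(r_new - r)) < tol
        r = r_new
        if done:
            break
    A = [_transition(rk) for rk in r]
    _, c = _forward(E, A)
    return float(np.log(c).sum()), r


def multipoint_loglik(
    order: list[str], gm: GenotypeMatrix, epsilon: float = 0.01, **fit_kwargs
) -> tuple[float, np.ndarray]:
    """Multipoint log-likelihood of a marker order, with interval r re-estimated.

    Groups of fewer than two markers get the trivial single-marker likelihood.
    """
    idx = gm.marker_index()
    calls = gm.calls[[idx[m] for m in order]]
    return fit_chain(calls, epsilon, **fit_kwargs)


def _pair_r_init(order_idx: list[int], pairs: PairwiseLinkage) -> np.ndarray:
    r = pairs.r_hat[order_idx[:-1], order_idx[1:]]
    return np.clip(np.nan_to_num(r, nan=0.3), 1e-6, _R_CAP)


def build_scaffold(
    members: list[str],
    pairs: PairwiseLinkage,
    seed_marker: str,
    min_spacing_cM: float = 10.0,
) -> list[str]:
    """Greedy well-spaced skeleton grown from one seed marker.

    Repeatedly attaches, to whichever scaffold end it is most strongly linked
    (highest two-point LOD), the marker whose estimated Haldane distance is at
    least ``min_spacing_cM`` from every current scaffold member.  Groups too
    small or too tight to spread return whatever could be placed (at minimum
    the seed).
    """
    if seed_marker not in members:
        raise ValueError("seed marker not in group")
    idx = pairs.index_of()
    mem_idx = np.array([idx[m] for m in members])
    pos_of = {m: i for i, m in enumerate(members)}
    r_local = pairs.r_hat[np.ix_(mem_idx, mem_idx)]
    lod_local = pairs.lod[np.ix_(mem_idx, mem_idx)]
    with np.errstate(invalid="ignore"):
        dist = np.where(
            np.isnan(r_local), np.inf, -50.0 * np.log1p(-2.0 * np.minimum(r_local, _R_CAP))
        )

    scaffold = [pos_of[seed_marker]]
    available = set(range(len(members))) - set(scaffold)
    while True:
        cand = [
            j for j in available if all(dist[j, s] >= min_spacing_cM for s in scaffold)
        ]
        if not cand:
            break
        ends = (scaffold[0], scaffold[-1])
        best = max(cand, key=lambda j: (max(lod_local[j, ends[0]], lod_local[j, ends[1]]), members[j]))
        if lod_local[best, ends[0]] >= lod_local[best, ends[1]]:
            scaffold.insert(0, best)
        else:
            scaffold.append(best)
        available.discard(best)
    return [members[j] for j in scaffold]


def _insertion_scores(
    order_idx: list[int],
    E: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    c: np.ndarray,
    cand_emit: np.ndarray,
    r_left: np.ndarray,
    r_right: np.ndarray,
) -> np.ndarray:
    """Log-likelihood of inserting one marker into each of the m+1 intervals.

    ``r_left[k]``/``r_right[k]`` give the recombination fraction to the marker
    left/right of interval ``k`` (k = 0 is before the first marker, k = m
    after the last).  Uses the fitted chain's forward/backward quantities, so
    each interval costs O(n_individuals) small-matrix work.
    """
    m = E.shape[0]
    logc = np.log(c)
    base = logc.sum(axis=0)  # (n,)
    scores = np.empty(m + 1)
    # before the first marker
    right = (E[0] * beta[0]) @ _transition(r_right[0]).T
    val = 0.25 * (cand_emit * right).sum(axis=1)
    scores[0] = float((base - logc[0] + np.log(np.maximum(val, 1e-300))).sum())
    # interior intervals
    for k in range(1, m):
        a1 = alpha[k - 1] @ _transition(r_left[k])
        right = (E[k] * beta[k]) @ _transition(r_right[k]).T
        val = (a1 * cand_emit * right).sum(axis=1)
        scores[k] = float((base - logc[k] + np.log(np.maximum(val, 1e-300))).sum())
    # after the last marker
    a1 = alpha[m - 1] @ _transition(r_left[m])
    val = (a1 * cand_emit).sum(axis=1)
    scores[m] = float((base + np.log(np.maximum(val, 1e-300))).sum())
    return scores


def _polish(
    order_idx: list[int],
    calls_full: np.ndarray,
    pairs: PairwiseLinkage,
    epsilon: float,
    max_passes: int = 1,
) -> tuple[list[int], float, np.ndarray]:
    """Window-3 permutation hill-climb; accepts a permutation if it improves."""
    order_idx = list(order_idx)

    def score(o):
        return fit_chain(
            calls_full[o], epsilon, r_init=_pair_r_init(o, pairs), tol=1e-3, max_iter=12
        )

    best_ll, best_r = score(order_idx)
    for _ in range(max_passes):
        improved = False
        for i in range(len(order_idx) - 2):
            window = order_idx[i : i + 3]
            for perm in permutations(window):
                if list(perm) == window:
                    continue
                trial = order_idx[:i] + list(perm) + order_idx[i + 3 :]
                ll, r = score(trial)
                if ll > best_ll + 1e-6:
                    order_idx, best_ll, best_r = trial, ll, r
                    improved = True
                    break
        if not improved:
            break
    return order_idx, best_ll, best_r


def build_framework(
    scaffold: list[str],
    members: list[str],
    gm: GenotypeMatrix,
    pairs: PairwiseLinkage,
    order_lod: float = 3.0,
    epsilon: float = 0.01,
) -> tuple[list[str], np.ndarray, list[str]]:
    """Densify a scaffold into a framework order; uncertain markers deferred.

    Returns ``(framework_order, interval_r, deferred_markers)``.  Candidates
    are tried in decreasing order of their best LOD to the group, each scored
    at every insertion interval through the fitted chain's forward/backward
    arrays with flanking r taken from the two-point estimates; the insertion
    is kept only when log10 LR(best vs second-best interval) > ``order_lod``.
    """
    idx = pairs.index_of()
    gidx = gm.marker_index()
    order_idx = [idx[m] for m in scaffold]
    calls_of = lambda i: gm.calls[gidx[pairs.markers[i]]]

    remaining = [m for m in members if m not in set(scaffold)]
    mem_idx = [idx[m] for m in members]
    remaining.sort(
        key=lambda m: (-float(np.nanmax(pairs.lod[idx[m], mem_idx])), m)
    )

    r = _pair_r_init(order_idx, pairs)
    calls = np.array([calls_of(i) for i in order_idx])
    ll, r = fit_chain(calls, epsilon, r_init=r)
    deferred: list[str] = []

    for marker in remaining:
        j = idx[marker]
        m = len(order_idx)
        E = _emissions(calls, epsilon)
        A = [_transition(rk) for rk in r]
        alpha, c = _forward(E, A)
        beta = _backward(E, A, c)
        cand_emit = _emissions(gm.calls[gidx[marker]][None, :], epsilon)[0]
        rr = pairs.r_hat[j, order_idx]
        rr = np.clip(np.nan_to_num(rr, nan=_R_CAP), 1e-6, _R_CAP)
        r_left = np.concatenate([[rr[0]], rr])  # r to marker left of interval k
        r_right = np.concatenate([rr, [rr[-1]]])  # r to marker right of interval k
        scores = _insertion_scores(order_idx, E, alpha, beta, c, cand_emit, r_left, r_right)
        top = np.argsort(scores)[::-1]
        lod_gap = (scores[top[0]] - scores[top[1]]) / _LN10
        if lod_gap <= order_lod:
            deferred.append(marker)
            continue
        k = int(top[0])
        order_idx.insert(k, j)
        calls = np.insert(calls, k, gm.calls[gidx[marker]], axis=0)
        if k == 0:
            r = np.concatenate([[r_right[0]], r])
        elif k == m:
            r = np.concatenate([r, [r_left[m]]])
        else:
            r = np.concatenate([r[: k - 1], [r_left[k], r_right[k]], r[k:]])
        ll, r = fit_chain(calls, epsilon, r_init=r, tol=1e-3, max_iter=15)

    framework = [pairs.markers[i] for i in order_idx]
    return framework, r, deferred


def bin_map(
    framework: list[str],
    framework_pos: np.ndarray,
    deferred: list[str],
    pairs: PairwiseLinkage,
    lod_threshold: float = 5.0,
) -> tuple[dict[str, float], list[str]]:
    """Place deferred markers at the position of their closest framework marker.

    Closest = smallest two-point r estimate; ties broken by highest LOD, then
    lexicographic framework-marker id.  A marker whose LOD to every framework
    marker is below ``lod_threshold`` is reported unplaced.
    """
    idx = pairs.index_of()
    f_idx = np.array([idx[m] for m in framework])
    placed: dict[str, float] = {}
    unplaced: list[str] = []
    for marker in deferred:
        j = idx[marker]
        lods = pairs.lod[j, f_idx]
        if np.nanmax(lods) < lod_threshold:
            unplaced.append(marker)
            continue
        rs = np.nan_to_num(pairs.r_hat[j, f_idx], nan=np.inf)
        best = min(
            range(len(framework)),
            key=lambda k: (rs[k], -lods[k], framework[k]),
        )
        placed[marker] = float(framework_pos[best])
    return placed, unplaced


@dataclass
class OrderedGroup:
    """Result of ordering one linkage group."""

    group: str
    scaffold: list[str]
    framework: list[str]
    table: pd.DataFrame  # marker_id, position_cM, tier
    interval_r: np.ndarray  # F2-assumed scale, between framework markers
    unplaced: list[str] = field(default_factory=list)
    seed_concordance: float | None = None
    loglik: float | None = None


def _scaffold_concordance(orders: list[list[str]]) -> float | None:
    taus = []
    for a in range(len(orders)):
        for b in range(a + 1, len(orders)):
            shared = [m for m in orders[a] if m in set(orders[b])]
            if len(shared) < 3:
                continue
            rank_b = {m: i for i, m in enumerate(orders[b])}
            tau = stats.kendalltau(range(len(shared)), [rank_b[m] for m in shared]).statistic
            if np.isfinite(tau):
                taus.append(abs(tau))
    return float(np.mean(taus)) if taus else None


def order_group(
    gm: GenotypeMatrix,
    pairs: PairwiseLinkage,
    members: list[str],
    group_name: str = "LG",
    n_seeds: int = 10,
    min_spacing_cM: float = 10.0,
    order_lod: float = 3.0,
    epsilon: float = 0.01,
    bin_lod_threshold: float = 5.0,
    coseg_bins: dict[str, list[str]] | None = None,
    rng: np.random.Generator | None = None,
) -> OrderedGroup:
    """Full ordering of one linkage group: seeds -> scaffold -> framework -> bins.

    ``coseg_bins`` (representative -> members) re-attaches markers that were
    collapsed before two-point estimation; bin members share their
    representative's position.
    """
    rng = rng or np.random.default_rng(0)
    members = sorted(members)
    gidx = gm.marker_index()
    if len(members) < 2:
        table = pd.DataFrame(
            {"marker_id": members, "position_cM": [0.0] * len(members), "tier": "scaffold"}
        )
        return OrderedGroup(group_name, members, members, table, np.empty(0))

    seeds = list(rng.choice(members, size=min(n_seeds, len(members)), replace=False))
    replicates = [build_scaffold(members, pairs, s, min_spacing_cM) for s in seeds]
    concordance = _scaffold_concordance(replicates)

    def scaffold_score(order: list[str]) -> float:
        if len(order) < 2:
            return -np.inf
        ll, _ = multipoint_loglik(order, gm, epsilon, tol=1e-3, max_iter=15)
        return ll / len(order)

    best_scaffold = max(replicates, key=scaffold_score)
    idx = pairs.index_of()
    calls_full = gm.calls[[gidx[m] for m in pairs.markers]]
    scaf_idx, _, _ = _polish(
        [idx[m] for m in best_scaffold], calls_full, pairs, epsilon
    )
    scaffold = [pairs.markers[i] for i in scaf_idx]

    framework, r, deferred = build_framework(
        scaffold, members, gm, pairs, order_lod=order_lod, epsilon=epsilon
    )
    fw_idx, _, r = _polish([idx[m] for m in framework], calls_full, pairs, epsilon)
    framework = [pairs.markers[i] for i in fw_idx]
    # final refit at full precision
    ll, r = fit_chain(calls_full[fw_idx], epsilon, r_init=r)

    # deterministic orientation: smaller end-marker id first
    if framework and framework[0] > framework[-1]:
        framework = framework[::-1]
        r = r[::-1]
        scaffold = scaffold[::-1]

    positions = np.concatenate([[0.0], np.cumsum(f3model.haldane_cM(np.minimum(r, _R_CAP)))])
    placed, unplaced = bin_map(framework, positions, deferred, pairs, bin_lod_threshold)

    scaffold_set = set(scaffold)
    rows = [
        (m, p, "scaffold" if m in scaffold_set else "framework")
        for m, p in zip(framework, positions)
    ]
    rows += [(m, p, "binned") for m, p in placed.items()]
    if coseg_bins:
        rep_pos = {m: p for m, p, _ in rows}
        extra = []
        for rep, bin_members in coseg_bins.items():
            if rep in rep_pos:
                extra += [
                    (m, rep_pos[rep], "binned") for m in bin_members if m != rep
                ]
        rows += extra
    table = (
        pd.DataFrame(rows, columns=["marker_id", "position_cM", "tier"])
        .sort_values(["position_cM", "marker_id"], kind="stable")
        .reset_index(drop=True)
    )
    return OrderedGroup(
        group=group_name,
        scaffold=scaffold,
        framework=framework,
        table=table,
        interval_r=r,
        unplaced=unplaced,
        seed_concordance=concordance,
        loglik=ll,
    )
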