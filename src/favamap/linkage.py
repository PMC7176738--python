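"""Two-point recombination estimation and LOD-based linkage grouping.

Recombination fractions between marker pairs are estimated by maximum
likelihood under the F2 intercross model in known coupling phase (the
biparental design fixes the phase), using EM over the ambiguous
double-heterozygote class, whose coupling/repulsion composition is the only
hidden quantity in the two-point problem.  The data are in fact F3, so these
estimates live on the "F2-assumed" scale; the f3model module converts them to
true per-meiosis fractions downstream.

Markers are assigned to linkage groups as connected components of the graph
whose edges join pairs with LOD at or above a threshold (default 5.0) —
single-linkage transitive closure, so grouping is idempotent and
order-independent.

The LOD used for grouping is evaluated under the F3 two-locus model (the
generation the data actually come from) at the corrected recombination
fraction.  The F2-model LOD is misspecified on F3 data — the F2 model
expects 50% heterozygotes where F3 data carry 25% — which inflates its null
tail by an order of magnitude; with tens of thousands of marker pairs that
produces spurious bridges between chromosomes at any fixed threshold.  The
F3-model LOD is calibrated under independence, so a LOD 5.0 cutoff behaves
as intended.  Both statistics are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd

from . import f3model
from .io import GenotypeMatrix

__all__ = [
    "LinkagePair",
    "PairwiseLinkage",
    "LinkageGroupSet",
    "twopoint_r",
    "pairwise_linkage",
    "group_markers",
    "collapse_cosegregating",
]

_LN10 = np.log(10.0)

# recombinant-gamete count contributed by each unambiguous joint genotype
# class (rows: genotype at marker 1; cols: marker 2; coupling phase).  The
# double heterozygote (1,1) is resolved by EM.
_REC_COUNT = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)


@dataclass
class LinkagePair:
    """Two-point estimate for one marker pair (F2-assumed scale)."""

    marker_i: str
    marker_j: str
    r_hat_f2: float
    lod: float
    n_informative: int


@dataclass
class LinkageGroupSet:
    """Partition of markers into linkage groups plus unlinked singletons."""

    groups: dict[str, list[str]]
    unassigned: list[str] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def assignment(self) -> dict[str, str]:
        return {m: g for g, members in self.groups.items() for m in members}


def _f2_probs(r: np.ndarray) -> np.ndarray:
    """F2 unphased joint genotype probabilities; shape r.shape + (3, 3)."""
    r = np.asarray(r, dtype=float)
    p00 = ((1.0 - r) / 2.0) ** 2
    p01 = r * (1.0 - r) / 2.0
    p02 = (r / 2.0) ** 2
    p11 = ((1.0 - r) ** 2 + r**2) / 2.0
    out = np.empty(r.shape + (3, 3))
    out[..., 0, 0] = out[..., 2, 2] = p00
    out[..., 0, 2] = out[..., 2, 0] = p02
    out[..., 0, 1] = out[..., 1, 0] = out[..., 1, 2] = out[..., 2, 1] = p01
    out[..., 1, 1] = p11
    return out


def _loglik(counts: np.ndarray, r: np.ndarray) -> np.ndarray:
    probs = _f2_probs(r)
    terms = np.where(
        counts > 0, counts * np.log(np.maximum(probs, 1e-300)), 0.0
    )
    return terms.sum(axis=(-2, -1))


def _em_r(
    counts: np.ndarray, r0: float = 0.25, tol: float = 1e-6, max_iter: int = 200
) -> np.ndarray:
    """EM for the F2 two-point recombination fraction; broadcasts over pairs.

    ``counts`` has shape (..., 3, 3).  The E-step attributes to each double
    heterozygote ``2 r^2 / ((1-r)^2 + r^2)`` expected recombinant gametes; the
    M-step divides total expected recombinants by twice the pair count.
    """
    counts = np.asarray(counts, dtype=float)
    squeeze = counts.ndim == 2
    if squeeze:
        counts = counts[None]
    n = counts.sum(axis=(-2, -1))
    n_safe = np.where(n > 0, n, 1.0)
    rec_known = (counts * _REC_COUNT).sum(axis=(-2, -1))
    n_dh = counts[..., 1, 1]
    r = np.full(n.shape, r0)
    for _ in range(max_iter):
        frac = 2.0 * r**2 / ((1.0 - r) ** 2 + r**2)
        r_new = (rec_known + n_dh * frac) / (2.0 * n_safe)
        np.clip(r_new, 0.0, 0.5, out=r_new)
        if np.all(np.abs(r_new - r) < tol):
            r = r_new
            break
        r = r_new
    out = np.where(n > 0, r, np.nan)
    return out[0] if squeeze else out


def twopoint_r(counts_9class) -> tuple[float, float]:
    """ML recombination fraction and LOD from a 3x3 joint genotype table.

    Rows index the genotype at the first marker (AA, Aa, aa), columns the
    second; only individuals non-missing at both markers are counted.
    Returns ``(r_hat_f2, lod)`` with LOD = log10 L(r_hat) - log10 L(0.5).
    """
    counts = np.asarray(counts_9class, dtype=float)
    if counts.shape != (3, 3) or np.any(counts < 0):
        raise ValueError("expected a non-negative 3x3 joint genotype table")
    if counts.sum() == 0:
        raise ValueError("no informative individuals for this pair")
    r_hat = float(_em_r(counts))
    lod = float((_loglik(counts, np.array(r_hat)) - _loglik(counts, np.array(0.5))) / _LN10)
    return r_hat, max(lod, 0.0)


@dataclass
class PairwiseLinkage:
    """All-pairs two-point estimates over one marker set.

    ``lod`` is the F3-model significance LOD used for grouping and linkage
    strength; ``lod_f2`` is the F2-assumed statistic matching ``r_hat``.
    Matrices are symmetric with NaN (r) / 0 (lod) diagonals; ``n_informative``
    counts individuals non-missing at both markers.
    """

    markers: list[str]
    r_hat: np.ndarray
    lod: np.ndarray
    lod_f2: np.ndarray
    n_informative: np.ndarray

    def to_pairs(self, min_lod: float = 0.0) -> pd.DataFrame:
        iu, ju = np.triu_indices(len(self.markers), k=1)
        keep = self.lod[iu, ju] >= min_lod
        iu, ju = iu[keep], ju[keep]
        names = np.asarray(self.markers)
        return pd.DataFrame(
            {
                "marker_i": names[iu],
                "marker_j": names[ju],
                "r_hat": self.r_hat[iu, ju],
                "lod": self.lod[iu, ju],
                "lod_f2": self.lod_f2[iu, ju],
                "n_informative": self.n_informative[iu, ju],
            }
        )

    def index_of(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.markers)}


@lru_cache(maxsize=1)
def _f3_grid_logprobs(n_grid: int = 501) -> tuple[np.ndarray, np.ndarray]:
    """Log joint genotype probabilities of the F3 model on an r grid."""
    grid = np.linspace(0.0, 0.5, n_grid)
    logp = np.empty((n_grid, 9))
    for k, r in enumerate(grid):
        logp[k] = np.log(np.maximum(f3model.f3_joint(r).ravel(), 1e-300))
    return grid, logp


def _f3_lod(counts_flat: np.ndarray) -> np.ndarray:
    """Grid-profile F3-model LOD for (n_pairs, 9) joint count rows."""
    _, logp = _f3_grid_logprobs()
    out = np.empty(counts_flat.shape[0])
    block = 65536
    for s in range(0, counts_flat.shape[0], block):
        ll = counts_flat[s : s + block] @ logp.T
        out[s : s + block] = (ll.max(axis=1) - ll[:, -1]) / _LN10
    return np.maximum(out, 0.0)


def pairwise_linkage(gm: GenotypeMatrix) -> PairwiseLinkage:
    """Vectorized two-point estimation over all marker pairs.

    ``r_hat`` is the F2-assumed EM estimate (the scale the ordering stage
    works on); ``lod`` the F3-model grid-profile LOD; ``lod_f2`` the
    F2-assumed LOD.
    """
    X = gm.calls
    ind = [(X == g).astype(np.float64) for g in (0, 1, 2)]
    m = gm.n_markers
    counts = np.empty((m, m, 3, 3))
    for a in range(3):
        for b in range(3):
            counts[:, :, a, b] = ind[a] @ ind[b].T
    n_inf = counts.sum(axis=(2, 3))
    r = _em_r(counts)
    lod_f2 = (
        _loglik(counts, np.nan_to_num(r, nan=0.5)) - _loglik(counts, np.full((m, m), 0.5))
    ) / _LN10
    lod_f2 = np.maximum(lod_f2, 0.0)
    lod = _f3_lod(counts.reshape(m * m, 9)).reshape(m, m)
    for mat in (lod, lod_f2):
        np.fill_diagonal(mat, 0.0)
    np.fill_diagonal(r, np.nan)
    return PairwiseLinkage(
        markers=list(gm.markers),
        r_hat=r,
        lod=lod,
        lod_f2=lod_f2,
        n_informative=n_inf.astype(int),
    )


def group_markers(
    pairs: PairwiseLinkage | pd.DataFrame,
    lod_threshold: float = 5.0,
    anchors: dict[str, str] | None = None,
    markers: list[str] | None = None,
) -> LinkageGroupSet:
    """Linkage groups as connected components of the LOD >= threshold graph.

    Accepts either a :class:`PairwiseLinkage` or a pairs DataFrame
    (``marker_i``, ``marker_j``, ``lod``).  Groups are labelled by the anchor
    file's chromosome name when any member is anchored (majority vote on
    conflicts), otherwise ``LG1``, ``LG2``, ... in decreasing size order.
    Singletons are reported as unassigned.
    """
    g = nx.Graph()
    if isinstance(pairs, PairwiseLinkage):
        g.add_nodes_from(pairs.markers)
        iu, ju = np.nonzero(np.triu(pairs.lod >= lod_threshold, k=1))
        names = np.asarray(pairs.markers)
        g.add_edges_from(zip(names[iu], names[ju]))
    else:
        if markers is not None:
            g.add_nodes_from(markers)
        sel = pairs[pairs["lod"] >= lod_threshold]
        g.add_edges_from(zip(sel["marker_i"], sel["marker_j"]))
        g.add_nodes_from(pairs["marker_i"])
        g.add_nodes_from(pairs["marker_j"])

    components = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    groups: dict[str, list[str]] = {}
    unassigned: list[str] = []
    anchors = anchors or {}
    auto = 0
    for comp in components:
        if len(comp) == 1:
            unassigned.extend(comp)
            continue
        hits = [anchors[m] for m in comp if m in anchors]
        if hits:
            label = max(sorted(set(hits)), key=hits.count)
            if label in groups:  # two components anchored to one chromosome
                label = f"{label}_bis{auto}"
                auto += 1
        else:
            auto += 1
            label = f"LG{auto}"
        # ensure auto labels never collide with anchored ones
        while label in groups:
            auto += 1
            label = f"LG{auto}"
        groups[label] = comp
    return LinkageGroupSet(groups=groups, unassigned=unassigned)


def collapse_cosegregating(
    gm: GenotypeMatrix,
) -> tuple[GenotypeMatrix, dict[str, list[str]]]:
    """Collapse markers with identical call vectors into cosegregation bins.

    Returns the matrix restricted to one representative per bin (first marker
    in input order) and a mapping representative -> all bin members.  Bin
    members are re-attached at the representative's position during
    bin-mapping.
    """
    seen: dict[bytes, str] = {}
    bins: dict[str, list[str]] = {}
    reps: list[str] = []
    for marker, row in zip(gm.markers, gm.calls):
        key = row.tobytes()
        if key in seen:
            bins[seen[key]].append(marker)
        else:
            seen[key] = marker
            bins[marker] = [marker]
            reps.append(marker)
    return gm.subset(reps), bins
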