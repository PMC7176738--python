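"""Consensus-map construction by minimizing the inter-map distance index I_D.

Two maps are compared through

    D(M, M') = sum_i sum_{j(i)} ( d(M_(i,j)) - d(M'_(i,j)) )^2,

where i runs over markers common to both maps and j(i) over common markers
whose distance to i, in the map supplying the constraint, lies between d_min
and d_max (too-close intervals are poorly determined, too-far ones carry
little information), keeping at most K per side so every marker weighs
equally.  Each unordered (i, j) pair is counted once.

The consensus M* of maps M_1..M_N minimizes I_D = sum_n w_n D(M*, M_n) with
w_n the population size of map n.  Because eligibility and the target
distances are fixed by the individual maps, I_D is quadratic in the unknown
consensus positions: each constraint asks ``x_j - x_i`` to match the signed
distance observed in a source map.  The minimizer solves the weighted-graph-
Laplacian normal equations, one connected constraint component at a time,
with the first marker anchored at the origin.  The consensus contains every
marker of every input map; markers without any usable constraint are placed
by translation from their best-weighted source map and flagged.

The method does not require the input maps to be collinear, but they must be
consistently oriented; :func:`orient_maps` flips whole groups against a
reference when that raises the Spearman correlation of shared markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse import csgraph
from scipy.sparse.linalg import spsolve

from .io import GeneticMap

__all__ = [
    "NeighborScheme",
    "ConsensusMap",
    "map_distance",
    "build_consensus",
    "orient_maps",
    "compare_maps",
    "summarize_map",
]


@dataclass(frozen=True)
class NeighborScheme:
    """Eligibility window for constraint pairs (cM) and per-side cap."""

    d_min: float = 0.5
    d_max: float = 100.0
    k_per_side: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.d_min < self.d_max):
            raise ValueError("need 0 < d_min < d_max")
        if self.k_per_side < 1:
            raise ValueError("k_per_side must be >= 1")


def _eligible_pairs(
    positions: dict[str, float], scheme: NeighborScheme
) -> list[tuple[str, str, float]]:
    """Unordered eligible pairs (i, j, signed distance pos_j - pos_i).

    Eligibility is judged in the supplied map: d_min <= |d| <= d_max, at most
    ``k_per_side`` nearest neighbours on each side of i.  Pairs are
    deduplicated so each enters a sum exactly once.
    """
    items = sorted(positions.items(), key=lambda kv: (kv[1], kv[0]))
    names = [m for m, _ in items]
    pos = np.array([p for _, p in items])
    chosen: set[tuple[str, str]] = set()
    out: list[tuple[str, str, float]] = []
    for a in range(len(names)):
        for direction in (1, -1):
            kept = 0
            b = a + direction
            while 0 <= b < len(names) and kept < scheme.k_per_side:
                d = abs(pos[b] - pos[a])
                if d > scheme.d_max:
                    break
                if d >= scheme.d_min:
                    key = (names[a], names[b]) if names[a] < names[b] else (names[b], names[a])
                    if key not in chosen:
                        chosen.add(key)
                        out.append((key[0], key[1], positions[key[1]] - positions[key[0]]))
                    kept += 1
                b += direction
    return out


def map_distance(
    map_a: GeneticMap, map_b: GeneticMap, scheme: NeighborScheme = NeighborScheme()
) -> tuple[float, list[tuple[str, str, str, float, float]]]:
    """D(map_a, map_b) and the constraint list used.

    Constraints are built from markers common to both maps, with eligibility
    judged in ``map_a`` (the map supplying the constraint).  Returns the
    scalar D and tuples ``(group, i, j, d_a, d_b)``.  Groups with fewer than
    two shared markers contribute nothing.
    """
    pos_b = map_b.positions()
    constraints: list[tuple[str, str, str, float, float]] = []
    total = 0.0
    for group in map_a.groups:
        ga = map_a.group_table(group)
        shared = {
            m: p for m, p in zip(ga["marker_id"], ga["position_cM"]) if m in pos_b.index
        }
        if len(shared) < 2:
            continue
        for i, j, d_a in _eligible_pairs(shared, scheme):
            d_b = float(pos_b[j] - pos_b[i])
            total += (d_a - d_b) ** 2
            constraints.append((group, i, j, float(d_a), d_b))
    return total, constraints


@dataclass
class ConsensusMap:
    """Merged map over all input markers, with source bookkeeping."""

    table: pd.DataFrame  # marker_id, chromosome, position_cM, sources, flagged
    index_I_D: float
    per_map_D: dict[str, float]
    scheme: NeighborScheme = field(default_factory=NeighborScheme)

    def as_genetic_map(self, population_id: str = "consensus") -> GeneticMap:
        df = self.table.rename(columns={"chromosome": "group"})[
            ["marker_id", "group", "position_cM"]
        ]
        return GeneticMap(population_id=population_id, table=df)


def _solve_component(
    markers: list[str],
    constraints: list[tuple[int, int, float, float]],
) -> np.ndarray:
    """Minimize sum w (x_j - x_i - d)^2 with x[0] anchored at 0."""
    n = len(markers)
    lap = sparse.lil_matrix((n, n))
    b = np.zeros(n)
    for i, j, d, w in constraints:
        lap[i, i] += w
        lap[j, j] += w
        lap[i, j] -= w
        lap[j, i] -= w
        b[i] -= w * d
        b[j] += w * d
    x = np.zeros(n)
    if n > 1:
        sub = lap.tocsr()[1:, 1:].tocsc()
        x[1:] = spsolve(sub, b[1:])
    return x


def build_consensus(
    maps: list[GeneticMap],
    population_sizes: dict[str, float] | None = None,
    scheme: NeighborScheme = NeighborScheme(),
) -> ConsensusMap:
    """Weighted least-squares consensus of one or more individual maps.

    ``population_sizes`` overrides the sizes stored on the maps; maps with no
    size anywhere default to weight 1.  Input maps must be consistently
    oriented (see :func:`orient_maps`).  Per chromosome, every marker of every
    map is included; the first marker of each connected constraint component
    sits at 0 and disconnected components or constraint-free markers are
    flagged in the output table.
    """
    if not maps:
        raise ValueError("need at least one input map")
    sizes = population_sizes or {}

    def weight(m: GeneticMap) -> float:
        return float(sizes.get(m.population_id, m.population_size or 1.0))

    chromosomes = list(dict.fromkeys(g for m in maps for g in m.groups))
    # a marker group-labelled differently across maps goes to the chromosome
    # carrying most population weight for it (it enters the consensus once)
    votes: dict[str, dict[str, float]] = {}
    for m in maps:
        w = weight(m)
        for chrom in m.groups:
            for mk in m.group_table(chrom)["marker_id"]:
                votes.setdefault(mk, {}).setdefault(chrom, 0.0)
                votes[mk][chrom] += w
    chrom_of = {
        mk: max(sorted(v), key=lambda c: v[c]) for mk, v in votes.items()
    }

    rows = []
    for chrom in chromosomes:
        marker_sources: dict[str, list[str]] = {}
        norm_pos: dict[str, list[float]] = {}
        constraints: list[tuple[str, str, float, float]] = []
        for m in maps:
            gt = m.group_table(chrom)
            gt = gt[[chrom_of[mk] == chrom for mk in gt["marker_id"]]]
            if gt.empty:
                continue
            positions = dict(zip(gt["marker_id"], gt["position_cM"]))
            lo, hi = min(positions.values()), max(positions.values())
            span = (hi - lo) or 1.0
            for mk, p in positions.items():
                marker_sources.setdefault(mk, []).append(m.population_id)
                norm_pos.setdefault(mk, []).append((p - lo) / span)
            w = weight(m)
            for i, j, d in _eligible_pairs(positions, scheme):
                constraints.append((i, j, d, w))

        markers = sorted(marker_sources)
        index = {mk: k for k, mk in enumerate(markers)}
        # connected components of the constraint graph
        adj = sparse.lil_matrix((len(markers), len(markers)), dtype=bool)
        for i, j, _, _ in constraints:
            adj[index[i], index[j]] = True
            adj[index[j], index[i]] = True
        n_comp, labels = csgraph.connected_components(adj.tocsr(), directed=False)

        fitted = np.zeros(len(markers))
        flagged = np.zeros(len(markers), dtype=bool)
        main_comp = np.argmax(np.bincount(labels)) if len(markers) else 0
        # solve constrained components first: isolated markers interpolate
        # from positions that must already be fitted
        comp_order = sorted(
            range(n_comp), key=lambda c: (np.sum(labels == c) == 1, c)
        )
        for comp in comp_order:
            comp_markers = [markers[k] for k in range(len(markers)) if labels[k] == comp]
            cidx = {mk: k for k, mk in enumerate(comp_markers)}
            comp_constraints = [
                (cidx[i], cidx[j], d, w)
                for i, j, d, w in constraints
                if i in cidx and j in cidx
            ]
            if len(comp_markers) == 1 and not comp_constraints:
                # no usable constraint: translate from the heaviest source map
                mk = comp_markers[0]
                best = max(
                    (m for m in maps if mk in set(m.group_table(chrom)["marker_id"])),
                    key=weight,
                )
                gt = best.group_table(chrom)
                pos_map = dict(zip(gt["marker_id"], gt["position_cM"]))
                anchored = [
                    k for k in pos_map if k in index and labels[index[k]] == main_comp
                ]
                if anchored:
                    offset = float(
                        np.mean([fitted[index[k]] - pos_map[k] for k in anchored])
                    )
                else:
                    offset = 0.0
                fitted[index[mk]] = pos_map[mk] + offset
                flagged[index[mk]] = True
                continue
            x = _solve_component(comp_markers, comp_constraints)
            x -= x.min()
            for mk, v in zip(comp_markers, x):
                fitted[index[mk]] = v
                if comp != main_comp and n_comp > 1:
                    flagged[index[mk]] = True

        for mk in markers:
            rows.append(
                {
                    "marker_id": mk,
                    "chromosome": chrom,
                    "position_cM": fitted[index[mk]],
                    "sources": ",".join(marker_sources[mk]),
                    "n_sources": len(marker_sources[mk]),
                    "mean_norm_pos": float(np.mean(norm_pos[mk])),
                    "flagged": bool(flagged[index[mk]]),
                }
            )

    table = (
        pd.DataFrame(rows)
        .sort_values(
            ["chromosome", "position_cM", "mean_norm_pos", "marker_id"], kind="stable"
        )
        .reset_index(drop=True)
    )
    consensus = ConsensusMap(table=table, index_I_D=0.0, per_map_D={}, scheme=scheme)
    cons_map = consensus.as_genetic_map()
    per_map_D = {}
    i_d = 0.0
    for m in maps:
        d, _ = map_distance(m, cons_map, scheme)
        per_map_D[m.population_id] = d
        i_d += weight(m) * d
    consensus.per_map_D = per_map_D
    consensus.index_I_D = float(i_d)
    return consensus


def orient_maps(maps: list[GeneticMap], reference: GeneticMap) -> list[GeneticMap]:
    """Flip whole groups of each map when that raises the Spearman correlation
    of shared-marker positions with the reference; ties keep the original."""
    ref_pos = reference.positions()
    out = []
    for m in maps:
        table = m.table.copy()
        for group in m.groups:
            gt = m.group_table(group)
            shared = gt[gt["marker_id"].isin(ref_pos.index)]
            if len(shared) < 3:
                continue
            a = shared["position_cM"].to_numpy()
            b = ref_pos[shared["marker_id"]].to_numpy()
            rho = stats.spearmanr(a, b).statistic
            rho_flip = stats.spearmanr(-a, b).statistic
            if np.isfinite(rho_flip) and (not np.isfinite(rho) or rho_flip > rho):
                sel = table["group"] == group
                table.loc[sel, "position_cM"] = (
                    table.loc[sel, "position_cM"].max() - table.loc[sel, "position_cM"]
                )
        out.append(
            GeneticMap(
                population_id=m.population_id,
                table=table,
                population_size=m.population_size,
            )
        )
    return out


def compare_maps(map_a: GeneticMap, map_b: GeneticMap):
    """Shared-marker count, Spearman correlations, and dot-plot data.

    Returns ``(n_shared, rho_by_group, pooled_rho, dotplot)`` where
    ``pooled_rho`` is computed on within-group normalized positions pooled
    over groups and ``dotplot`` has one row per shared marker.  Group
    correlations need at least three shared markers, else NaN.
    """
    pos_b = map_b.positions()
    rho_by_group: dict[str, float] = {}
    records = []
    for group in map_a.groups:
        ga = map_a.group_table(group)
        shared = ga[ga["marker_id"].isin(pos_b.index)]
        if shared.empty:
            continue
        a = shared["position_cM"].to_numpy()
        b = pos_b[shared["marker_id"]].to_numpy()

        def norm(x):
            span = x.max() - x.min()
            return (x - x.min()) / span if span > 0 else np.zeros_like(x)

        for mk, pa, pb, na, nb in zip(shared["marker_id"], a, b, norm(a), norm(b)):
            records.append((mk, group, pa, pb, na, nb))
        rho_by_group[group] = (
            float(stats.spearmanr(a, b).statistic) if len(shared) >= 3 else float("nan")
        )
    dotplot = pd.DataFrame(
        records,
        columns=["marker_id", "group", "pos_a", "pos_b", "norm_pos_a", "norm_pos_b"],
    )
    n_shared = len(dotplot)
    pooled = (
        float(stats.spearmanr(dotplot["norm_pos_a"], dotplot["norm_pos_b"]).statistic)
        if n_shared >= 3
        else float("nan")
    )
    return n_shared, rho_by_group, pooled, dotplot


def summarize_map(gmap: GeneticMap, large_gap_cM: float = 10.0) -> pd.DataFrame:
    """Per-group and total map features.

    Columns mirror the usual map-summary table: marker count, length (cM),
    unique positions, average marker density (markers/cM), average gap between
    non-colocalized adjacent markers, number of gaps larger than
    ``large_gap_cM`` and the largest gap.
    """
    rows = []
    all_gaps = []
    for group in gmap.groups:
        gt = gmap.group_table(group)
        pos = gt["position_cM"].to_numpy()
        uniq = np.unique(np.round(pos, 6))
        gaps = np.diff(uniq)
        all_gaps.append(gaps)
        length = float(pos.max() - pos.min()) if len(pos) else 0.0
        rows.append(
            {
                "group": group,
                "markers": len(gt),
                "length_cM": length,
                "unique_positions": len(uniq),
                "density_per_cM": len(gt) / length if length > 0 else np.nan,
                "mean_gap_cM": float(gaps.mean()) if len(gaps) else np.nan,
                "gaps_gt_10cM": int((gaps > large_gap_cM).sum()),
                "largest_gap_cM": float(gaps.max()) if len(gaps) else np.nan,
            }
        )
    gaps = np.concatenate(all_gaps) if all_gaps else np.array([])
    total_len = sum(r["length_cM"] for r in rows)
    total_markers = sum(r["markers"] for r in rows)
    rows.append(
        {
            "group": "Total",
            "markers": total_markers,
            "length_cM": total_len,
            "unique_positions": sum(r["unique_positions"] for r in rows),
            "density_per_cM": total_markers / total_len if total_len > 0 else np.nan,
            "mean_gap_cM": float(gaps.mean()) if len(gaps) else np.nan,
            "gaps_gt_10cM": int((gaps > large_gap_cM).sum()),
            "largest_gap_cM": float(gaps.max()) if len(gaps) else np.nan,
        }
    )
    return pd.DataFrame(rows)
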