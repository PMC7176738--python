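"""Simulation of F3 mapping populations with known truth.

The generator mirrors the biparental single-seed-descent design used for the
faba bean mapping populations: two fully homozygous, fully contrasting
parents; an F1 in complete coupling phase; F2 plants formed from two
independent F1 gametes; and each F3 individual produced by selfing one F2
plant once.  Crossovers follow a Markov switching process along each linkage
group with no interference (Haldane's model), so true adjacent recombination
fractions translate to cM through Haldane's function.

Segregation distortion is modelled as genotype-viability weighting at named
loci: an F3 individual survives sampling with probability proportional to the
product of its viability weights over all distortion loci.  Because linked
neighbours co-segregate with a distortion locus, this produces the clustered,
regional distortion profiles seen in real maps without modelling a mechanism.

Genotyping error (a wrong call replaced by one of the other two classes) and
missing data are applied last; the returned truth record keeps the pre-noise
genotypes and the F2-stage gametes so recombination can be recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import f3model
from .io import GenotypeMatrix, write_genotypes

__all__ = [
    "TrueLinkageGroup",
    "TrueMap",
    "SimConfig",
    "PopulationTruth",
    "simulate_gametes",
    "simulate_f3_population",
    "make_true_map",
    "write_fixture",
    "DEFAULT_GROUP_LENGTHS_CM",
    "DEFAULT_POPULATION_SIZES",
]

#: Per-group map lengths (cM) of the default six-group truth, within the
#: 150-550 cM range spanned by real faba bean linkage groups (LG1 longest).
DEFAULT_GROUP_LENGTHS_CM = (480.0, 255.0, 245.0, 215.0, 200.0, 170.0)

#: F3 population sizes of the three study populations (common female parent).
DEFAULT_POPULATION_SIZES = {"Pop1": 102, "Pop2": 147, "Pop3": 96}


@dataclass
class TrueLinkageGroup:
    """Ground truth for one linkage group: ordered markers and adjacent r."""

    name: str
    markers: list[str]
    r_adjacent: np.ndarray  # true recombination fractions, length len(markers)-1

    def __post_init__(self) -> None:
        self.r_adjacent = np.asarray(self.r_adjacent, dtype=float)
        if self.r_adjacent.shape != (max(len(self.markers) - 1, 0),):
            raise ValueError("r_adjacent length must be n_markers - 1")
        if np.any((self.r_adjacent < 0) | (self.r_adjacent >= 0.5)):
            raise ValueError("adjacent recombination fractions must lie in [0, 0.5)")

    def positions_cM(self) -> np.ndarray:
        if not self.markers:
            return np.array([])
        return np.concatenate([[0.0], np.cumsum(f3model.haldane_cM(self.r_adjacent))])


@dataclass
class TrueMap:
    """Ground-truth genetic map plus optional viability weights at distortion loci.

    ``viability`` maps marker_id -> (w_AA, w_AB, w_BB); weights are relative
    survival probabilities of the three F3 genotypes at that locus.
    """

    groups: list[TrueLinkageGroup]
    viability: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [m for g in self.groups for m in g.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("marker ids must be unique across groups")
        known = set(ids)
        for m, w in self.viability.items():
            if m not in known:
                raise ValueError(f"viability weight for unknown marker {m}")
            w = np.asarray(w, dtype=float)
            if w.shape != (3,) or np.any(w < 0) or not np.any(w > 0):
                raise ValueError(f"viability weights at {m} must be >= 0, not all zero")

    @property
    def n_markers(self) -> int:
        return sum(len(g.markers) for g in self.groups)

    def to_table(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            pos = g.positions_cM()
            for m, p in zip(g.markers, pos):
                w = self.viability.get(m, (1.0, 1.0, 1.0))
                rows.append((m, g.name, p, *w))
        return pd.DataFrame(
            rows,
            columns=["marker_id", "group", "true_position_cM", "w_AA", "w_AB", "w_BB"],
        )


@dataclass
class SimConfig:
    """Sampling conditions for one simulated F3 population."""

    population_size: int
    missing_rate: float = 0.05
    genotyping_error_rate: float = 0.005
    rng_seed: int = 0
    population_id: str = "Pop"

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("missing_rate", "genotyping_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class PopulationTruth:
    """Pre-noise record of one simulated population.

    ``f2_gametes`` holds, per group, the two F1 gametes that formed each
    individual's F2 parent (arrays of shape (n, n_markers_in_group)); the
    empirical switch rate between adjacent columns estimates the true r at
    the F2 stage.  ``true_calls`` are the F3 genotypes before error/missing.
    """

    true_map: TrueMap
    true_calls: np.ndarray  # (n_markers_total, n) int8, no noise
    f2_gametes: dict[str, tuple[np.ndarray, np.ndarray]]
    markers: list[str]


def _check_r_vector(r_vector: np.ndarray) -> np.ndarray:
    r = np.asarray(r_vector, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("r_vector entries must lie in [0, 0.5)")
    return r


def _strand_paths(n: int, r_vector: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """n binary strand-choice paths over len(r)+1 loci; switch prob r_k."""
    m = len(r_vector) + 1
    start = rng.integers(0, 2, size=n)
    if m == 1:
        return start[:, None]
    switches = (rng.random((n, m - 1)) < r_vector[None, :]).astype(np.int8)
    path = np.empty((n, m), dtype=np.int8)
    path[:, 0] = start
    acc = np.cumsum(switches, axis=1)
    path[:, 1:] = (start[:, None] + acc) % 2
    return path


def simulate_gametes(
    parent: np.ndarray, r_vector, rng: np.random.Generator, n: int = 1
) -> np.ndarray:
    """Draw ``n`` gametes from a parent's two-strand genotype.

    ``parent`` is a (2, n_loci) array of haplotype alleles.  The gamete copies
    the first locus from a random strand and switches strand between loci k
    and k+1 with probability ``r_vector[k]`` (no interference).
    """
    parent = np.asarray(parent)
    if parent.ndim != 2 or parent.shape[0] != 2:
        raise ValueError("parent must be a (2, n_loci) two-strand genotype")
    r = _check_r_vector(r_vector)
    if len(r) != parent.shape[1] - 1:
        raise ValueError("r_vector length must be n_loci - 1")
    paths = _strand_paths(n, r, rng)
    cols = np.arange(parent.shape[1])
    return parent[paths, cols[None, :]]


def _simulate_group_batch(
    group: TrueLinkageGroup, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate n F3 individuals for one group.

    Returns (genotypes (n, m), f2_gamete_1, f2_gamete_2).  With the F1 strands
    being all-0 and all-1, an F1 gamete equals its strand-choice path.
    """
    r = group.r_adjacent
    g1 = _strand_paths(n, r, rng)  # first F1 gamete -> F2 strand 1
    g2 = _strand_paths(n, r, rng)  # second F1 gamete -> F2 strand 2
    # two gametes of the selfed F2: strand-choice paths over the F2 diplotype
    t1 = _strand_paths(n, r, rng)
    t2 = _strand_paths(n, r, rng)
    h1 = np.where(t1 == 0, g1, g2)
    h2 = np.where(t2 == 0, g1, g2)
    return (h1 + h2).astype(np.int8), g1, g2


def simulate_f3_population(
    true_map: TrueMap, config: SimConfig
) -> tuple[GenotypeMatrix, PopulationTruth]:
    """Simulate one F3 population under ``true_map`` and ``config``.

    Viability weights act as sampling weights on whole individuals (rejection
    sampling against the product of per-locus genotype weights), then missing
    data and genotyping error are overlaid.  The truth record keeps pre-noise
    genotypes and the F2-stage gametes.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_target = config.population_size
    markers = [m for g in true_map.groups for m in g.markers]
    marker_pos = {m: i for i, m in enumerate(markers)}

    # per-group list of (marker row slice, distortion locus indices + weights)
    weights_by_group = []
    offset = 0
    for g in true_map.groups:
        loci = [
            (marker_pos[m] - offset, np.asarray(true_map.viability[m], dtype=float))
            for m in g.markers
            if m in true_map.viability
        ]
        weights_by_group.append(loci)
        offset += len(g.markers)

    accepted_calls: list[np.ndarray] = []
    accepted_f2: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {
        g.name: [] for g in true_map.groups
    }
    n_have = 0
    max_rounds = 200
    for _ in range(max_rounds):
        if n_have >= n_target:
            break
        batch = max(n_target - n_have, 32)
        per_group = [
            _simulate_group_batch(g, batch, rng) for g in true_map.groups
        ]
        weight = np.ones(batch)
        for (geno, _, _), loci in zip(per_group, weights_by_group):
            for col, w in loci:
                weight *= w[geno[:, col]] / w.max()
        keep = rng.random(batch) < weight
        if not keep.any():
            continue
        calls = np.concatenate([geno[keep] for geno, _, _ in per_group], axis=1)
        accepted_calls.append(calls)
        for g, (_, f2a, f2b) in zip(true_map.groups, per_group):
            accepted_f2[g.name].append((f2a[keep], f2b[keep]))
        n_have += int(keep.sum())
    if n_have < n_target:
        raise RuntimeError(
            "viability rejection sampling failed to reach the population size"
        )

    true_calls = np.concatenate(accepted_calls, axis=0)[:n_target].T.copy()  # (M, n)
    f2_gametes = {
        name: (
            np.concatenate([a for a, _ in parts], axis=0)[:n_target],
            np.concatenate([b for _, b in parts], axis=0)[:n_target],
        )
        for name, parts in accepted_f2.items()
    }

    # genotyping error, then missingness (a missing call hides any error)
    noisy = true_calls.copy()
    if config.genotyping_error_rate > 0:
        err = rng.random(noisy.shape) < config.genotyping_error_rate
        shift = rng.integers(1, 3, size=noisy.shape)
        noisy[err] = ((noisy[err] + shift[err]) % 3).astype(np.int8)
    if config.missing_rate > 0:
        noisy[rng.random(noisy.shape) < config.missing_rate] = -1

    individuals = [f"{config.population_id}_I{i + 1:03d}" for i in range(n_target)]
    hints = [g.name for g in true_map.groups for _ in g.markers]
    gm = GenotypeMatrix(
        markers=markers, individuals=individuals, calls=noisy, group_hint=hints
    )
    truth = PopulationTruth(
        true_map=true_map, true_calls=true_calls, f2_gametes=f2_gametes, markers=markers
    )
    return gm, truth


def make_true_map(
    n_markers: int = 300,
    group_lengths_cM=DEFAULT_GROUP_LENGTHS_CM,
    rng_seed: int = 0,
    distortion_region: bool = True,
    distortion_weights: tuple[float, float, float] = (0.5, 0.75, 1.0),
    distortion_span_cM: float = 40.0,
) -> TrueMap:
    """A study-like random truth: six groups with well-distributed markers.

    Markers are allotted to groups proportionally to group length and placed
    on a jittered regular grid (uniform jitter of up to +/-45% of the mean
    spacing), emulating maps whose markers are dense and well distributed
    rather than Poisson-scattered; the largest inter-marker gap stays below
    twice the mean spacing.  When ``distortion_region`` is set, markers in the
    last ``distortion_span_cM`` of the first group carry viability weights
    favouring the male-parent homozygote, emulating the distorted region
    observed at the bottom of the longest linkage group.
    """
    rng = np.random.default_rng(rng_seed)
    lengths = np.asarray(group_lengths_cM, dtype=float)
    counts = np.maximum(2, np.round(n_markers * lengths / lengths.sum()).astype(int))
    groups = []
    viability: dict[str, tuple[float, float, float]] = {}
    for g, (length, count) in enumerate(zip(lengths, counts), start=1):
        spacing = length / (count - 1)
        grid = np.arange(count) * spacing
        pos = np.sort(grid + rng.uniform(-0.45, 0.45, size=count) * spacing)
        pos -= pos[0]
        r_adj = f3model.haldane_inverse(np.diff(pos))
        ids = [f"M{g}_{j + 1:04d}" for j in range(count)]
        groups.append(TrueLinkageGroup(name=f"LG{g}", markers=ids, r_adjacent=r_adj))
        if distortion_region and g == 1:
            for m, p in zip(ids, pos):
                if p >= pos[-1] - distortion_span_cM:
                    viability[m] = distortion_weights
    return TrueMap(groups=groups, viability=viability)


def write_fixture(gm: GenotypeMatrix, truth: PopulationTruth, out_dir) -> dict[str, Path]:
    """Write the genotype and truth TSVs for one simulated population."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pop = gm.individuals[0].rsplit("_", 1)[0] if gm.individuals else "pop"
    geno_path = out / f"{pop}.geno.tsv"
    truth_path = out / f"{pop}.truth.tsv"
    write_genotypes(gm, geno_path)
    df = truth.true_map.to_table()
    df["true_position_cM"] = df["true_position_cM"].map(lambda x: f"{x:.6f}")
    df.to_csv(truth_path, sep="\t", index=False)
    return {"genotypes": geno_path, "truth": truth_path}
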