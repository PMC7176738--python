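"""End-to-end orchestration: simulate -> qc -> group -> order -> correct -> consensus.

A run is fully specified by a :class:`RunConfig` (round-trippable through
YAML/JSON) and a single integer seed; every stage draws randomness from a
stream forked off that seed by a stable label, so reruns are byte-identical
and stages rerun in isolation reproduce their in-run behaviour.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus as cons
from . import f3model, linkage, markerqc, ordering, popsim
from ._rng import stage_rng, stage_seed
from .io import (
    GeneticMap,
    GenotypeMatrix,
    read_anchors,
    read_genotypes,
    write_genotypes,
    write_map,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("favamap")


@dataclass
class PopulationSpec:
    id: str
    size: int


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run."""

    seed: int = 0
    out_dir: str = "favamap_run"
    # input: simulated populations ...
    simulate: bool = True
    n_markers: int = 300
    populations: list[PopulationSpec] = field(
        default_factory=lambda: [
            PopulationSpec(pid, n) for pid, n in popsim.DEFAULT_POPULATION_SIZES.items()
        ]
    )
    missing_rate: float = 0.05
    genotyping_error_rate: float = 0.005
    distortion_region: bool = True
    # ... or genotype TSVs supplied by the user (population id -> path)
    genotype_files: dict[str, str] = field(default_factory=dict)
    population_sizes: dict[str, int] = field(default_factory=dict)
    anchor_file: str | None = None
    # stage parameters
    distortion_threshold: float = 0.8
    max_missing_fraction: float = 0.2
    grouping_lod: float = 5.0
    n_seeds: int = 10
    min_spacing_cM: float = 10.0
    order_lod: float = 3.0
    # HMM genotyping-error rate; default matches the simulator's error rate
    epsilon: float = 0.005
    d_min: float = 0.5
    d_max: float = 100.0
    k_per_side: int = 10

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate <= 1 and 0 <= self.genotyping_error_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        for name in ("distortion_threshold", "grouping_lod", "order_lod", "epsilon"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.simulate and not self.genotype_files:
            raise ValueError("either enable simulation or supply genotype files")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        pops = d.get("populations")
        if pops is not None:
            d["populations"] = [
                p if isinstance(p, PopulationSpec) else PopulationSpec(**p) for p in pops
            ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _map_one_population(
    pop_id: str,
    gm: GenotypeMatrix,
    cfg: RunConfig,
    anchors: dict[str, str] | None,
    out: Path,
    size: int | None,
) -> tuple[GeneticMap, pd.DataFrame]:
    """QC, grouping, ordering and F3 correction for one population."""
    kept, _, report = markerqc.filter_markers(
        gm, cfg.distortion_threshold, cfg.max_missing_fraction
    )
    report.to_csv(out / f"{pop_id}.qc.tsv", sep="\t", index=False)
    log.info("%s: %d/%d markers pass QC", pop_id, kept.n_markers, gm.n_markers)

    collapsed, bins = linkage.collapse_cosegregating(kept)
    pairs = linkage.pairwise_linkage(collapsed)
    pairs.to_pairs(min_lod=cfg.grouping_lod).to_csv(
        out / f"{pop_id}.pairs.tsv", sep="\t", index=False, float_format="%.6f"
    )
    groups = linkage.group_markers(pairs, cfg.grouping_lod, anchors=anchors)
    log.info(
        "%s: %d linkage groups, %d unassigned markers",
        pop_id,
        groups.n_groups,
        len(groups.unassigned),
    )

    tables = []
    for label in sorted(groups.groups):
        members = groups.groups[label]
        rng = stage_rng(cfg.seed, f"order:{pop_id}:{label}")
        og = ordering.order_group(
            collapsed,
            pairs,
            members,
            group_name=label,
            n_seeds=cfg.n_seeds,
            min_spacing_cM=cfg.min_spacing_cM,
            order_lod=cfg.order_lod,
            epsilon=cfg.epsilon,
            bin_lod_threshold=cfg.grouping_lod,
            coseg_bins=bins,
            rng=rng,
        )
        t = og.table.copy()
        t.insert(1, "group", label)
        tables.append(t)
        if og.unplaced:
            log.info("%s %s: %d markers unplaced", pop_id, label, len(og.unplaced))
    table = pd.concat(tables, ignore_index=True)
    f2_map = GeneticMap(population_id=pop_id, table=table, population_size=size)
    write_map(f2_map, out / f"{pop_id}.map.f2scale.tsv")

    # F2-assumed -> true F3 scale, per group, as a post-processing step
    corrected = []
    for label in f2_map.groups:
        gt = f2_map.group_table(label).copy()
        gt["position_cM"] = f3model.correct_map_positions(
            gt["position_cM"].to_numpy()
        )
        corrected.append(gt)
    f3_map = GeneticMap(
        population_id=pop_id,
        table=pd.concat(corrected, ignore_index=True),
        population_size=size,
    )
    write_map(f3_map, out / f"{pop_id}.map.tsv")
    return f3_map, report


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns artifact paths and key results."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        return _run(cfg, out)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run(cfg: RunConfig, out: Path) -> dict:
    cfg.to_yaml(out / "config.yaml")
    log.info("favamap run, seed=%d", cfg.seed)

    anchors: dict[str, str] | None = None
    populations: dict[str, GenotypeMatrix] = {}
    sizes: dict[str, int] = dict(cfg.population_sizes)
    truths: dict[str, popsim.PopulationTruth] = {}

    if cfg.simulate:
        true_map = popsim.make_true_map(
            n_markers=cfg.n_markers,
            rng_seed=stage_seed(cfg.seed, "truemap"),
            distortion_region=cfg.distortion_region,
        )
        truth_table = true_map.to_table()
        truth_table.to_csv(out / "truth.map.tsv", sep="\t", index=False, float_format="%.6f")
        anchors = dict(zip(truth_table["marker_id"], truth_table["group"]))
        pd.DataFrame(
            {"marker_id": list(anchors), "chromosome_name": list(anchors.values())}
        ).to_csv(out / "anchors.tsv", sep="\t", index=False)
        for spec in cfg.populations:
            sc = popsim.SimConfig(
                population_size=spec.size,
                missing_rate=cfg.missing_rate,
                genotyping_error_rate=cfg.genotyping_error_rate,
                rng_seed=stage_seed(cfg.seed, f"sim:{spec.id}"),
                population_id=spec.id,
            )
            gm, truth = popsim.simulate_f3_population(true_map, sc)
            write_genotypes(gm, out / f"{spec.id}.geno.tsv")
            populations[spec.id] = gm
            sizes[spec.id] = spec.size
            truths[spec.id] = truth
            log.info("simulated %s: %d individuals, %d markers", spec.id, spec.size, gm.n_markers)
    else:
        for pop_id, path in cfg.genotype_files.items():
            gm = read_genotypes(path)
            populations[pop_id] = gm
            sizes.setdefault(pop_id, gm.n_individuals)
        if cfg.anchor_file:
            anchors = read_anchors(cfg.anchor_file)

    maps: list[GeneticMap] = []
    for pop_id, gm in populations.items():
        f3_map, _ = _map_one_population(
            pop_id, gm, cfg, anchors, out, sizes.get(pop_id)
        )
        maps.append(f3_map)
        cons.summarize_map(f3_map).to_csv(
            out / f"{pop_id}.summary.tsv", sep="\t", index=False, float_format="%.4f"
        )

    oriented = cons.orient_maps(maps, maps[0]) if len(maps) > 1 else maps
    scheme = cons.NeighborScheme(cfg.d_min, cfg.d_max, cfg.k_per_side)
    consensus_map = cons.build_consensus(oriented, sizes, scheme)
    consensus_map.table.to_csv(
        out / "consensus.map.tsv", sep="\t", index=False, float_format="%.6f"
    )
    cons_gm = consensus_map.as_genetic_map()
    cons.summarize_map(cons_gm).to_csv(
        out / "consensus.summary.tsv", sep="\t", index=False, float_format="%.4f"
    )

    comparisons = {}
    dot_rows = []
    for m in oriented:
        n_shared, rho_by_group, pooled, dotplot = cons.compare_maps(m, cons_gm)
        comparisons[f"{m.population_id}-consensus"] = {
            "n_shared": n_shared,
            "pooled_spearman": pooled,
            "by_group": rho_by_group,
        }
        dotplot.insert(0, "comparison", f"{m.population_id}-consensus")
        dot_rows.append(dotplot)
    for a in range(len(oriented)):
        for b in range(a + 1, len(oriented)):
            n_shared, rho_by_group, pooled, _ = cons.compare_maps(
                oriented[a], oriented[b]
            )
            comparisons[f"{oriented[a].population_id}-{oriented[b].population_id}"] = {
                "n_shared": n_shared,
                "pooled_spearman": pooled,
                "by_group": rho_by_group,
            }
    pd.concat(dot_rows, ignore_index=True).to_csv(
        out / "dotplot.tsv", sep="\t", index=False, float_format="%.6f"
    )
    diagnostics = {
        "I_D": consensus_map.index_I_D,
        "per_map_D": consensus_map.per_map_D,
        "comparisons": comparisons,
    }
    with open(out / "diagnostics.json", "w") as fhj:
        json.dump(diagnostics, fhj, indent=2, sort_keys=True)
    log.info("consensus: %d markers, I_D = %.3f", len(consensus_map.table), consensus_map.index_I_D)

    return {
        "out_dir": out,
        "maps": maps,
        "oriented_maps": oriented,
        "consensus": consensus_map,
        "diagnostics": diagnostics,
        "truths": truths,
    }
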