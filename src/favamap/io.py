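"""Containers and tab-delimited file formats shared across the pipeline.

Genotype calls are coded internally as small integers:

====  ==========================================================
code  meaning
====  ==========================================================
0     homozygote for the common (female) parent allele (``A``)
1     heterozygote (``H``)
2     homozygote for the other parent allele (``B``)
-1    missing (``-``)
====  ==========================================================

The genotype TSV has one header row (``marker_id``, optional ``group``, then
individual ids) and one row per marker with calls in ``{A, H, B, -}``.  Map
files are plain TSVs with one row per marker (``marker_id``, ``group``,
``position_cM`` and optionally ``tier``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CALL_CODES",
    "CODE_CALLS",
    "GenotypeMatrix",
    "GeneticMap",
    "read_genotypes",
    "write_genotypes",
    "read_map",
    "write_map",
    "read_anchors",
    "read_population_sizes",
]

CALL_CODES = {"A": 0, "H": 1, "B": 2, "-": -1}
CODE_CALLS = {v: k for k, v in CALL_CODES.items()}


@dataclass
class GenotypeMatrix:
    """Codominant genotype calls for one F3 population (markers x individuals)."""

    markers: list[str]
    individuals: list[str]
    calls: np.ndarray  # int8, shape (n_markers, n_individuals)
    group_hint: list[str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), len(self.individuals)):
            raise ValueError("calls shape does not match marker/individual ids")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker ids")
        bad = ~np.isin(self.calls, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def marker_index(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.markers)}

    def subset(self, marker_ids) -> "GenotypeMatrix":
        idx = self.marker_index()
        rows = [idx[m] for m in marker_ids]
        hint = [self.group_hint[i] for i in rows] if self.group_hint else None
        return GenotypeMatrix(
            markers=list(marker_ids),
            individuals=list(self.individuals),
            calls=self.calls[rows],
            group_hint=hint,
        )


@dataclass
class GeneticMap:
    """Ordered marker positions (cM) per linkage group for one population.

    ``table`` columns: ``marker_id``, ``group``, ``position_cM`` and, when the
    map came out of the ordering stage, ``tier`` in {scaffold, framework,
    binned}.  Positions are weakly increasing within each group.
    """

    population_id: str
    table: pd.DataFrame
    population_size: int | None = None

    def __post_init__(self) -> None:
        required = {"marker_id", "group", "position_cM"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"map table must have columns {sorted(required)}")
        if self.table["marker_id"].duplicated().any():
            raise ValueError("duplicate marker ids within a map")
        self.table = self.table.sort_values(
            ["group", "position_cM", "marker_id"], kind="stable"
        ).reset_index(drop=True)

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def group_table(self, group: str) -> pd.DataFrame:
        return self.table[self.table["group"] == group].reset_index(drop=True)

    def positions(self) -> pd.Series:
        return self.table.set_index("marker_id")["position_cM"]


# ---------------------------------------------------------------------------
# readers / writers


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("marker_id\tgroup\t" + "\t".join(gm.individuals) + "\n")
        hints = gm.group_hint or ["."] * gm.n_markers
        for m, hint, row in zip(gm.markers, hints, gm.calls):
            calls = "\t".join(CODE_CALLS[int(c)] for c in row)
            fh.write(f"{m}\t{hint or '.'}\t{calls}\n")


def read_genotypes(path) -> GenotypeMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "marker_id":
            raise ValueError(f"{path}: expected a header starting with 'marker_id'")
        has_group = len(header) > 1 and header[1] == "group"
        individuals = header[2:] if has_group else header[1:]
        markers: list[str] = []
        hints: list[str | None] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(f"{path}:{lineno}: wrong field count")
            markers.append(parts[0])
            calls = parts[2:] if has_group else parts[1:]
            hints.append(parts[1] if has_group and parts[1] != "." else None)
            try:
                rows.append([CALL_CODES[c] for c in calls])
            except KeyError as exc:
                raise ValueError(f"{path}:{lineno}: bad call {exc}") from None
    return GenotypeMatrix(
        markers=markers,
        individuals=individuals,
        calls=np.array(rows, dtype=np.int8),
        group_hint=hints if has_group and any(h for h in hints) else None,
    )


def write_map(gmap: GeneticMap, path) -> None:
    df = gmap.table.copy()
    df["position_cM"] = df["position_cM"].map(lambda x: f"{x:.6f}")
    df.to_csv(path, sep="\t", index=False)


def read_map(path, population_id: str | None = None, population_size: int | None = None) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "group": str})
    return GeneticMap(
        population_id=population_id or Path(path).stem,
        table=df,
        population_size=population_size,
    )


def read_anchors(path) -> dict[str, str]:
    """marker_id -> chromosome_name from a two-column anchor TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns[:2])
    return dict(zip(df[cols[0]], df[cols[1]]))


def read_population_sizes(path) -> dict[str, int]:
    """population_id -> size from a two-column TSV."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:2])
    return {str(k): int(v) for k, v in zip(df[cols[0]], df[cols[1]])}
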