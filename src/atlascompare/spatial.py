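"""Transcript-count gating of spatial cells into neuronal populations.

A cell belongs to a population when it carries at least ``min_count``
transcripts of the neuronal gate gene (RBFOX3 by default, excluding
non-neuronal cells) and of every applicable population marker.
Y-linked markers listed as male-only are skipped in female samples.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

COORD_COLUMNS = ("cell_id", "x", "y")


@dataclass
class GateSpec:
    """Gating rule for one neuronal population."""

    name: str
    marker_genes: list
    gate_gene: str = "RBFOX3"
    min_count: int = 3
    male_only_markers: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.marker_genes:
            raise ValueError(f"population {self.name!r}: marker_genes is empty")
        extra = set(self.male_only_markers) - set(self.marker_genes)
        if extra:
            raise ValueError(
                f"population {self.name!r}: male_only_markers not a subset of "
                f"marker_genes: {sorted(extra)}"
            )

    def applicable_markers(self, sex: str) -> list:
        if sex == "F":
            return [m for m in self.marker_genes if m not in self.male_only_markers]
        return list(self.marker_genes)


def read_spatial_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a transcript-count table; wide (gene columns) or long format auto-detected."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"cell_id", "gene", "count"}.issubset(cols):
        wide = df.pivot_table(index="cell_id", columns="gene", values="count",
                              aggfunc="sum", fill_value=0).reset_index()
        for c in ("x", "y"):
            if c in cols:
                coords = df.groupby("cell_id")[c].first()
                wide[c] = wide["cell_id"].map(coords)
        return wide
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicate cell id {dup!r}")
    return df


def gate_population(table: pd.DataFrame, spec: GateSpec, sex: str = "F") -> list:
    """Return the ids of cells passing the population gate, in table order.

    A cell passes iff its count is >= ``spec.min_count`` for the gate gene
    and for every applicable marker (male-only markers are skipped when
    ``sex == "F"``).
    """
    needed = [spec.gate_gene] + spec.applicable_markers(sex)
    missing = [g for g in needed if g not in table.columns]
    if missing:
        raise ValueError(f"marker column missing from table: {missing[0]!r}")
    mask = pd.Series(True, index=table.index)
    for g in needed:
        mask &= table[g] >= spec.min_count
    return table.loc[mask, "cell_id"].tolist()


def gate_population_bruteforce(table: pd.DataFrame, spec: GateSpec, sex: str = "F") -> list:
    """Per-cell loop oracle used to verify the vectorized gating in tests."""
    needed = [spec.gate_gene] + spec.applicable_markers(sex)
    out = []
    for _, row in table.iterrows():
        if all(row[g] >= spec.min_count for g in needed):
            out.append(row["cell_id"])
    return out


def export_selection(
    table: pd.DataFrame, selections: dict, path: str | os.PathLike
) -> pd.DataFrame:
    """Write gated coordinates as CSV: one row per (cell, population).

    Cells may satisfy multiple gates and then appear once per population.
    """
    coords = table.set_index("cell_id")[["x", "y"]]
    rows = []
    for pop, ids in selections.items():
        missing = [i for i in ids if i not in coords.index]
        if missing:
            raise ValueError(f"selection for {pop!r} references unknown cells: {missing[:3]}")
        for cid in ids:
            rows.append({"cell_id": cid, "x": coords.at[cid, "x"],
                         "y": coords.at[cid, "y"], "population": pop})
    out = pd.DataFrame(rows, columns=["cell_id", "x", "y", "population"])
    out.to_csv(path, index=False)
    return out


def load_gate_specs(path: str | os.PathLike) -> list[GateSpec]:
    """Load gate specs from YAML: a mapping of population name to fields."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = []
    for name, entry in raw.items():
        specs.append(
            GateSpec(
                name=name,
                marker_genes=list(entry["marker_genes"]),
                gate_gene=entry.get("gate_gene", "RBFOX3"),
                min_count=int(entry.get("min_count", 3)),
                male_only_markers=list(entry.get("male_only_markers", [])),
            )
        )
    return specs
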