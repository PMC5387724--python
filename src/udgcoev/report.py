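"""Tiering and export of co-evolving residue pairs, Circos-plot style.

Significant pairs are ranked by Z and split into the three colour tiers of
the circular co-evolution diagram: the top 5% of relationships ("top5",
drawn red), those between the 95th and 70th percentile ("mid", black), and
the remainder ("rest", gray).  Percentiles are computed over the
significant pairs only; a pair landing exactly on a tier boundary joins
the higher tier (ceiling rule), which keeps the partition deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from udgcoev.alignment import ColumnMap

TIERS = ("top5", "mid", "rest")


@dataclass(frozen=True)
class Edge:
    column_i: int
    column_j: int
    z: float
    tier: str
    ref_pos_i: Optional[int] = None
    ref_pos_j: Optional[int] = None
    ref_res_i: Optional[str] = None
    ref_res_j: Optional[str] = None


@dataclass
class EdgeList:
    """Tiered co-evolving pairs plus per-position annotations."""

    edges: list[Edge] = field(default_factory=list)
    conservation: Optional[np.ndarray] = None
    cmi: Optional[np.ndarray] = None
    column_map: Optional[ColumnMap] = None

    def __len__(self) -> int:
        return len(self.edges)

    def tier_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in TIERS}
        for e in self.edges:
            counts[e.tier] += 1
        return counts


def tier_edges(
    pairs: Sequence[tuple[int, int, float]],
    column_map: Optional[ColumnMap] = None,
    conservation: Optional[np.ndarray] = None,
    cmi: Optional[np.ndarray] = None,
) -> EdgeList:
    """Assign colour tiers to significant pairs by Z-rank percentile.

    ``pairs`` must already be sorted by descending Z (the output of
    ``significant_pairs``).  With n pairs, ranks 1..ceil(0.05 n) are
    "top5", ranks up to ceil(0.30 n) are "mid" (i.e. down to the 70th
    percentile), and the rest are "rest".
    """
    zs = [p[2] for p in pairs]
    if any(b > a for a, b in zip(zs, zs[1:])):
        raise ValueError("pairs must be sorted by descending Z")
    n = len(pairs)
    edges = []
    top5_end = math.ceil(0.05 * n)
    mid_end = math.ceil(0.30 * n)
    for rank, (i, j, z) in enumerate(pairs, start=1):
        if rank <= top5_end:
            tier = "top5"
        elif rank <= mid_end:
            tier = "mid"
        else:
            tier = "rest"
        kwargs = {}
        if column_map is not None:
            # i, j index the filtered alignment, i.e. positions in the
            # kept-column list of the map
            if i >= len(column_map.kept_columns) or j >= len(column_map.kept_columns):
                raise KeyError(f"edge column ({i}, {j}) missing from column map")
            kwargs = dict(
                ref_pos_i=column_map.ref_numbers[i],
                ref_pos_j=column_map.ref_numbers[j],
                ref_res_i=column_map.ref_residues[i],
                ref_res_j=column_map.ref_residues[j],
            )
        edges.append(Edge(i, j, z, tier, **kwargs))
    return EdgeList(
        edges=edges, conservation=conservation, cmi=cmi, column_map=column_map
    )


def export_report(
    edges: EdgeList, cmap: ColumnMap, out_dir: str | Path
) -> dict[str, Path]:
    """Write the tiered edge TSV and the per-position annotation TSV.

    Edge positions are reported in 1-based reference numbering (blank
    where the reference row is gapped).  Output is deterministic.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edges_path = out_dir / "edges.tsv"
    with open(edges_path, "w") as fh:
        fh.write(
            "ref_pos_i\tref_residue_i\tref_pos_j\tref_residue_j\tZ\ttier\t"
            "column_i\tcolumn_j\n"
        )
        for e in edges.edges:
            if e.column_i >= len(cmap.kept_columns) or e.column_j >= len(cmap.kept_columns):
                raise KeyError(
                    f"edge column ({e.column_i}, {e.column_j}) missing from column map"
                )
            pi, pj = cmap.ref_numbers[e.column_i], cmap.ref_numbers[e.column_j]
            ri, rj = cmap.ref_residues[e.column_i], cmap.ref_residues[e.column_j]
            fh.write(
                f"{'' if pi is None else pi}\t{'' if ri is None else ri}\t"
                f"{'' if pj is None else pj}\t{'' if rj is None else rj}\t"
                f"{e.z:.6f}\t{e.tier}\t{e.column_i}\t{e.column_j}\n"
            )
    ann_path = out_dir / "positions.tsv"
    with open(ann_path, "w") as fh:
        fh.write("alignment_column\tref_number\tref_residue\tconservation\tcMI\n")
        for k, col in enumerate(cmap.kept_columns):
            cons = "" if edges.conservation is None else f"{edges.conservation[k]:.6f}"
            cmi = "" if edges.cmi is None else f"{edges.cmi[k]:.6f}"
            num = cmap.ref_numbers[k]
            res = cmap.ref_residues[k]
            fh.write(
                f"{col}\t{'' if num is None else num}\t{'' if res is None else res}\t"
                f"{cons}\t{cmi}\n"
            )
    return {"edges": edges_path, "positions": ann_path}


def read_edges_tsv(path: str | Path) -> EdgeList:
    """Parse an exported edge TSV back into an :class:`EdgeList`."""
    edges = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("ref_pos_i"):
            raise ValueError(f"{path}: unexpected header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            edges.append(
                Edge(
                    column_i=int(f[6]),
                    column_j=int(f[7]),
                    z=float(f[4]),
                    tier=f[5],
                    ref_pos_i=int(f[0]) if f[0] else None,
                    ref_pos_j=int(f[2]) if f[2] else None,
                    ref_res_i=f[1] or None,
                    ref_res_j=f[3] or None,
                )
            )
    return EdgeList(edges=edges)
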