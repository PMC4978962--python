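"""Node/ROI bookkeeping for a six-region default-mode-network layout.

The DMN is represented by six regions of interest — precuneus (Pc),
posterior cingulate (PCC), anterior cingulate (ACC), frontal medial cortex
(FMC) and the two inferior parietal lobes (lIPL, rIPL) — each holding a
block of source-space nodes in a fixed canonical order.  The full-scale
layout carries 156 nodes (26 per ROI by default, overridable); a 24-node
desk-scale layout (4 per ROI) is the test default.

Node coordinates are synthetic: a 1-cm grid grown around per-ROI seed
points at typical MNI locations of these regions.  Coordinates feed only
reporting (motif centroids), never statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

ROI_LABELS = ("Pc", "PCC", "ACC", "FMC", "lIPL", "rIPL")

#: synthetic per-ROI seed coordinates (MNI mm) for grid placement
ROI_SEEDS = {
    "Pc": (5.0, -60.0, 38.0),
    "PCC": (0.0, -52.0, 26.0),
    "ACC": (1.0, 20.0, 25.0),
    "FMC": (-1.0, 43.0, -16.0),
    "lIPL": (-53.0, -47.0, 35.0),
    "rIPL": (54.0, -43.0, 33.0),
}


class AtlasError(KeyError):
    """Unknown ROI label or malformed layout."""


@dataclass(frozen=True)
class AtlasLayout:
    """Partition of nodes into ROIs plus per-node MNI coordinates.

    ``table`` columns: node_id, roi_label, x_mni, y_mni, z_mni.  Row order
    is the canonical node order used by every connectivity matrix.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"node_id", "roi_label", "x_mni", "y_mni", "z_mni"}
        if not required.issubset(self.table.columns):
            raise AtlasError(f"atlas table needs columns {sorted(required)}")
        if self.table["node_id"].duplicated().any():
            raise AtlasError("node ids must be globally unique")
        unknown = set(self.table["roi_label"]) - set(ROI_LABELS)
        if unknown:
            raise AtlasError(f"unknown ROI labels {sorted(unknown)}")

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def node_ids(self) -> list[str]:
        return list(self.table["node_id"])

    def roi_of(self, node_index: int) -> str:
        return self.table["roi_label"].iat[node_index]

    def roi_nodes(self, roi: str) -> list[int]:
        """Indices (canonical order) of the nodes belonging to one ROI."""
        if roi not in ROI_LABELS:
            raise AtlasError(f"unknown ROI label {roi!r}")
        mask = self.table["roi_label"] == roi
        return list(np.flatnonzero(mask.to_numpy()))

    def roi_sizes(self) -> dict[str, int]:
        return {roi: len(self.roi_nodes(roi)) for roi in ROI_LABELS}

    def coordinates(self) -> np.ndarray:
        return self.table[["x_mni", "y_mni", "z_mni"]].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AtlasLayout":
        return cls(pd.read_csv(path))


def _grid_offsets(count: int, spacing: float = 10.0) -> np.ndarray:
    """First ``count`` points of a cubic grid ordered by distance from origin."""
    r = 0
    while (2 * r + 1) ** 3 < count:
        r += 1
    pts = np.array(list(product(range(-r, r + 1), repeat=3)), dtype=float)
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], (pts**2).sum(axis=1)))
    return pts[order[:count]] * spacing


def default_atlas(
    nodes_per_roi: int | dict[str, int] = 26, spacing: float = 10.0
) -> AtlasLayout:
    """Synthetic DMN layout; ``nodes_per_roi=26`` gives the 156-node grid."""
    if isinstance(nodes_per_roi, int):
        counts = dict.fromkeys(ROI_LABELS, nodes_per_roi)
    else:
        counts = {roi: int(nodes_per_roi.get(roi, 0)) for roi in ROI_LABELS}
    rows = []
    for roi in ROI_LABELS:
        n = counts[roi]
        if n < 1:
            raise AtlasError(f"ROI {roi} needs at least one node")
        seed = np.asarray(ROI_SEEDS[roi])
        for k, offset in enumerate(_grid_offsets(n, spacing)):
            x, y, z = seed + offset
            rows.append(
                {
                    "node_id": f"{roi}_{k + 1:03d}",
                    "roi_label": roi,
                    "x_mni": x,
                    "y_mni": y,
                    "z_mni": z,
                }
            )
    return AtlasLayout(pd.DataFrame(rows))


def desk_atlas() -> AtlasLayout:
    """24-node (4 per ROI) layout used for fast simulation studies."""
    return default_atlas(nodes_per_roi=4)


def link_universe(
    atlas: AtlasLayout, roi_a: str, roi_b: str
) -> list[tuple[int, int]]:
    """All analysed node pairs for one ROI pair, in deterministic order.

    For distinct ROIs this is the full bipartite cross product; for
    ``roi_a == roi_b`` the within-ROI upper-triangle pairs.  Pairs are
    returned as (low index, high index) tuples in canonical node order.
    """
    nodes_a = atlas.roi_nodes(roi_a)
    nodes_b = atlas.roi_nodes(roi_b)
    if roi_a == roi_b:
        return [
            (nodes_a[i], nodes_a[j])
            for i in range(len(nodes_a))
            for j in range(i + 1, len(nodes_a))
        ]
    return [tuple(sorted((i, j))) for i in nodes_a for j in nodes_b]


def motif_centroid(
    motif_nodes, atlas: AtlasLayout
) -> dict[str, np.ndarray]:
    """Unweighted per-ROI mean MNI coordinate of a motif's member nodes."""
    nodes = sorted(set(motif_nodes))
    if not nodes:
        raise ValueError("motif node set is empty")
    coords = atlas.coordinates()
    out: dict[str, list[np.ndarray]] = {}
    for idx in nodes:
        if not 0 <= idx < atlas.n_nodes:
            raise AtlasError(f"node index {idx} outside atlas")
        out.setdefault(atlas.roi_of(idx), []).append(coords[idx])
    return {roi: np.mean(pts, axis=0) for roi, pts in out.items()}
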