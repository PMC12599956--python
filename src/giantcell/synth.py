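"""Synthetic labeled-tissue generation.

Space-filling tessellations are produced by a weighted-Voronoi (power-diagram)
construction: seed points carry radii drawn from a log-normal body with an
optional heavy-tail fraction, and every pixel is assigned to the seed
minimizing ``dist² − r²``.  Optional stomatal clusters (one small near-round
cell ringed by 3-6 small cells) and planted giant-cell patterns (random /
clustered / dispersed) give downstream stages realistic structure to test
against without any real data.
"""

from __future__ import annotations

import dataclasses
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from giantcell.errors import ConfigError
from giantcell.tissue import CellTable, LabeledTissue, build_adjacency


@dataclasses.dataclass
class SynthSpec:
    """Parameters of the synthetic tissue generator."""

    n_cells: int = 100
    shape: tuple[int, int] = (256, 256)  # (H, W) pixels
    pixel_size: float = 1.0
    area_sigma: float = 0.15         # log-normal shape of the radius body
    tail_fraction: float = 0.0       # fraction of seeds with inflated radii
    tail_scale: float = 10.0         # area multiplier for tail seeds
    anisotropy: float = 1.0          # >1 elongates cells along x
    n_stomata: int = 0               # number of stoma+ring clusters
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 4:
            raise ConfigError("n_cells must be >= 4")
        h, w = self.shape
        # require a few pixels per cell on average
        if h * w < 16 * (self.n_cells + 7 * self.n_stomata):
            raise ConfigError(
                f"raster {self.shape} too small for {self.n_cells} cells"
            )
        if not 0 <= self.tail_fraction < 1:
            raise ConfigError("tail_fraction must be in [0, 1)")


def _seed_points(spec: SynthSpec, rng: np.random.Generator):
    """Seed positions, squared-radius weights, and cell types."""
    h, w = spec.shape
    mean_area = h * w / (spec.n_cells + 7 * spec.n_stomata)
    base_r = np.sqrt(mean_area / np.pi)

    pts_list: list[np.ndarray] = []
    radii_list: list[float] = []
    types_list: list[str] = []

    # stomatal clusters first (one small round stoma + 3-6 small ring cells)
    # so pavement dart-throwing respects their footprint
    for _ in range(spec.n_stomata):
        center = rng.uniform([0.15 * h, 0.15 * w], [0.85 * h, 0.85 * w])
        stoma_r = 0.45 * base_r
        pts_list.append(center)
        radii_list.append(stoma_r)
        types_list.append("stoma")
        n_ring = int(rng.integers(3, 7))
        angles = rng.uniform(0, 2 * np.pi) + np.linspace(
            0, 2 * np.pi, n_ring, endpoint=False
        )
        for ang in angles:
            p = center + 1.0 * base_r * np.array([np.sin(ang), np.cos(ang)])
            pts_list.append(p)
            radii_list.append(0.4 * base_r)
            types_list.append("pavement")

    # dart-throwing with a soft minimum distance keeps the tessellation even
    n_placed = 0
    min_d = 0.85 * base_r
    while n_placed < spec.n_cells:
        cand = rng.uniform([0, 0], [h, w], size=(2,))
        if pts_list:
            d = np.sqrt(((np.array(pts_list) - cand) ** 2).sum(axis=1)).min()
            if d < min_d:
                min_d *= 0.995  # relax to guarantee termination
                continue
        pts_list.append(cand)
        radii_list.append(
            base_r * rng.lognormal(mean=0.0, sigma=spec.area_sigma)
        )
        types_list.append("pavement")
        n_placed += 1

    pts = np.array(pts_list)
    radii = np.array(radii_list)
    types = np.array(types_list, dtype=object)
    if spec.tail_fraction > 0:
        pavement_idx = np.flatnonzero(types == "pavement")
        n_tail = max(1, int(round(spec.tail_fraction * spec.n_cells)))
        tail_idx = rng.choice(pavement_idx, size=n_tail, replace=False)
        radii[tail_idx] *= np.sqrt(spec.tail_scale)
    return pts, radii**2, types


def generate_tissue(spec: SynthSpec) -> tuple[LabeledTissue, CellTable]:
    """Generate a space-filling synthetic tissue and a lightweight cell table.

    The table carries area, centroid, ``cell_type`` (known by construction)
    and ``is_border``; shape features are left NaN and can be filled in with
    :func:`giantcell.tissue.compute_features`.  Output is bit-reproducible
    from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    pts, weights, types = _seed_points(spec, rng)

    rr, cc = np.mgrid[0:h, 0:w]
    coords = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.float64)
    # anisotropy: compress x (columns) in the metric so cells elongate along x
    metric = np.array([1.0, 1.0 / spec.anisotropy])
    # power diagram via lifted coordinates: argmin |x-p|² − w  =
    # argmin (−2x·p + |p|² − w), a single matmul over all seeds
    xs = (coords * metric).astype(np.float32)
    ps = (pts * metric).astype(np.float32)
    score = xs @ (-2.0 * ps.T)
    score += (((ps**2).sum(axis=1) - weights)[None, :]).astype(np.float32)
    labels = (score.argmin(axis=1) + 1).astype(np.int32).reshape(h, w)

    # drop empty labels and relabel consecutively
    present = np.unique(labels)
    remap = np.zeros(int(present.max()) + 1, dtype=np.int32)
    remap[present] = np.arange(1, len(present) + 1)
    labels = remap[labels]
    tissue = LabeledTissue(labels, spec.pixel_size)

    areas = tissue.areas_um2()
    border = tissue.border_ids
    flat = labels.ravel()
    counts = np.bincount(flat)
    sum_r = np.bincount(flat, weights=rr.ravel())
    sum_c = np.bincount(flat, weights=cc.ravel())
    records = []
    for new_id, old in enumerate(present, start=1):
        records.append(
            dict(
                id=new_id,
                area_um2=areas[new_id],
                centroid_x=sum_c[new_id] / counts[new_id] * spec.pixel_size,
                centroid_y=sum_r[new_id] / counts[new_id] * spec.pixel_size,
                cell_type=types[old - 1],
                is_border=new_id in border,
            )
        )
    table = CellTable(pd.DataFrame.from_records(records), provenance=f"synth(seed={spec.seed})")
    return tissue, table


def plant_pattern(
    tissue: LabeledTissue,
    table: CellTable,
    mode: str,
    k: int,
    seed: int,
    area_floor: float = 0.0,
    boost: float = 10.0,
    graph: nx.Graph | None = None,
) -> set[int]:
    """Plant a giant-cell pattern among eligible pavement cells.

    mode='random' draws a uniform sample; 'clustered' samples sequentially
    with probability boosted by ``boost`` for cells adjacent to an already
    selected giant; 'dispersed' rejects candidates adjacent to selected
    giants while feasible.  Eligible cells are non-border pavement cells with
    area > ``area_floor``.  The giant flag is written into ``table``
    (cell_type = 'giant').
    """
    rng = np.random.default_rng(seed)
    frame = table.frame
    eligible = frame[
        (frame["cell_type"] == "pavement")
        & (frame["area_um2"] > area_floor)
        & (frame["is_border"] != True)  # noqa: E712  (may be NaN)
    ]["id"].tolist()
    if k > len(eligible):
        raise ConfigError(f"k={k} exceeds {len(eligible)} eligible cells")
    if k == 0:
        return set()

    if mode == "random":
        giants = set(int(i) for i in rng.choice(eligible, size=k, replace=False))
    elif mode in ("clustered", "dispersed"):
        if graph is None:
            graph = build_adjacency(tissue)
        giants: set[int] = set()
        pool = list(eligible)
        while len(giants) < k and pool:
            if mode == "clustered":
                adj = [
                    c for c in pool if any(nb in giants for nb in graph.neighbors(c))
                ]
                if giants and adj and np.isinf(boost):
                    choice = int(rng.choice(adj))
                else:
                    weights = np.array(
                        [boost if c in set(adj) else 1.0 for c in pool]
                    )
                    probs = weights / weights.sum()
                    choice = int(rng.choice(pool, p=probs))
            else:
                allowed = [
                    c for c in pool if not any(nb in giants for nb in graph.neighbors(c))
                ]
                if not allowed:
                    warnings.warn(
                        f"dispersed pattern infeasible beyond {len(giants)} giants; "
                        "returning partial pattern",
                        stacklevel=2,
                    )
                    break
                choice = int(rng.choice(allowed))
            giants.add(choice)
            pool.remove(choice)
    else:
        raise ConfigError(f"unknown pattern mode {mode!r}")

    table.frame.loc[table.frame["id"].isin(giants), "cell_type"] = "giant"
    return giants
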