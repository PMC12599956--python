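"""Shape-preserving tissue randomization (the spatial null model),
reconstructions, oversegmentation, and Cut-and-Merge random giant patterns.

The randomization engine rotates every non-fixed cell mask by a draw from the
orientation range, anchors it at a random position (placement order:
descending area; rejection sampling with a decaying overlap cap), and then
re-fills the remaining space by nearest-placed-pixel competition under a
distance transform.  Cell sizes are preserved tightly and shapes
approximately (more convex, noisier edges) — the documented artifact profile
of the image-based method this stands in for; the engine is isolated behind
this module so an alternative can be swapped in.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from giantcell.errors import ConfigError, PlacementError
from giantcell.tissue import LabeledTissue, build_adjacency

_UNASSIGNED = -1


@dataclasses.dataclass
class RandomizationSpec:
    """Parameters of the randomization null model.

    ``orientation_range=None`` draws rotations uniformly on (−π, π];
    a float r constrains draws to [−r, +r] (sepal mode: π/6).
    ``fix_background_as_cell`` keeps the background region fixed as a single
    pseudo-cell (whole-tissue mode for uncropped images);
    ``fix_border`` keeps cells touching the raster edge in place
    (cropped-image mode).
    """

    n_random: int = 400
    orientation_range: float | None = None
    fix_border: bool = True
    fix_background_as_cell: bool = False
    position_noise_max: float = 5.0  # µm, reconstruction mode
    seed: int = 0
    max_tries: int = 240

    def validate(self) -> None:
        if self.n_random < 1:
            raise ConfigError("n_random must be >= 1")
        if self.orientation_range is not None and not (
            0 < self.orientation_range <= math.pi
        ):
            raise ConfigError("orientation_range must lie in (0, pi]")


def _cell_masks(tissue: LabeledTissue) -> dict[int, tuple[tuple, np.ndarray]]:
    objects = ndimage.find_objects(tissue.labels)
    out = {}
    for cid in tissue.cell_ids:
        sl = objects[cid - 1]
        out[cid] = (sl, tissue.labels[sl] == cid)
    return out


def _rotated(mask: np.ndarray, angle_rad: float) -> np.ndarray:
    if abs(angle_rad) < 1e-9:
        return mask
    rot = ndimage.rotate(
        mask.astype(np.uint8), np.degrees(angle_rad), order=0, reshape=True
    ).astype(bool)
    if not rot.any():  # degenerate tiny mask; keep original
        return mask
    rows = np.flatnonzero(rot.any(axis=1))
    cols = np.flatnonzero(rot.any(axis=0))
    return rot[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def _place_cell(
    canvas: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    cid: int,
    max_tries: int,
    anchor_sampler=None,
) -> tuple[int, int]:
    """Paint ``mask`` onto free canvas pixels at a sampled anchor.

    Anchors come from ``anchor_sampler()`` when given (reconstruction mode:
    noisy draws around the original position), otherwise uniformly at random.
    Accepts the first anchor whose free-pixel fraction beats a decaying
    threshold; after ``max_tries`` the best-seen anchor is used.  Returns the
    accepted top-left anchor.  Raises :class:`PlacementError` when no anchor
    yields a single free pixel.
    """
    h, w = mask.shape
    H, W = canvas.shape
    if h > H or w > W:  # clip central crop for pathologically large masks
        mask = mask[:H, :W]
        h, w = mask.shape
    pts = np.argwhere(mask)
    if len(pts) > 64:  # free-fraction estimated from a pixel subsample
        pts = pts[np.linspace(0, len(pts) - 1, 64).astype(int)]
    if anchor_sampler is not None:
        anchors = np.array([anchor_sampler() for _ in range(max_tries)], dtype=int)
        anchors[:, 0] = np.clip(anchors[:, 0], 0, H - h)
        anchors[:, 1] = np.clip(anchors[:, 1], 0, W - w)
    else:
        anchors = np.stack(
            [rng.integers(0, H - h + 1, max_tries),
             rng.integers(0, W - w + 1, max_tries)], axis=1,
        )
    rows = anchors[:, 0][:, None] + pts[None, :, 0]
    cols = anchors[:, 1][:, None] + pts[None, :, 1]
    frac = (canvas[rows, cols] == _UNASSIGNED).mean(axis=1)
    # decaying acceptance threshold: first anchor beating it wins, else best
    thresh = np.full(max_tries, 0.3)
    thresh[:180] = 0.5
    thresh[:100] = 0.7
    thresh[:40] = 0.9
    ok = np.flatnonzero(frac >= thresh[: len(frac)])
    idx = int(ok[0]) if len(ok) else int(frac.argmax())
    r0, c0 = int(anchors[idx, 0]), int(anchors[idx, 1])
    window = canvas[r0 : r0 + h, c0 : c0 + w]
    paint = mask & (window == _UNASSIGNED)
    if not paint.any():
        raise PlacementError(f"could not place cell {cid}: no free pixels found")
    window[paint] = cid
    return r0, c0


def _compete_fill(canvas: np.ndarray, movable_ids: set[int]) -> None:
    """Assign every unassigned pixel to the nearest placed movable-cell pixel."""
    free = canvas == _UNASSIGNED
    if not free.any():
        return
    seeds = (canvas > 0) & np.isin(canvas, list(movable_ids))
    if not seeds.any():
        raise PlacementError("no placed cells to fill from")
    _, (ir, ic) = ndimage.distance_transform_edt(~seeds, return_indices=True)
    canvas[free] = canvas[ir[free], ic[free]]


def _randomize(
    tissue: LabeledTissue,
    spec: RandomizationSpec,
    k: int,
    reconstruction: bool = False,
) -> tuple[LabeledTissue, dict]:
    """Shared engine for randomizations and reconstructions.

    Returns the new tissue plus an info dict with the drawn rotation angle
    and anchor per movable cell ("engine: place-compete-v1").
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, k)))
    labels = tissue.labels
    H, W = labels.shape
    canvas = np.full((H, W), _UNASSIGNED, dtype=np.int32)

    fixed_ids: set[int] = set()
    if spec.fix_border and not spec.fix_background_as_cell:
        fixed_ids = set(tissue.border_ids)
    if spec.fix_background_as_cell:
        canvas[labels == 0] = 0
    masks = _cell_masks(tissue)
    for cid in fixed_ids:
        sl, mask = masks[cid]
        canvas[sl][mask] = cid

    movable = sorted(
        (cid for cid in tissue.cell_ids if cid not in fixed_ids),
        key=lambda c: -int(masks[c][1].sum()),
    )
    info: dict = {"engine": "place-compete-v1", "angles": {}, "anchors": {}}
    for cid in movable:
        sl, mask = masks[cid]
        if reconstruction:
            angle = 0.0
            noise_px = spec.position_noise_max / tissue.pixel_size
            r_orig, c_orig = sl[0].start, sl[1].start

            def anchor_sampler(r=r_orig, c=c_orig, n=noise_px):
                return (round(r + rng.uniform(-n, n)), round(c + rng.uniform(-n, n)))

        else:
            if spec.orientation_range is None:
                angle = float(rng.uniform(-math.pi, math.pi))
            else:
                angle = float(
                    rng.uniform(-spec.orientation_range, spec.orientation_range)
                )
            mask = _rotated(mask, angle)
            anchor_sampler = None
        placed = _place_cell(
            canvas, mask, rng, cid, spec.max_tries, anchor_sampler=anchor_sampler
        )
        info["angles"][cid] = angle
        info["anchors"][cid] = placed

    _compete_fill(canvas, set(movable))
    canvas[canvas == _UNASSIGNED] = 0  # only possible when nothing was movable
    out = LabeledTissue(canvas, tissue.pixel_size)
    if out.cell_ids != tissue.cell_ids:
        missing = tissue.cell_ids - out.cell_ids
        raise PlacementError(f"cells lost during randomization: {sorted(missing)[:5]}")
    return out, info


def randomize_tissue(
    tissue: LabeledTissue, spec: RandomizationSpec, k: int
) -> LabeledTissue:
    """Randomization k of the ensemble: positions and orientations shuffled,
    sizes/shapes approximately preserved, fixed cells untouched."""
    return _randomize(tissue, spec, k, reconstruction=False)[0]


def reconstruct_tissue(
    tissue: LabeledTissue, spec: RandomizationSpec, k: int = 0
) -> LabeledTissue:
    """Reconstruction: same engine, but each cell stays at its original
    position plus uniform noise of at most ±position_noise_max µm per axis,
    with orientation unchanged — reproduces the randomizations' shape-artifact
    class for fair comparison."""
    return _randomize(tissue, spec, k, reconstruction=True)[0]


def randomize_ensemble(
    tissue: LabeledTissue, spec: RandomizationSpec
) -> list[LabeledTissue]:
    """The full ensemble of ``spec.n_random`` randomizations."""
    return [randomize_tissue(tissue, spec, k) for k in range(spec.n_random)]


# ---------------------------------------------------------------------------
# Oversegmentation and Cut-and-Merge


def oversegment(
    tissue: LabeledTissue, fragment_radius: float, seed: int = 0
) -> tuple[LabeledTissue, dict[int, int]]:
    """Partition each cell into contiguous fragments of characteristic radius
    ≈ ``fragment_radius`` (Voronoi of a Poisson-disk-style sample inside the
    cell mask).  Cells smaller than one fragment are kept whole.

    Returns the fragment tissue and a map fragment id → parent cell id.
    """
    if fragment_radius <= tissue.pixel_size:
        raise ConfigError("fragment_radius must exceed the pixel size")
    rng = np.random.default_rng(seed)
    r_px = fragment_radius / tissue.pixel_size
    labels = tissue.labels
    out = np.zeros_like(labels, dtype=np.int32)
    parents: dict[int, int] = {}
    next_label = 1
    objects = ndimage.find_objects(labels)
    for cid in sorted(tissue.cell_ids):
        sl = objects[cid - 1]
        mask = labels[sl] == cid
        pix = np.argwhere(mask)
        target_frags = mask.sum() / (math.pi * r_px**2)
        if target_frags <= 1.5:
            out[sl][mask] = next_label
            parents[next_label] = cid
            next_label += 1
            continue
        order = rng.permutation(len(pix))
        centers: list[np.ndarray] = []
        for i in order:
            p = pix[i]
            # centers at least one fragment diameter apart so each fragment
            # has characteristic radius ~ r_px
            if not centers or np.min(
                ((np.array(centers) - p) ** 2).sum(axis=1)
            ) >= (2 * r_px) ** 2:
                centers.append(p)
        centers_arr = np.array(centers)
        d2 = ((pix[:, None, :] - centers_arr[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        frag_local = np.zeros(mask.shape, dtype=np.int32)
        frag_local[pix[:, 0], pix[:, 1]] = assign + 1
        # Euclidean Voronoi inside a non-convex mask can split a fragment;
        # relabel connected components so fragments stay contiguous
        for f in range(1, len(centers) + 1):
            comp, n_comp = ndimage.label(frag_local == f)
            for c in range(1, n_comp + 1):
                sel = comp == c
                out[sl][sel] = next_label
                parents[next_label] = cid
                next_label += 1
    return LabeledTissue(out, tissue.pixel_size), parents


def cut_and_merge(
    template: LabeledTissue,
    giant_areas: list[float],
    seed: int = 0,
    exclude: set[int] | None = None,
    max_retries: int = 100,
) -> tuple[LabeledTissue, set[int]]:
    """Random giant pattern by recursive fragment merging.

    Each target giant is seeded at a random unused fragment and merged with
    random neighboring fragments until its target area (µm²) is reached;
    giant count and sizes are preserved (realized area within one fragment of
    target).  ``exclude`` masks fragments (e.g. stomata) out of giants.
    """
    total_area = sum(template.areas_um2().values())
    if sum(giant_areas) >= total_area:
        raise ConfigError("sum of giant areas exceeds the tissue area")
    rng = np.random.default_rng(seed)
    graph = build_adjacency(template, connectivity=4, min_contact=1)
    frag_area = template.areas_um2()
    used: set[int] = set(exclude or ())
    realized: list[set[int]] = []
    for target in sorted(giant_areas, reverse=True):
        success = False
        for _ in range(max_retries):
            candidates = [f for f in graph.nodes if f not in used]
            if not candidates:
                break
            start = int(rng.choice(candidates))
            region = {start}
            area = frag_area[start]
            while area < target:
                frontier = sorted(
                    {
                        nb
                        for f in region
                        for nb in graph.neighbors(f)
                        if nb not in used and nb not in region
                    }
                )
                if not frontier:
                    break
                nxt = int(rng.choice(frontier))
                region.add(nxt)
                area += frag_area[nxt]
            if area >= target:
                realized.append(region)
                used |= region
                success = True
                break
        if not success:
            raise PlacementError(
                f"could not realize a giant of area {target} after {max_retries} retries"
            )
    labels = template.labels.copy()
    giant_ids: set[int] = set()
    next_label = int(labels.max()) + 1
    for region in realized:
        sel = np.isin(labels, list(region))
        labels[sel] = next_label
        giant_ids.add(next_label)
        next_label += 1
    return LabeledTissue(labels, template.pixel_size), giant_ids
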