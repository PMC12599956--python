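"""Cell-type assignment and the giant-cell size-threshold rule."""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from giantcell.errors import ConfigError, DegenerateInputError
from giantcell.tissue import CellTable


@dataclasses.dataclass(frozen=True)
class GiantThreshold:
    """Giant-cell area threshold derived from a pooled reference sample.

    The threshold is the mean of the nearest-rank percentile value (default
    99.3rd) in the sorted pooled sample and the next strictly larger value;
    cells with area strictly above it are giant.
    """

    value: float
    percentile: float
    reference: str = ""

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ConfigError("threshold must be positive")


def giant_size_threshold(
    pooled_reference_areas: Sequence[float],
    percentile: float = 99.3,
    reference: str = "",
) -> GiantThreshold:
    """Compute the giant-cell size threshold from pooled reference areas.

    Nearest-rank convention: the percentile value is the element at 1-based
    rank ``ceil(p/100 * n)`` of the sorted sample.  Raises
    :class:`DegenerateInputError` when the sample holds no value strictly
    above the percentile value.
    """
    areas = np.sort(np.asarray(pooled_reference_areas, dtype=float))
    n = len(areas)
    if n < 2:
        raise DegenerateInputError("need at least 2 reference areas")
    rank = int(np.ceil(percentile / 100.0 * n))
    rank = min(max(rank, 1), n)
    value = areas[rank - 1]
    above = areas[areas > value]
    if len(above) == 0:
        raise DegenerateInputError(
            f"percentile value {value} is the sample maximum; "
            "no value immediately above"
        )
    return GiantThreshold(
        value=float((value + above[0]) / 2.0),
        percentile=percentile,
        reference=reference or "nearest-rank on pooled sample",
    )


def rule_classifier(
    stoma_area_cap: float = 300.0, stoma_circularity_floor: float = 0.7
) -> Callable[[pd.DataFrame], pd.Series]:
    """Default transparent classifier: stoma iff small and near-circular."""

    def classify(frame: pd.DataFrame) -> pd.Series:
        is_stoma = (frame["area_um2"] < stoma_area_cap) & (
            frame["circularity"] > stoma_circularity_floor
        )
        return pd.Series(np.where(is_stoma, "stoma", "pavement"), index=frame.index)

    return classify


def passthrough_classifier() -> Callable[[pd.DataFrame], pd.Series]:
    """Keep pre-assigned cell types (e.g. from the synthetic generator);
    unlabeled cells become pavement."""

    def classify(frame: pd.DataFrame) -> pd.Series:
        types = frame["cell_type"].fillna("pavement").replace("giant", "pavement")
        return types

    return classify


def assign_types(
    table: CellTable,
    classifier: Callable[[pd.DataFrame], pd.Series] | None = None,
    threshold: GiantThreshold | None = None,
) -> CellTable:
    """Label cells pavement/stoma with a pluggable classifier and flag giants.

    ``classifier`` maps the feature frame to a Series of {'pavement',
    'stoma'}; the default is the transparent area/circularity rule.  When a
    ``threshold`` is given, pavement cells with area strictly above it get
    ``cell_type='giant'``; stomata are never giant.  Raises
    :class:`ConfigError` listing absent feature columns.
    """
    needed = ["area_um2"] + (["circularity"] if classifier is None else [])
    classifier = classifier or rule_classifier()
    frame = table.frame.copy()
    missing = [c for c in needed if frame[c].isna().all()]
    if missing:
        raise ConfigError(f"missing features required for classification: {missing}")
    frame["cell_type"] = classifier(frame).values
    if threshold is not None:
        giant = (frame["cell_type"] == "pavement") & (
            frame["area_um2"] > threshold.value
        )
        frame.loc[giant, "cell_type"] = "giant"
    return CellTable(frame, provenance=table.provenance)


def giant_ids(table: CellTable) -> set[int]:
    frame = table.frame
    return set(int(i) for i in frame.loc[frame["cell_type"] == "giant", "id"])


def select_population(
    table: CellTable,
    graph: nx.Graph | None,
    mode: str,
    target_total_area: float | None = None,
    area_floor: float = 0.0,
    seed: int = 0,
    mid_anchor: float = 5000.0,
) -> set[int]:
    """Select a pavement-cell population of roughly a target total area.

    mode='giant' returns the giant-flagged cells; 'mid' adds pavement cells
    ranked by |area − mid_anchor| until the total reaches the target; 'small'
    adds cells in ascending area; 'random' draws uniformly among pavement
    cells with area > ``area_floor``.  Greedy modes stop at the first set
    whose total area is ≥ target (overshoot allowed).
    """
    frame = table.frame
    if mode == "giant":
        return giant_ids(table)
    pavement = frame[
        frame["cell_type"].isin(["pavement", "giant"])
        & (frame["area_um2"] > area_floor)
    ]
    if pavement.empty:
        raise DegenerateInputError("no pavement cells available")
    if target_total_area is None:
        raise ConfigError(f"mode {mode!r} requires target_total_area")

    if mode == "mid":
        order = pavement.assign(rank=(pavement["area_um2"] - mid_anchor).abs())
        order = order.sort_values(["rank", "id"])
    elif mode == "small":
        order = pavement.sort_values(["area_um2", "id"])
    elif mode == "random":
        rng = np.random.default_rng(seed)
        order = pavement.iloc[rng.permutation(len(pavement))]
    else:
        raise ConfigError(f"unknown population mode {mode!r}")

    selected: set[int] = set()
    total = 0.0
    for _, row in order.iterrows():
        if total >= target_total_area:
            break
        selected.add(int(row["id"]))
        total += float(row["area_um2"])
    if total < target_total_area:
        raise ConfigError(
            f"target total area {target_total_area} unreachable; achieved {total}"
        )
    return selected
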