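"""Spatial observables on a selected cell population and the
randomization-based hypothesis test.

The central statistic is the number of same-population neighbors per cell
(e.g. giant-cell neighbors per giant cell).  Cells of the studied population
touching the image border are excluded as centers but still count as
neighbors of interior cells.  Observed statistics are tested one-sidedly
against the null distribution formed by the same statistic on randomized
tissues; ties count as extreme, and an observed value more extreme than every
null value is reported as the floor p < 1/n_random.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np

from giantcell.errors import ConfigError, UndefinedStatisticError


@dataclasses.dataclass
class NullTestResult:
    """Observed statistic, null sample, and p-value with floor reporting."""

    observed: float
    null_sample: np.ndarray
    p_value: float
    floored: bool
    n_random: int
    statistic: str = ""
    direction: str = "greater"
    excluded_border: int = 0

    @property
    def p_label(self) -> str:
        if self.floored:
            return f"< {1.0 / self.n_random:g}"
        return f"{self.p_value:g}"

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_sample": [float(v) for v in self.null_sample],
            "p_value": self.p_value,
            "p_label": self.p_label,
            "floored": self.floored,
            "n_random": self.n_random,
            "statistic": self.statistic,
            "direction": self.direction,
            "excluded_border": self.excluded_border,
        }


def giant_neighbor_stats(
    graph: nx.Graph, giants: Iterable[int], border_ids: Iterable[int]
) -> tuple[dict[int, int], float]:
    """Per-giant count of adjacent giants, and the mean over counted giants.

    Giants in ``border_ids`` are not counted as centers but still count as
    neighbors.  Raises :class:`UndefinedStatisticError` when no countable
    giant exists.
    """
    giants = set(giants)
    border = set(border_ids)
    missing = giants - set(graph.nodes)
    if missing:
        raise ConfigError(f"giants not in graph: {sorted(missing)[:5]}")
    counts = {
        g: sum(1 for nb in graph.neighbors(g) if nb in giants)
        for g in giants
        if g not in border
    }
    if not counts:
        raise UndefinedStatisticError("no countable (interior) giants")
    return counts, float(np.mean(list(counts.values())))


@dataclasses.dataclass
class ExtraObservables:
    min_shortest_path: dict[int, int]   # per interior giant; singletons excluded
    excluded_singletons: int
    fraction_in_contact: float
    cluster_sizes: list[int]


def extra_observables(
    graph: nx.Graph, giants: Iterable[int], border_ids: Iterable[int]
) -> ExtraObservables:
    """Minimum shortest path between giants, contact fraction, cluster sizes.

    min shortest path is in graph path length (1 = the pair is in contact);
    cluster sizes are the connected-component sizes of the giant-induced
    subgraph (all giants, including border ones).
    """
    giants = set(giants)
    border = set(border_ids)
    interior = [g for g in giants if g not in border]
    if not interior:
        raise UndefinedStatisticError("no countable (interior) giants")

    min_sp: dict[int, int] = {}
    excluded = 0
    others = giants
    for g in interior:
        if len(giants) < 2:
            excluded += 1
            continue
        lengths = nx.single_source_shortest_path_length(graph, g)
        best = min(
            (d for node, d in lengths.items() if node in others and node != g),
            default=None,
        )
        if best is None:
            excluded += 1
        else:
            min_sp[g] = best

    counts, _ = giant_neighbor_stats(graph, giants, border)
    fraction = float(np.mean([c >= 1 for c in counts.values()]))
    sub = graph.subgraph(giants)
    cluster_sizes = sorted((len(c) for c in nx.connected_components(sub)), reverse=True)
    return ExtraObservables(min_sp, excluded, fraction, cluster_sizes)


def null_test(
    observed: float,
    null_sample: Sequence[float],
    direction: str = "greater",
    statistic: str = "",
    excluded_border: int = 0,
) -> NullTestResult:
    """One-sided (or two-sided) Monte-Carlo test against a null sample.

    p = (# null values the same or more extreme) / n; ties are extreme.  If
    no null value is as extreme, the result is floored at p < 1/n.
    """
    null = np.asarray(null_sample, dtype=float)
    if null.size == 0:
        raise ConfigError("empty null sample")
    n = null.size
    if direction == "greater":
        extreme = int((null >= observed).sum())
    elif direction == "less":
        extreme = int((null <= observed).sum())
    elif direction == "two-sided":
        center = float(np.mean(null))
        extreme = int((np.abs(null - center) >= abs(observed - center)).sum())
    else:
        raise ConfigError(f"unknown direction {direction!r}")
    floored = extreme == 0
    p = (1.0 / n) if floored else extreme / n
    return NullTestResult(
        observed=float(observed),
        null_sample=null,
        p_value=p,
        floored=floored,
        n_random=n,
        statistic=statistic,
        direction=direction,
        excluded_border=excluded_border,
    )


def pooled_null_test(
    per_replicate_observed: Sequence[Sequence[float]],
    per_replicate_null: Sequence[Sequence[Sequence[float]]],
    direction: str = "greater",
    statistic_fn: Callable[[np.ndarray], float] = np.mean,
    statistic_name: str = "mean giant neighbors per giant",
) -> NullTestResult:
    """Pooled test across replicates, pairing randomization k by index.

    ``per_replicate_observed[r]`` holds the per-cell values of replicate r
    (e.g. giant-neighbor counts of its interior giants);
    ``per_replicate_null[r][k]`` holds the same values from randomization k
    of replicate r.  The observed statistic is computed on the union across
    replicates; null value k is the statistic on the union of randomization k
    of every replicate ("one random image per replicate"), giving exactly
    n_random null values.
    """
    n_rands = {len(nulls) for nulls in per_replicate_null}
    if len(n_rands) != 1:
        raise ConfigError(f"mismatched n_random across replicates: {sorted(n_rands)}")
    n_random = n_rands.pop()
    if n_random < 1:
        raise ConfigError("need at least one randomization per replicate")

    observed_pool = np.concatenate([np.asarray(v, float) for v in per_replicate_observed])
    if observed_pool.size == 0:
        raise UndefinedStatisticError("no countable cells in any replicate")
    observed = float(statistic_fn(observed_pool))
    null_values = np.empty(n_random)
    for k in range(n_random):
        pool = np.concatenate(
            [np.asarray(nulls[k], float) for nulls in per_replicate_null]
        )
        null_values[k] = statistic_fn(pool) if pool.size else np.nan
    if np.isnan(null_values).any():
        raise UndefinedStatisticError("a pooled randomization has no countable cells")
    return null_test(observed, null_values, direction, statistic=statistic_name)
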