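"""Orchestration: derived per-stage seeds, the clustering-test driver used by
both the CLI and the acceptance tooling, and the multi-stage pipeline runner.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from giantcell import __version__
from giantcell.errors import ConfigError
from giantcell.randomize import RandomizationSpec, randomize_tissue
from giantcell.spatial import NullTestResult, giant_neighbor_stats, pooled_null_test
from giantcell.tissue import LabeledTissue, build_adjacency


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed from hashing (global seed, stage name); adding stages
    never perturbs earlier stages' streams."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**63)


def neighbor_counts(
    tissue: LabeledTissue,
    population: set[int],
    connectivity: int = 4,
    min_contact: int = 2,
    graph: nx.Graph | None = None,
) -> list[int]:
    """Interior-population neighbor counts (the per-cell observable)."""
    if graph is None:
        graph = build_adjacency(tissue, connectivity, min_contact)
    counts, _ = giant_neighbor_stats(graph, population, tissue.border_ids)
    return list(counts.values())


def replicate_null_counts(
    tissue: LabeledTissue,
    population: set[int],
    spec: RandomizationSpec,
    connectivity: int = 4,
    min_contact: int = 2,
) -> tuple[list[int], list[list[int]]]:
    """Observed counts plus the counts in each of n_random randomizations."""
    observed = neighbor_counts(tissue, population, connectivity, min_contact)
    nulls = []
    for k in range(spec.n_random):
        rand = randomize_tissue(tissue, spec, k)
        nulls.append(neighbor_counts(rand, population, connectivity, min_contact))
    return observed, nulls


def clustering_test(
    replicates: Sequence[tuple[LabeledTissue, set[int]]],
    spec: RandomizationSpec,
    direction: str = "greater",
    connectivity: int = 4,
    min_contact: int = 2,
) -> NullTestResult:
    """Full pooled one-sided clustering test over replicate tissues."""
    per_obs, per_null = [], []
    for r, (tissue, population) in enumerate(replicates):
        rep_spec = RandomizationSpec(**{**spec.__dict__, "seed": spec.seed + 1000 * r})
        obs, nulls = replicate_null_counts(
            tissue, population, rep_spec, connectivity, min_contact
        )
        per_obs.append(obs)
        per_null.append(nulls)
    return pooled_null_test(per_obs, per_null, direction=direction)


# ---------------------------------------------------------------------------
# Pipeline runner


_KNOWN_STAGES = {"synth", "simulate", "classify", "randomize", "stats", "sizestats"}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_config(config: dict) -> None:
    """Schema validation before any stage runs; names the offending key."""
    if "stages" not in config or not isinstance(config["stages"], list):
        raise ConfigError("config requires a 'stages' list")
    if "seed" not in config:
        raise ConfigError("config requires a global 'seed'")
    produced: set[str] = set()
    for i, stage in enumerate(config["stages"]):
        if "name" not in stage:
            raise ConfigError(f"stage {i} missing 'name'")
        if stage["name"] not in _KNOWN_STAGES:
            raise ConfigError(f"unknown stage name {stage['name']!r}")
        for key in stage.get("inputs", []):
            if key not in produced and not Path(key).exists():
                raise ConfigError(
                    f"stage {stage['name']!r} input {key!r} neither exists "
                    "nor is produced by an earlier stage"
                )
        produced.update(stage.get("outputs", []))


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute stages in order and return the run manifest.

    The manifest records the package version, derived per-stage seeds, and
    SHA-256 hashes of every declared output; a stage failure marks the
    manifest as partial.
    """
    from giantcell import cli  # late import: stages reuse the CLI helpers

    validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config["seed"],
        "timestamp": time.time(),
        "stages": [],
        "complete": False,
    }
    try:
        for stage in config["stages"]:
            name = stage["name"]
            seed = stage_seed(config["seed"], name)
            params = dict(stage.get("params", {}))
            params.setdefault("seed", seed)
            cli.run_stage(name, params, outdir)
            entry = {"name": name, "seed": seed, "outputs": {}}
            for rel in stage.get("outputs", []):
                path = outdir / rel
                if path.exists():
                    entry["outputs"][rel] = _sha256(path)
            manifest["stages"].append(entry)
        manifest["complete"] = True
    finally:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
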