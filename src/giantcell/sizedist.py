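"""Cell-size distribution comparison: 1-D Wasserstein distances, permutation
tests, classical MDS (PCoA) embedding, per-replicate mean normalization, and
giant-cell density/area summaries with equal-variance t-tests."""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from giantcell.errors import ConfigError, DegenerateInputError


@dataclasses.dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ConfigError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ConfigError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ConfigError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ConfigError("distances must be nonnegative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def wasserstein_1d(a: Sequence[float], b: Sequence[float]) -> float:
    """1-Wasserstein distance between empirical distributions
    (integral of the absolute quantile difference)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise DegenerateInputError("empty sample")
    return float(stats.wasserstein_distance(a, b))


def wasserstein_test(
    a: Sequence[float], b: Sequence[float], n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Label-permutation test on the 1-Wasserstein distance.

    p = (1 + #{permuted ≥ observed}) / (n_perm + 1) (add-one smoothing).
    A degenerate pooled sample (all values equal) returns p = 1.
    """
    if n_perm < 99:
        raise ConfigError("n_perm must be >= 99")
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    observed = wasserstein_1d(a, b)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return observed, 1.0
    rng = np.random.default_rng(seed)
    n_a = a.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if stats.wasserstein_distance(perm[:n_a], perm[n_a:]) >= observed:
            count += 1
    return observed, (1 + count) / (n_perm + 1)


def distance_matrix(
    samples: Mapping[str, Sequence[float]]
) -> DistanceMatrix:
    """Pairwise 1-Wasserstein distances between named samples."""
    labels = list(samples)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = wasserstein_1d(samples[labels[i]], samples[labels[j]])
    return DistanceMatrix(labels, d)


def pcoa_embed(
    dmat: DistanceMatrix, dims: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Classical MDS: double-centered Gram eigen-decomposition.

    Returns (coordinates, eigenvalues, pairs) where ``pairs`` stacks input
    distances against embedded Euclidean distances for the linearity check.
    Sign convention: each coordinate's largest-magnitude loading is positive.
    Warns when large negative eigenvalues indicate a heavily non-Euclidean
    input.
    """
    D = dmat.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval.size and eigval[0] > 0 and (eigval < -1e-6 * eigval[0]).any():
        neg = eigval[eigval < 0]
        warnings.warn(
            f"distance matrix is non-Euclidean: negative eigenvalues {neg[:3]}",
            stacklevel=2,
        )
    coords = np.zeros((n, dims))
    for d in range(min(dims, n)):
        if eigval[d] > 0:
            coords[:, d] = eigvec[:, d] * np.sqrt(eigval[d])
            i_max = np.argmax(np.abs(coords[:, d]))
            if coords[i_max, d] < 0:
                coords[:, d] = -coords[:, d]
    iu = np.triu_indices(n, k=1)
    embedded = np.sqrt(((coords[iu[0]] - coords[iu[1]]) ** 2).sum(axis=1))
    pairs = np.stack([D[iu], embedded], axis=1)
    return coords, eigval, pairs


def normalize_by_mean(
    samples: Mapping[str, Sequence[float]]
) -> dict[str, np.ndarray]:
    """Divide every replicate by its own mean so each replicate has mean 1,
    leaving only the higher moments of the distributions to compare."""
    out = {}
    for name, values in samples.items():
        v = np.asarray(values, float)
        if v.size == 0:
            raise DegenerateInputError(f"empty sample {name!r}")
        m = v.mean()
        if m == 0:
            raise DegenerateInputError(f"zero mean in sample {name!r}")
        out[name] = v / m
    return out


def giant_density_and_area(
    giant_counts: Mapping[str, Sequence[float]],
    giant_areas: Mapping[str, Sequence[float]],
    segmented_areas: Mapping[str, Sequence[float]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Giant-cell density (per mm²), giant area fraction, and pairwise
    two-sample equal-variance two-tailed t-tests on density between groups.

    Inputs are keyed by group (genotype); each value is a per-replicate list:
    number of giants, summed giant area (µm²), and segmented area (µm²).
    """
    rows = []
    densities: dict[str, np.ndarray] = {}
    for group in giant_counts:
        counts = np.asarray(giant_counts[group], float)
        g_area = np.asarray(giant_areas[group], float)
        seg = np.asarray(segmented_areas[group], float)
        if not (len(counts) == len(g_area) == len(seg)):
            raise ConfigError(f"replicate lists for {group!r} differ in length")
        dens = counts / (seg / 1e6)  # µm² → mm²
        frac = g_area / seg
        densities[group] = dens
        for r, (d, f) in enumerate(zip(dens, frac)):
            rows.append(dict(group=group, replicate=r, density_per_mm2=d, area_fraction=f))
    summary = pd.DataFrame(rows)

    tests = []
    groups = list(giant_counts)
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = densities[groups[i]], densities[groups[j]]
            if len(a) < 2 or len(b) < 2:
                tests.append(
                    dict(group_a=groups[i], group_b=groups[j], t=np.nan, p=np.nan,
                         note="single replicate; test skipped")
                )
                continue
            t, p = stats.ttest_ind(a, b, equal_var=True)
            tests.append(dict(group_a=groups[i], group_b=groups[j], t=float(t), p=float(p), note=""))
    return summary, pd.DataFrame(tests)
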