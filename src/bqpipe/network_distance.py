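"""Network distance measures and pairwise distance matrices.

Four measures: unweighted Jaccard on node sets, weighted Jaccard and
(Adkins-normalized) Canberra on node-abundance vectors over the union
compound universe. PHYLIP lower-triangular export/import for tree building.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .metabolic_network import MetabolicNetwork, node_abundance_vector

__all__ = [
    "DistanceMatrix",
    "jaccard_distance",
    "weighted_jaccard",
    "canberra",
    "adkins_canberra",
    "distance_matrix",
    "write_phylip_lower",
    "read_phylip_lower",
    "MEASURES",
]


def jaccard_distance(I: set, J: set) -> float:
    """1 - |I∩J|/|I∪J|; two empty sets count as identical (distance 0)."""
    union = len(I | J)
    if union == 0:
        return 0.0
    return 1.0 - len(I & J) / union


def _check_vectors(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vector length mismatch: {x.shape} vs {y.shape}")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative entries are not allowed")
    return x, y


def weighted_jaccard(x: Sequence[float], y: Sequence[float]) -> float:
    """1 - Σmin(x_i,y_i)/Σmax(x_i,y_i); 0 for two all-zero vectors.

    Reduces to the unweighted Jaccard distance of the supports when x and y
    are 0/1 indicator vectors.
    """
    x, y = _check_vectors(np.asarray(x), np.asarray(y))
    denom = np.maximum(x, y).sum()
    if denom == 0:
        return 0.0
    return float(1.0 - np.minimum(x, y).sum() / denom)


def canberra(x: Sequence[float], y: Sequence[float]) -> float:
    """Σ |x_i-y_i| / (|x_i|+|y_i|), with 0/0 terms contributing 0."""
    x, y = _check_vectors(np.asarray(x), np.asarray(y))
    denom = np.abs(x) + np.abs(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, np.abs(x - y) / np.where(denom > 0, denom, 1), 0.0)
    return float(terms.sum())


def adkins_canberra(
    x: Sequence[float], y: Sequence[float], nz_mode: str = "either"
) -> float:
    """Canberra distance divided by the count NZ of active positions.

    ``nz_mode="either"`` (default) counts positions nonzero in x or y, making
    the result the mean of active Canberra terms, bounded in [0, 1].
    ``nz_mode="both"`` is the strict joint-nonzero reading. NZ = 0 returns 0
    with a warning.
    """
    xa, ya = _check_vectors(np.asarray(x), np.asarray(y))
    if nz_mode == "either":
        nz = int(((xa != 0) | (ya != 0)).sum())
    elif nz_mode == "both":
        nz = int(((xa != 0) & (ya != 0)).sum())
    else:
        raise ValueError(f"unknown nz_mode {nz_mode!r}")
    if nz == 0:
        warnings.warn("Adkins-Canberra with NZ=0 defined as 0", stacklevel=2)
        return 0.0
    return canberra(xa, ya) / nz


MEASURES = ("jaccard", "wjaccard", "canberra", "adcan")


@dataclass
class DistanceMatrix:
    """Labeled symmetric nonnegative matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be nonnegative")
        if not np.isfinite(self.values).all():
            raise ValueError("distances must be finite")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])


def distance_matrix(
    networks: Sequence[MetabolicNetwork],
    measure: str = "adcan",
    nz_mode: str = "either",
) -> DistanceMatrix:
    """Pairwise species distance matrix over a shared compound universe.

    The unweighted ``jaccard`` measure compares node sets; ``wjaccard``,
    ``canberra`` and ``adcan`` compare node-abundance vectors over the union
    universe of all input networks.
    """
    if len(networks) < 3:
        raise ValueError("need at least 3 networks (NJ requires >= 3 taxa)")
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    labels = [n.species for n in networks]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate species labels")
    universe = sorted(set().union(*(n.nodes for n in networks)))
    vectors = [node_abundance_vector(n, universe) for n in networks]
    n = len(networks)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if measure == "jaccard":
                d = jaccard_distance(networks[i].nodes, networks[j].nodes)
            elif measure == "wjaccard":
                d = weighted_jaccard(vectors[i], vectors[j])
            elif measure == "canberra":
                d = canberra(vectors[i], vectors[j])
            else:
                d = adkins_canberra(vectors[i], vectors[j], nz_mode=nz_mode)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(labels=labels, values=mat)


def _sanitize_label(label: str, relaxed: bool) -> str:
    clean = re.sub(r"[\s:;,()\[\]]", "_", label)
    return clean if relaxed else clean[:10]


def write_phylip_lower(
    matrix: DistanceMatrix, path: str | Path, relaxed: bool = False
) -> Path:
    """Write a PHYLIP lower-triangular distance file.

    Strict mode pads/truncates labels to 10 characters; ``relaxed`` keeps full
    labels separated from values by whitespace. Duplicate sanitized labels
    raise ValueError.
    """
    path = Path(path)
    names = [_sanitize_label(l, relaxed) for l in matrix.labels]
    if len(set(names)) != len(names):
        raise ValueError("duplicate species labels after PHYLIP sanitization")
    with path.open("w") as fh:
        fh.write(f"{len(names)}\n")
        for i, name in enumerate(names):
            field = name if relaxed else f"{name:<10}"
            vals = " ".join(f"{matrix.values[i, j]:.6f}" for j in range(i))
            fh.write(f"{field} {vals}".rstrip() + "\n")
    return path


def read_phylip_lower(path: str | Path) -> DistanceMatrix:
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    labels: list[str] = []
    mat = np.zeros((n, n))
    for i, line in enumerate(lines[1 : n + 1]):
        parts = line.split()
        labels.append(parts[0])
        for j, v in enumerate(parts[1 : i + 1]):
            mat[i, j] = mat[j, i] = float(v)
    return DistanceMatrix(labels=labels, values=mat)
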