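"""Binary band-pattern analytics: RAPD / mtDNA-RFLP fingerprints.

Gel band patterns scored as presence/absence vectors are compared with
standard binary similarity coefficients, clustered with UPGMA into an
ultrametric dendrogram, and counted into distinct-pattern classes (two
strains fall in one class iff their filtered band patterns are identical).
Band-size filtering implements rules like "bands larger than 1 kb".
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

COEFFICIENTS = ("jaccard", "dice", "simple_matching")


@dataclass
class BandMatrix:
    strain_ids: list[str]
    band_ids: list[str]
    presence: np.ndarray  # strains x bands, bool
    band_sizes: Optional[list[float]] = None  # bp, parallel to band_ids

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise ValueError("duplicate strain ids")
        if len(set(self.band_ids)) != len(self.band_ids):
            raise ValueError("duplicate band ids")
        if not self.strain_ids:
            raise ValueError("band matrix needs at least one strain")
        if self.presence.shape != (len(self.strain_ids), len(self.band_ids)):
            raise ValueError(
                f"presence shape {self.presence.shape} does not match "
                f"{len(self.strain_ids)} strains x {len(self.band_ids)} bands"
            )
        if self.band_sizes is not None and len(self.band_sizes) != len(self.band_ids):
            raise ValueError("band_sizes length does not match band_ids")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BandMatrix":
        """Build from a strains x bands 0/1 DataFrame.

        A row indexed ``size_bp`` (case-insensitive) is interpreted as the
        band-size header and removed from the strain rows.
        """
        sizes = None
        size_rows = [i for i in df.index if str(i).lower() in ("size_bp", "size", "bp")]
        if size_rows:
            sizes = [float(x) for x in df.loc[size_rows[0]]]
            df = df.drop(index=size_rows)
        return cls(
            strain_ids=[str(i) for i in df.index],
            band_ids=[str(c) for c in df.columns],
            presence=df.to_numpy(dtype=float).astype(bool),
            band_sizes=sizes,
        )

    @classmethod
    def read_csv(cls, path, sep: str = ",") -> "BandMatrix":
        return cls.from_frame(pd.read_csv(path, sep=sep, index_col=0))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.presence.astype(int), index=self.strain_ids, columns=self.band_ids
        )
        if self.band_sizes is not None:
            df = pd.concat(
                [pd.DataFrame([self.band_sizes], index=["size_bp"], columns=self.band_ids), df]
            )
        return df


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if np.any(np.isnan(v)) or np.any(v < 0):
            raise ValueError("distances must be nonnegative and finite")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class Dendrogram:
    tree: TreeNode
    newick: str
    leaf_ids: list[str]

    def leaf_depths(self) -> dict[str, float]:
        return {
            t.name: t.accumulate_to_ancestor(self.tree) for t in self.tree.tips()
        }


@dataclass
class PatternClasses:
    classes: list[list[str]]
    n_patterns: int
    undistinguishable_pairs: list[tuple[str, str]]


def filter_bands(matrix: BandMatrix, min_size_bp: float, strict: bool = True) -> BandMatrix:
    """Drop bands at or below ``min_size_bp`` (strictly-greater rule by default)."""
    if matrix.band_sizes is None:
        raise ValueError("band-size filtering requested but the matrix carries no sizes")
    if strict:
        keep = [i for i, s in enumerate(matrix.band_sizes) if s > min_size_bp]
    else:
        keep = [i for i, s in enumerate(matrix.band_sizes) if s >= min_size_bp]
    if not keep:
        warnings.warn("all bands removed by the size filter; empty band set")
    sub = matrix.presence[:, keep] if keep else np.zeros((len(matrix.strain_ids), 0), bool)
    empty = [sid for sid, row in zip(matrix.strain_ids, sub) if not row.any()]
    if empty and keep:
        warnings.warn(f"strains left with empty band patterns: {empty}")
    return BandMatrix(
        strain_ids=list(matrix.strain_ids),
        band_ids=[matrix.band_ids[i] for i in keep],
        presence=sub,
        band_sizes=[matrix.band_sizes[i] for i in keep],
    )


def band_distance(a: Sequence, b: Sequence, coefficient: str = "dice") -> float:
    """Distance = 1 - similarity under jaccard, dice or simple matching."""
    if coefficient not in COEFFICIENTS:
        raise ValueError(f"unknown coefficient {coefficient!r}; choose from {COEFFICIENTS}")
    x = np.asarray(a, dtype=bool)
    y = np.asarray(b, dtype=bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("band vectors must be one-dimensional and of equal length")
    both = int(np.sum(x & y))
    only_x = int(np.sum(x & ~y))
    only_y = int(np.sum(~x & y))
    neither = int(np.sum(~x & ~y))
    if coefficient == "simple_matching":
        sim = (both + neither) / x.size
    elif coefficient == "jaccard":
        union = both + only_x + only_y
        if union == 0:
            warnings.warn("jaccard distance of two all-zero patterns defined as 0")
            return 0.0
        sim = both / union
    else:  # dice
        denom = 2 * both + only_x + only_y
        if denom == 0:
            warnings.warn("dice distance of two all-zero patterns defined as 0")
            return 0.0
        sim = 2 * both / denom
    return 1.0 - sim


def distance_matrix(matrix: BandMatrix, coefficient: str = "dice") -> DistanceMatrix:
    n = len(matrix.strain_ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = band_distance(
                matrix.presence[i], matrix.presence[j], coefficient
            )
    return DistanceMatrix(ids=list(matrix.strain_ids), values=d)


def upgma(d: DistanceMatrix) -> Dendrogram:
    """Size-weighted average-linkage agglomeration into an ultrametric tree.

    Node height is half the merge distance (so cophenetic distance between
    two leaves equals the distance at which their clusters merged). Ties are
    broken by the lowest (row, column) index pair with ids ordered
    lexicographically at the start, making the dendrogram deterministic.
    """
    if len(d.ids) < 2:
        raise ValueError("UPGMA needs at least two ids")
    order = sorted(range(len(d.ids)), key=lambda i: d.ids[i])
    ids = [d.ids[i] for i in order]
    dist = d.values[np.ix_(order, order)].astype(float).copy()

    nodes = [TreeNode(name=name) for name in ids]
    heights = [0.0] * len(ids)
    sizes = [1] * len(ids)
    active = list(range(len(ids)))

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                val = dist[i, j]
                if best is None or val < best[0] - 1e-15:
                    best = (val, ai, aj)
        val, ai, aj = best
        i, j = active[ai], active[aj]
        h = val / 2.0
        left, right = nodes[i], nodes[j]
        left.length = h - heights[i]
        right.length = h - heights[j]
        parent = TreeNode(children=[left, right])
        # size-weighted (arithmetic-mean) update
        for k in active:
            if k in (i, j):
                continue
            dist[i, k] = dist[k, i] = (
                sizes[i] * dist[i, k] + sizes[j] * dist[j, k]
            ) / (sizes[i] + sizes[j])
        nodes[i] = parent
        heights[i] = h
        sizes[i] = sizes[i] + sizes[j]
        active.pop(aj)

    root = nodes[active[0]]
    root.length = None
    newick = str(root).strip()
    return Dendrogram(tree=root, newick=newick, leaf_ids=ids)


def distinct_patterns(matrix: BandMatrix) -> PatternClasses:
    """Group strains by bitwise-identical band patterns.

    Also reports every unordered pair of strains the fingerprint cannot
    differentiate (pairs within a class of size >= 2).
    """
    groups: dict[bytes, list[str]] = {}
    for sid, row in zip(matrix.strain_ids, matrix.presence):
        groups.setdefault(np.packbits(row).tobytes(), []).append(sid)
    classes = list(groups.values())
    pairs = [
        pair
        for cls in classes
        for pair in itertools.combinations(cls, 2)
    ]
    return PatternClasses(
        classes=classes, n_patterns=len(classes), undistinguishable_pairs=pairs
    )
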