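"""Pairwise Jaccard similarity over dominant binary markers.

The Jaccard coefficient for a pair of accessions is computed over the
markers scored (non-missing) in *both*: with ``a`` the count of shared band
presences and ``b``, ``c`` the counts present in only one of the two,

    J = a / (a + b + c)

Joint absences carry no information for dominant markers and never
contribute.  Missing calls are handled pairwise-complete: each pair is
scored on the markers it co-observes, and the co-observed count is exported
(``n_shared``) so low-overlap pairs can be filtered downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MarkerMatrix

__all__ = [
    "SimilarityMatrix",
    "GroupSimilarityStats",
    "DensityProfile",
    "jaccard",
    "pairwise_matrix",
    "group_stats",
    "density_profile",
    "write_similarity_matrix",
    "write_similarity_long",
]


@dataclass
class SimilarityMatrix:
    """Symmetric Jaccard matrix with per-pair co-observed marker counts.

    ``S`` holds values in [0, 1], NaN where a pair co-observes no
    informative (non-jointly-absent) marker.
    """

    S: pd.DataFrame
    n_shared: pd.DataFrame

    @property
    def accession_ids(self) -> list[str]:
        return list(self.S.index)

    def value(self, a: str, b: str) -> float:
        return float(self.S.at[a, b])

    def subset(self, ids: list[str]) -> "SimilarityMatrix":
        return SimilarityMatrix(self.S.loc[ids, ids], self.n_shared.loc[ids, ids])

    def pairs(self, lower: float = -np.inf, upper: float = np.inf) -> pd.DataFrame:
        """Long-form upper-triangle pairs with lower <= score < upper."""
        ids = self.accession_ids
        s = self.S.to_numpy()
        iu, ju = np.triu_indices(len(ids), k=1)
        vals = s[iu, ju]
        mask = np.isfinite(vals) & (vals >= lower) & (vals < upper)
        return pd.DataFrame({
            "acc_i": [ids[i] for i in iu[mask]],
            "acc_j": [ids[j] for j in ju[mask]],
            "score": vals[mask],
            "n_shared": self.n_shared.to_numpy()[iu[mask], ju[mask]],
        })


@dataclass
class GroupSimilarityStats:
    group: str
    n_members: int
    min_within: float
    max_within: float
    mean_within: float
    max_vs_nonmember: float  # NaN when the complement is empty


@dataclass
class DensityProfile:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    degenerate: bool = False


def jaccard(x, y) -> float:
    """Jaccard similarity of two 0/1/NaN call vectors, pairwise-complete.

    Returns NaN when no co-observed marker is informative (a+b+c = 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    both = ~np.isnan(x) & ~np.isnan(y)
    xs, ys = x[both], y[both]
    a = np.sum((xs == 1) & (ys == 1))
    bc = np.sum(xs != ys)
    denom = a + bc
    if denom == 0:
        return float("nan")
    return float(a / denom)


def pairwise_matrix(matrix: MarkerMatrix) -> SimilarityMatrix:
    """All-pairs Jaccard similarity of a marker matrix.

    Vectorized via matrix products: with P the (observed) presence
    indicator and O the observed indicator, the pairwise counts are
    a = P P', and the union a+b+c = P O' + O P' - a.
    """
    X = matrix.calls.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >=2 accessions")
    O = (~np.isnan(X)).astype(float)
    P = np.where(np.nan_to_num(X) == 1.0, 1.0, 0.0) * O
    a = P @ P.T
    union = P @ O.T + O @ P.T - a
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(union > 0, a / np.where(union > 0, union, 1.0), np.nan)
    n_shared = (O @ O.T).astype(int)
    ids = matrix.accession_ids
    return SimilarityMatrix(
        S=pd.DataFrame(S, index=ids, columns=ids),
        n_shared=pd.DataFrame(n_shared, index=ids, columns=ids),
    )


def group_stats(
    sim: SimilarityMatrix, groups: dict[str, str]
) -> list[GroupSimilarityStats]:
    """Within-group min/max/mean similarity and the maximum similarity of
    any member to any non-member (the clone-baseline table shape).

    Accessions absent from ``groups`` count as non-members.  Singleton
    groups report NaN within-group statistics.
    """
    ids = sim.accession_ids
    S = sim.S.to_numpy()
    idx = {a: i for i, a in enumerate(ids)}
    out = []
    for label in sorted(set(groups.values())):
        members = [a for a, g in groups.items() if g == label and a in idx]
        mi = [idx[a] for a in members]
        rest = [i for i in range(len(ids)) if i not in set(mi)]
        if len(mi) >= 2:
            block = S[np.ix_(mi, mi)]
            tri = block[np.triu_indices(len(mi), k=1)]
            tri = tri[np.isfinite(tri)]
            w_min, w_max, w_mean = (
                (float(tri.min()), float(tri.max()), float(tri.mean()))
                if tri.size else (np.nan, np.nan, np.nan)
            )
        else:
            w_min = w_max = w_mean = np.nan
        if rest and mi:
            cross = S[np.ix_(mi, rest)]
            cross = cross[np.isfinite(cross)]
            x_max = float(cross.max()) if cross.size else np.nan
        else:
            x_max = np.nan
        out.append(GroupSimilarityStats(
            group=label, n_members=len(mi), min_within=w_min,
            max_within=w_max, mean_within=w_mean, max_vs_nonmember=x_max,
        ))
    return out


def density_profile(
    values, bandwidth: float = 0.75, n_grid: int = 512
) -> DensityProfile:
    """Gaussian kernel density estimate with the bandwidth as the kernel SD.

    The grid spans [min - 3h, max + 3h] so the estimate integrates to 1
    (trapezoid rule) to within ~1e-3.  All-identical input yields a
    degenerate-distribution flag with the kernel centred on the point.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need >=2 finite values")
    h = float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    degenerate = bool(np.all(v == v[0]))
    grid = np.linspace(v.min() - 3 * h, v.max() + 3 * h, n_grid)
    z = (grid[None, :] - v[:, None]) / h
    dens = np.exp(-0.5 * z**2).mean(axis=0) / (h * np.sqrt(2 * np.pi))
    return DensityProfile(grid=grid, density=dens, bandwidth=h,
                          degenerate=degenerate)


def write_similarity_matrix(sim: SimilarityMatrix, path, decimals: int = 3) -> None:
    """Square CSV with accession header, values printed to 3 decimals."""
    sim.S.round(decimals).to_csv(path, index_label="accession")


def write_similarity_long(sim: SimilarityMatrix, path, decimals: int = 3) -> None:
    df = sim.pairs()
    df["score"] = df["score"].round(decimals)
    df.to_csv(path, index=False)
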