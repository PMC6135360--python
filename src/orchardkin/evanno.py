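"""Evanno-style delta-K and ln-probability plateau diagnostics.

Bayesian clustering runs report an estimated ln probability of the data
L(K) per replicate at each candidate cluster number K.  The delta-K
statistic is the mean absolute second-order rate of change of L across K,
divided by the replicate standard deviation at K:

    L''_r(K) = L_r(K+1) - 2 L_r(K) + L_r(K-1)
    dK(K)    = mean_r |L''_r(K)| / sd_r(L_r(K))

Peaks of dK suggest cluster numbers.  All local maxima are reported with
a prominence measure (peak value over the median dK), not only the
global one — secondary peaks can be informative.  The plateau diagnostic
operationalizes the visual "increases in K cease to change L meaningfully"
criterion with an explicit relative tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import StructureRunSummary

__all__ = ["DeltaKResult", "PlateauResult", "compute_delta_k", "plateau_k"]


@dataclass
class DeltaKResult:
    """Per-K diagnostics and the ranked delta-K peak list.

    ``table`` columns: K, n_replicates, mean_lnP, sd_lnP, lprime
    (mean first difference), mean_abs_lsecond, delta_k.  delta_k is NaN at
    the endpoints and wherever the replicate SD is zero or replicates are
    missing (those K are listed in ``flags``).
    """

    table: pd.DataFrame
    peaks: list[tuple[int, float, float]]  # (K, delta_k, prominence)
    flags: dict[int, str] = field(default_factory=dict)

    @property
    def best_k(self) -> int | None:
        return self.peaks[0][0] if self.peaks else None

    def delta_k(self, K: int) -> float:
        row = self.table.loc[self.table["K"] == K, "delta_k"]
        return float(row.iloc[0]) if len(row) else float("nan")


@dataclass
class PlateauResult:
    K: int | None
    rel_tol: float


def _pivot(runs: list[StructureRunSummary]) -> pd.DataFrame:
    if not runs:
        raise ValueError("no runs supplied")
    df = pd.DataFrame([(r.K, r.replicate, r.lnP) for r in runs],
                      columns=["K", "replicate", "lnP"])
    ks = sorted(df["K"].unique())
    if len(ks) < 3:
        raise ValueError("need runs spanning >=3 K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        missing = sorted(set(range(ks[0], ks[-1] + 1)) - set(ks))
        raise ValueError(f"K ladder has gaps at {missing}")
    return df.pivot(index="replicate", columns="K", values="lnP")


def compute_delta_k(runs: list[StructureRunSummary]) -> DeltaKResult:
    """Delta-K over a replicate ladder of clustering log-probabilities.

    Replicate labels are paired across K when every replicate covers every
    K; otherwise the curvature falls back to the second difference of the
    per-K means (flagged ``unpaired_replicates``).  Order of the input is
    irrelevant.
    """
    wide = _pivot(runs)
    ks = list(wide.columns)
    paired = not wide.isna().to_numpy().any()

    flags: dict[int, str] = {}
    rows = []
    for K in ks:
        col = wide[K].dropna()
        rows.append({
            "K": K,
            "n_replicates": int(col.size),
            "mean_lnP": float(col.mean()),
            "sd_lnP": float(col.std(ddof=1)) if col.size > 1 else np.nan,
        })
    table = pd.DataFrame(rows)
    means = table.set_index("K")["mean_lnP"]

    table["lprime"] = [
        float(means[K] - means[K - 1]) if K - 1 in means.index else np.nan
        for K in table["K"]
    ]

    mean_abs_l2, delta = [], []
    for i, K in enumerate(table["K"]):
        if i == 0 or i == len(ks) - 1:
            mean_abs_l2.append(np.nan)
            delta.append(np.nan)
            continue
        if paired:
            l2 = wide[K + 1] - 2 * wide[K] + wide[K - 1]
            m = float(l2.abs().mean())
        else:
            m = float(abs(means[K + 1] - 2 * means[K] + means[K - 1]))
            flags.setdefault(K, "unpaired_replicates")
        mean_abs_l2.append(m)
        sd = table.loc[i, "sd_lnP"]
        if not np.isfinite(sd):
            flags[K] = "single_replicate"
            delta.append(np.nan)
        elif sd == 0:
            flags[K] = "zero_sd"
            delta.append(np.nan)
        else:
            delta.append(m / sd)
    table["mean_abs_lsecond"] = mean_abs_l2
    table["delta_k"] = delta

    dk = table.set_index("K")["delta_k"].dropna()
    peaks = []
    if len(dk):
        med = float(dk.median())
        for K in dk.index:
            left = dk.get(K - 1, -np.inf) if K - 1 in dk.index else -np.inf
            right = dk.get(K + 1, -np.inf) if K + 1 in dk.index else -np.inf
            if dk[K] >= left and dk[K] >= right:
                prom = float(dk[K] / med) if med > 0 else np.inf
                peaks.append((int(K), float(dk[K]), prom))
        peaks.sort(key=lambda p: (-p[1], p[0]))
    return DeltaKResult(table=table, peaks=peaks, flags=flags)


def plateau_k(
    runs: list[StructureRunSummary], rel_tol: float = 0.01
) -> PlateauResult:
    """Smallest K at which the mean ln-probability stops changing
    meaningfully: (m(K+1) - m(K)) / |m(K+1) - m(1)| < rel_tol.

    Returns K=None when growth never levels off.
    """
    wide = _pivot(runs)
    means = wide.mean(axis=0)
    ks = list(means.index)
    k1 = means[ks[0]]
    for K in ks[:-1]:
        total = abs(means[K + 1] - k1)
        if total == 0:
            continue
        if (means[K + 1] - means[K]) / total < rel_tol:
            return PlateauResult(K=int(K), rel_tol=rel_tol)
    return PlateauResult(K=None, rel_tol=rel_tol)
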