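"""Post-processing of per-frame binding-energy tables.

The binding energies themselves come from upstream end-point calculations
(MM/GBSA); this module only subsamples frames, converts total energies to
ligand efficiency LE = dG / (1 + ln HAC), summarises per replica and pools
across replicas after flagging outlier replicas by a median +/- k*MAD rule
on the replica means.  Flags are always reported, never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, NrtrajError

ENERGY_TERMS = ("dg_total", "dg_lipo", "dg_coulomb", "dg_hbond")


@dataclass
class EnergyTable:
    """Per-frame dG decomposition with replica labels and the ligand's HAC.

    ``records`` is a DataFrame with columns frame, replica, dg_total,
    dg_lipo, dg_coulomb, dg_hbond; (replica, frame) pairs are unique.
    """

    records: pd.DataFrame
    hac: int = 1

    def __post_init__(self) -> None:
        if self.hac < 1:
            raise NrtrajError(f"hac must be >= 1, got {self.hac}")
        if self.records.duplicated(subset=["replica", "frame"]).any():
            raise NrtrajError("duplicate (replica, frame) keys in energy table")

    @property
    def replicas(self) -> list[int]:
        return sorted(int(r) for r in self.records["replica"].unique())


@dataclass
class EnergySummary:
    per_replica: pd.DataFrame        # one row per replica: mean/sd/n per term + LE
    pooled: pd.Series                # same statistics over retained replicas' frames
    flagged_replicas: list[dict] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        """Per-replica rows plus a 'pooled' row, for delimited-text export."""
        pooled = self.pooled.to_frame().T
        pooled.index = ["pooled"]
        return pd.concat([self.per_replica, pooled])


def subsample_frames(n_frames: int, stride: int = 10) -> list[int]:
    """End-anchored every-``stride``-th frame indices.

    Returns stride-1, 2*stride-1, ... below ``n_frames``: a 5000-frame
    stream at stride 10 gives exactly 500 indices, 10000 gives 1000.
    """
    if n_frames < 1 or stride < 1:
        raise ValueError("n_frames and stride must be positive")
    return list(range(stride - 1, n_frames, stride))


def ligand_efficiency(dg: float, hac: int) -> float:
    """Heavy-atom-normalised binding energy: dG / (1 + ln HAC), kcal/mol."""
    if hac < 1:
        raise ValueError(f"hac must be >= 1, got {hac}")
    return dg / (1.0 + math.log(hac))


def _mad_flags(means: pd.Series, k: float) -> list[dict]:
    med = means.median()
    mad = (means - med).abs().median()
    scale = 1.4826 * mad  # consistent with an SD under normality
    flags = []
    for rep, m in means.items():
        dev = abs(m - med)
        if (scale > 0 and dev > k * scale) or (scale == 0 and dev > 1e-9 * max(1.0, abs(med))):
            flags.append({"replica": int(rep), "mean": float(m),
                          "reason": f"|mean - median| = {dev:.3g} > {k} x MAD scale {scale:.3g}"})
    return flags


def summarize_energies(table: EnergyTable, subsample: bool = True,
                       stride: int = 10, outlier_k: float = 3.0) -> EnergySummary:
    """Per-replica and pooled statistics of LE and the energy terms.

    With ``subsample`` the every-``stride``-th-frame rule is applied within
    each replica (by frame order).  A replica is flagged when its mean LE
    deviates from the median of replica means by more than ``outlier_k``
    times the MAD-based scale of those means; pooled statistics cover only
    unflagged replicas.  SDs use the n-1 denominator over frames.
    """
    df = table.records.copy()
    if df.empty:
        raise DegenerateDataError("empty energy table")
    if subsample:
        parts = []
        for _rep, grp in df.groupby("replica", sort=True):
            grp = grp.sort_values("frame")
            keep = subsample_frames(len(grp), stride)
            parts.append(grp.iloc[keep])
        df = pd.concat(parts) if parts else df.iloc[:0]
        if df.empty:
            raise DegenerateDataError(
                f"subsampling at stride {stride} left no frames in any replica")
    df = df.assign(le=df["dg_total"] / (1.0 + math.log(table.hac)))

    cols = ["le", *ENERGY_TERMS]
    per_replica = df.groupby("replica")[cols].agg(["mean", "std", "count"])
    per_replica.columns = [f"{c}_{s}" if s != "count" else "n"
                           for c, s in per_replica.columns]
    per_replica = per_replica.loc[:, ~per_replica.columns.duplicated()]
    per_replica["n"] = df.groupby("replica").size()
    per_replica = per_replica.fillna({c: 0.0 for c in per_replica.columns
                                      if c.endswith("_std")})

    flags = _mad_flags(per_replica["le_mean"], outlier_k) if len(per_replica) > 1 else []
    flagged_ids = {f["replica"] for f in flags}
    retained = df[~df["replica"].isin(flagged_ids)]
    if retained.empty:
        raise DegenerateDataError("all replicas flagged as outliers")
    pooled = pd.Series(dtype=float)
    for c in cols:
        pooled[f"{c}_mean"] = retained[c].mean()
        pooled[f"{c}_std"] = retained[c].std(ddof=1) if len(retained) > 1 else 0.0
    pooled["n"] = float(len(retained))
    return EnergySummary(per_replica=per_replica, pooled=pooled, flagged_replicas=flags)
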