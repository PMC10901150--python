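"""Scoring of the RNAi cell-death screen.

Each siRNA's cell-death readout is standardized as ``z = (x - mu) / sigma``
against the population of all siRNA conditions sharing the same compound,
time point and death type; log2 fold changes against the scrambled control
quantify the direction of the effect; and genes are classified as
cytotoxicity-protective (death falls after knockdown) or -enhancing
(death rises) by a reproducible threshold rule, with Ward clustering of the
per-gene profiles available as an alternative mode.

sigma is the sample standard deviation (n-1 denominator) and the
population includes the control records; both choices are configurable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

CONTROLS = ("mock", "scrambled")
DEFAULT_Z_MIN = 1.0
DEFAULT_MIN_STRATA = 2
DEFAULT_EPS = 1e-3

_STRATUM = ["compound", "time_h", "death_type"]


def _aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """Mean cell-death value per (target, compound, time, death type)."""
    return (
        table.groupby(["target"] + _STRATUM, sort=True)["value"]
        .mean()
        .rename("value")
        .reset_index()
    )


def zscore_cell_death(
    table: pd.DataFrame,
    include_controls: bool = True,
    ddof: int = 1,
    aggregate_replicates: bool = True,
) -> pd.DataFrame:
    """z-score every siRNA within its (compound, time, death type) population.

    Replicates are averaged per siRNA first (each siRNA contributes one
    value to the population).  Populations with fewer than two members or
    zero spread yield missing z-scores and a warning.
    """
    agg = _aggregate(table) if aggregate_replicates else table.copy()
    out = []
    degenerate = []
    for stratum, grp in agg.groupby(_STRATUM, sort=True):
        pop = grp if include_controls else grp[~grp["target"].isin(CONTROLS)]
        x = pop["value"].to_numpy(float)
        if len(x) < 2 or x.std(ddof=ddof) == 0:
            degenerate.append(stratum)
            z = np.full(len(grp), np.nan)
        else:
            mu, sigma = x.mean(), x.std(ddof=ddof)
            z = (grp["value"].to_numpy(float) - mu) / sigma
        sub = grp.copy()
        sub["z"] = z
        out.append(sub)
    if degenerate:
        warnings.warn(f"populations with undefined z-scores: {degenerate[:5]}", stacklevel=2)
    return pd.concat(out, ignore_index=True)


def log2fc_vs_control(
    table: pd.DataFrame,
    control: str = "scrambled",
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame:
    """log2 ratio of each siRNA's mean death value to the scrambled control's.

    ``log2((mean target + eps) / (mean control + eps))`` per stratum; the
    epsilon guards zero readouts.
    """
    agg = _aggregate(table)
    ctrl = agg[agg["target"] == control].set_index(_STRATUM)["value"]
    rows = []
    for _, rec in agg[agg["target"] != control].iterrows():
        key = (rec["compound"], rec["time_h"], rec["death_type"])
        if key not in ctrl.index:
            raise ValueError(f"stratum without a {control} control: {key}")
        rows.append(
            {
                "target": rec["target"],
                "compound": rec["compound"],
                "time_h": rec["time_h"],
                "death_type": rec["death_type"],
                "log2fc": float(np.log2((rec["value"] + eps) / (ctrl[key] + eps))),
            }
        )
    return pd.DataFrame(rows)


def classify_hits(
    zscores: pd.DataFrame,
    z_min: float = DEFAULT_Z_MIN,
    k: int = DEFAULT_MIN_STRATA,
    mode: str = "threshold",
    exclude_compounds: tuple[str, ...] = (),
    vehicle: str | None = "DMSO",
) -> pd.DataFrame:
    """Classify each siRNA target as protective, enhancing, or none.

    Only challenge-compound strata enter the rule: the vehicle condition
    (``vehicle``, default DMSO) is a no-injury control whose z-scores are
    pure noise, so it is excluded alongside any ``exclude_compounds``.

    Threshold mode (default): a gene is protective when ``z <= -z_min`` in
    at least ``k`` strata, enhancing when ``z >= +z_min`` in at least ``k``;
    a gene meeting both rules is classed ``none`` with a conflict flag.
    Cluster mode cuts a Ward dendrogram of per-gene z profiles into two
    groups and labels them by the sign of their mean z; genes whose own
    mean |z| stays below ``z_min / 2`` remain ``none``.
    """
    z = zscores[~zscores["target"].isin(CONTROLS)].copy()
    drop = set(exclude_compounds) | ({vehicle} if vehicle else set())
    if drop:
        z = z[~z["compound"].isin(drop)]
    targets = sorted(z["target"].unique())
    n_strata = z.groupby("target").size()
    if len(n_strata) and k > int(n_strata.max()):
        warnings.warn(f"rule requires {k} strata but at most {int(n_strata.max())} are available",
                      stacklevel=2)

    if mode == "cluster":
        return _classify_by_clustering(z, z_min)
    if mode != "threshold":
        raise ValueError("mode must be 'threshold' or 'cluster'")

    rows = []
    for target in targets:
        zz = z.loc[z["target"] == target, "z"].to_numpy(float)
        valid = zz[~np.isnan(zz)]
        n_prot = int((valid <= -z_min).sum())
        n_enh = int((valid >= z_min).sum())
        is_prot = n_prot >= k
        is_enh = n_enh >= k
        if valid.size == 0:
            cls, conflict = "none", False
        elif is_prot and is_enh:
            cls, conflict = "none", True
        elif is_prot:
            cls, conflict = "protective", False
        elif is_enh:
            cls, conflict = "enhancing", False
        else:
            cls, conflict = "none", False
        rows.append(
            {
                "target": target,
                "class": cls,
                "n_protective_strata": n_prot,
                "n_enhancing_strata": n_enh,
                "conflict": conflict,
                "all_missing": valid.size == 0,
            }
        )
    return pd.DataFrame(rows)


def _classify_by_clustering(z: pd.DataFrame, z_min: float) -> pd.DataFrame:
    wide = z.pivot_table(index="target", columns=_STRATUM, values="z").fillna(0.0)
    if len(wide) < 2:
        return pd.DataFrame(
            {"target": wide.index, "class": "none", "n_protective_strata": 0,
             "n_enhancing_strata": 0, "conflict": False, "all_missing": False}
        )
    Z = hierarchy.linkage(wide.to_numpy(), method="ward")
    groups = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    means = {g: wide.to_numpy()[groups == g].mean() for g in np.unique(groups)}
    label_of = {g: ("protective" if means[g] < 0 else "enhancing") for g in means}
    rows = []
    for target, g in zip(wide.index, groups):
        own_mean = wide.loc[target].mean()
        cls = "none" if abs(own_mean) < z_min / 2 else label_of[g]
        rows.append(
            {"target": target, "class": cls, "n_protective_strata": int((wide.loc[target] <= -z_min).sum()),
             "n_enhancing_strata": int((wide.loc[target] >= z_min).sum()),
             "conflict": False, "all_missing": False}
        )
    return pd.DataFrame(rows)
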