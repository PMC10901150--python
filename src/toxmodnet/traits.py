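"""Module-eigengene vs cell-death correlation screening.

Aligns eigengene scores with cell-death fractions on shared (compound,
concentration) exposure conditions, computes per-compound Pearson
correlations for every death type and death measurement time, applies a
four-part module hit rule (correlation adjusted p < .1, r > 0.5, eigengene
score > 2 in at least one shared point, and strictly more than 4 DILI
compounds passing), and selects candidate genes within hit modules
(adjusted p < .1 and log2FC > 2 in at least one condition).

The screen pairs all transcriptomic time points of the eigengene with a
single death measurement time; the headline configuration uses death at
58 h, where early module activity correlates most strongly with outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import LogFCMatrix, StudyDesign, TraitScreenResult, validate_trait_table

DEFAULT_PADJ_MAX = 0.1
DEFAULT_MIN_R = 0.5
DEFAULT_MIN_EG = 2.0
DEFAULT_MIN_DILI_COMPOUNDS = 4  # strictly greater than
DEFAULT_GENE_PADJ_MAX = 0.1
DEFAULT_GENE_MIN_LFC = 2.0
DEFAULT_MIN_POINTS = 3


def align_conditions(
    egs: pd.DataFrame,
    trait: pd.DataFrame,
    design: StudyDesign,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair eigengene scores with death fractions on shared exposure conditions.

    ``egs`` is indexed by (compound, dose_level, time_h); the trait table
    keys conditions by (compound, concentration).  Returns a long paired
    table — one row per (module, compound, concentration, transcriptomic
    time, death time, death type) — plus a report of unmatched conditions.
    """
    if egs.empty or trait.empty:
        raise ValueError("both eigengene scores and trait table must be nonempty")
    validate_trait_table(trait)
    conc_of = design.concentration_of()
    eg_long = egs.stack().rename("eg").reset_index()
    eg_long.columns = ["compound", "dose_level", "time_h", "module", "eg"]
    eg_long["concentration"] = [
        conc_of.get((c, d), np.nan) for c, d in zip(eg_long["compound"], eg_long["dose_level"])
    ]
    eg_long = eg_long.dropna(subset=["concentration"])

    eg_keys = set(zip(eg_long["compound"], eg_long["concentration"]))
    trait_keys = set(zip(trait["compound"], trait["concentration"]))
    shared = eg_keys & trait_keys
    unmatched = pd.DataFrame(
        [{"compound": c, "concentration": x, "present_in": "eigengenes"}
         for c, x in sorted(eg_keys - trait_keys)]
        + [{"compound": c, "concentration": x, "present_in": "trait"}
           for c, x in sorted(trait_keys - eg_keys)]
    )
    if not shared:
        raise ValueError(
            f"no shared (compound, concentration) conditions; {len(unmatched)} unmatched"
        )
    paired = eg_long.merge(
        trait[["compound", "concentration", "death_time_h", "death_type", "fraction"]],
        on=["compound", "concentration"],
        how="inner",
    )
    paired = paired.rename(columns={"time_h": "tx_time_h", "fraction": "death_frac"})
    return paired, unmatched


def correlate_modules_death(
    paired: pd.DataFrame,
    min_points: int = DEFAULT_MIN_POINTS,
    padj_family: str = "per_death_stratum",
) -> pd.DataFrame:
    """Pearson r/p per (module, compound, death type, death time).

    Each correlation pools the shared concentration points across all
    transcriptomic time points.  Records with fewer than ``min_points``
    pairs or zero variance on either axis are skipped (noted in the
    ``skipped`` column of the returned frame is absent — they simply do not
    appear).  BH adjustment runs within each (death_type, death_time_h)
    family by default, or globally with ``padj_family="global"``.
    """
    rows = []
    for (module, compound, dtype, dtime), grp in paired.groupby(
        ["module", "compound", "death_type", "death_time_h"], sort=True
    ):
        x = grp["eg"].to_numpy(float)
        y = grp["death_frac"].to_numpy(float)
        if len(x) < min_points or x.std() == 0 or y.std() == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r, p = stats.pearsonr(x, y)
        if not (np.isfinite(r) and np.isfinite(p)):
            continue
        rows.append(
            {
                "module": module,
                "compound": compound,
                "death_type": dtype,
                "death_time_h": dtime,
                "r": float(r),
                "p": float(p),
                "n": len(x),
            }
        )
    records = pd.DataFrame(rows)
    if records.empty:
        records["padj"] = pd.Series(dtype=float)
        return records
    if padj_family == "global":
        records["padj"] = multipletests(records["p"].to_numpy(), method="fdr_bh")[1]
    else:
        records["padj"] = np.nan
        for _, idx in records.groupby(["death_type", "death_time_h"]).groups.items():
            records.loc[idx, "padj"] = multipletests(
                records.loc[idx, "p"].to_numpy(), method="fdr_bh"
            )[1]
    return records


@dataclass
class HitCriteria:
    """The four-part module hit rule."""

    padj_max: float = DEFAULT_PADJ_MAX
    min_r: float = DEFAULT_MIN_R
    min_eg: float = DEFAULT_MIN_EG
    min_dili_compounds: int = DEFAULT_MIN_DILI_COMPOUNDS  # strict >
    eg_absolute: bool = False


def select_hit_modules(
    records: pd.DataFrame,
    paired: pd.DataFrame,
    compound_categories: Mapping[str, str],
    criteria: HitCriteria | None = None,
) -> TraitScreenResult:
    """Apply the four-part hit rule per death type.

    A (module, compound) pair passes when its correlation record has
    ``padj < padj_max`` and ``r > min_r`` and the module's eigengene score
    exceeds ``min_eg`` in at least one shared data point for that compound.
    A module is a hit for a death type when the number of distinct passing
    DILI-category compounds is strictly greater than ``min_dili_compounds``.
    """
    criteria = criteria or HitCriteria()
    eg_col = paired["eg"].abs() if criteria.eg_absolute else paired["eg"]
    max_eg = eg_col.groupby([paired["module"], paired["compound"]]).max()

    hits: dict[str, set[int]] = {}
    support_rows = []
    if not records.empty:
        passing = records[
            (records["padj"] < criteria.padj_max) & (records["r"] > criteria.min_r)
        ].copy()
        eg_ok = np.array(
            [
                max_eg.get((m, c), -np.inf) > criteria.min_eg
                for m, c in zip(passing["module"], passing["compound"])
            ],
            dtype=bool,
        )
        passing = passing.loc[eg_ok]
        dili_ok = np.array(
            [compound_categories.get(c) == "DILI" for c in passing["compound"]], dtype=bool
        )
        passing = passing.loc[dili_ok]
        for (module, dtype), grp in passing.groupby(["module", "death_type"]):
            compounds = sorted(grp["compound"].unique())
            if len(compounds) > criteria.min_dili_compounds:
                hits.setdefault(dtype, set()).add(module)
                support_rows.append(
                    {
                        "module": module,
                        "death_type": dtype,
                        "n_passing_dili": len(compounds),
                        "compounds": ",".join(compounds),
                    }
                )
    support = pd.DataFrame(
        support_rows, columns=["module", "death_type", "n_passing_dili", "compounds"]
    )
    return TraitScreenResult(records=records, hits=hits, support=support)


def select_candidate_genes(
    hit_modules: set[int],
    assignment: pd.Series,
    logfc: LogFCMatrix,
    padj_max: float = DEFAULT_GENE_PADJ_MAX,
    min_lfc: float = DEFAULT_GENE_MIN_LFC,
) -> pd.DataFrame:
    """Genes of hit modules upregulated with padj < .1 and log2FC > 2 somewhere.

    Both thresholds must hold in the same condition (strict inequalities).
    """
    if not hit_modules:
        raise ValueError("hit module set is empty")
    member = assignment[assignment.isin(hit_modules)]
    genes = [g for g in member.index if g in set(logfc.values.columns)]
    rows = []
    for g in genes:
        v = logfc.values[g].to_numpy(float)
        p = logfc.padj[g].to_numpy(float)
        mask = (p < padj_max) & (v > min_lfc)
        if mask.any():
            rows.append(
                {
                    "gene": g,
                    "module": int(member[g]),
                    "max_log2fc": float(v[mask].max()),
                    "min_padj": float(p[mask].min()),
                    "n_passing_conditions": int(mask.sum()),
                }
            )
    return pd.DataFrame(
        rows, columns=["gene", "module", "max_log2fc", "min_padj", "n_passing_conditions"]
    )
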