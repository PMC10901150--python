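"""Core in-memory containers shared across pipeline stages.

The pipeline moves through a small set of tabular objects: raw counts with
their experimental design, a condition x gene log2 fold-change matrix with
matched adjusted p-values, a module set (gene assignments plus eigengene
scores), and result tables for preservation, trait association and the RNAi
screen.  All of them wrap plain :class:`pandas.DataFrame` objects so they
serialize to TSV without loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

#: Compound categories used throughout the package.
CATEGORIES = ("DILI", "stress_reference", "cytokine_growth_factor", "negative", "vehicle")

#: Names of the columns that identify a treated experimental condition.
CONDITION_NAMES = ("compound", "dose_level", "time_h")

DESIGN_COLUMNS = (
    "sample_id",
    "compound",
    "category",
    "severity",
    "dose_level",
    "concentration",
    "conc_unit",
    "time_h",
    "replicate",
    "batch",
    "vehicle_of",
)


@dataclass
class StudyDesign:
    """Sample-level metadata for a dose/time-course toxicogenomics experiment.

    ``samples`` has one row per sequenced sample with the columns in
    :data:`DESIGN_COLUMNS`.  Vehicle (solvent-control) samples carry
    ``category == "vehicle"``, ``dose_level == 0`` and an empty
    ``vehicle_of``; every treated sample names the vehicle compound it is
    contrasted against, which must be present in the same batch and time
    point.
    """

    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"design is missing columns: {missing}")
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples.loc[self.samples["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(dup)[:5]}")
        bad_cat = set(self.samples["category"]) - set(CATEGORIES)
        if bad_cat:
            raise ValueError(f"unknown compound categories: {sorted(bad_cat)}")
        self.samples = self.samples.reset_index(drop=True)
        self._check_vehicle_matching()
        self._check_dose_ordering()

    # -- invariants ------------------------------------------------------

    def _check_vehicle_matching(self) -> None:
        veh = self.vehicles
        available = set(zip(veh["compound"], veh["time_h"], veh["batch"]))
        treated = self.treated
        keys = set(zip(treated["vehicle_of"], treated["time_h"], treated["batch"]))
        orphans = keys - available
        if orphans:
            raise ValueError(
                "treated samples without a matched vehicle in the same "
                f"batch/time point: {sorted(orphans)[:5]}"
            )

    def _check_dose_ordering(self) -> None:
        for compound, grp in self.treated.groupby("compound"):
            per_dose = grp.groupby("dose_level")["concentration"].agg(["min", "max"])
            if (per_dose["min"] != per_dose["max"]).any():
                raise ValueError(f"{compound}: inconsistent concentration within a dose level")
            conc = per_dose["min"].sort_index()
            if not conc.is_monotonic_increasing or conc.duplicated().any():
                raise ValueError(f"{compound}: dose levels not strictly ordered by concentration")

    # -- views -----------------------------------------------------------

    @property
    def treated(self) -> pd.DataFrame:
        return self.samples[self.samples["category"] != "vehicle"]

    @property
    def vehicles(self) -> pd.DataFrame:
        return self.samples[self.samples["category"] == "vehicle"]

    @property
    def compounds(self) -> list[str]:
        return sorted(self.treated["compound"].unique())

    def condition_index(self) -> pd.MultiIndex:
        """MultiIndex of the distinct treated (compound, dose_level, time_h)."""
        cells = (
            self.treated[list(CONDITION_NAMES)]
            .drop_duplicates()
            .sort_values(list(CONDITION_NAMES))
        )
        return pd.MultiIndex.from_frame(cells)

    def category_of(self) -> dict[str, str]:
        return dict(zip(self.samples["compound"], self.samples["category"]))

    def concentration_of(self) -> dict[tuple[str, int], float]:
        t = self.treated
        return dict(zip(zip(t["compound"], t["dose_level"]), t["concentration"]))

    def subset(self, sample_ids) -> "StudyDesign":
        keep = self.samples[self.samples["sample_id"].isin(set(sample_ids))]
        return StudyDesign(keep.copy())

    # -- serialization ---------------------------------------------------

    def to_tsv(self, path=None) -> str | None:
        return self.samples.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "StudyDesign":
        df = pd.read_csv(path, sep="\t")
        df["vehicle_of"] = df["vehicle_of"].fillna("")
        df["severity"] = df["severity"].astype("Int64")
        return cls(df)


@dataclass
class CountMatrix:
    """Raw probe/gene counts (rows) per sample (columns), plus the design.

    ``truth`` optionally carries generator ground truth (planted module
    labels, corrupted samples, true module activations) so downstream
    filters can be checked against an oracle.
    """

    values: pd.DataFrame
    design: StudyDesign
    truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("probe ids must be unique")
        known = set(self.design.samples["sample_id"])
        unknown = [s for s in self.values.columns if s not in known]
        if unknown:
            raise ValueError(f"samples absent from design: {unknown[:5]}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def library_sizes(self) -> pd.Series:
        return self.values.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        # the design (study description) is kept whole; only columns shrink
        cols = [s for s in self.values.columns if s in set(sample_ids)]
        return CountMatrix(self.values[cols], self.design, self.truth)


@dataclass
class LogFCMatrix:
    """Condition x gene log2 fold changes with aligned adjusted p-values.

    Rows are indexed by the (compound, dose_level, time_h) MultiIndex;
    ``n_replicates`` records how many treated replicates entered each
    condition's contrast.
    """

    values: pd.DataFrame
    padj: pd.DataFrame
    n_replicates: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.shape != self.padj.shape:
            raise ValueError("values and padj must have identical dimensions")
        if not self.values.index.equals(self.padj.index) or not self.values.columns.equals(
            self.padj.columns
        ):
            raise ValueError("values and padj must share index and columns")
        vals = self.values.to_numpy()
        if not np.isfinite(vals[~np.isnan(vals)]).all():
            raise ValueError("log2FC values must be finite")
        p = self.padj.to_numpy()
        ok = np.isnan(p) | ((p >= 0) & (p <= 1))
        if not ok.all():
            raise ValueError("adjusted p-values must lie in [0, 1]")

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> pd.MultiIndex:
        return self.values.index

    def subset_genes(self, genes) -> "LogFCMatrix":
        genes = [g for g in self.values.columns if g in set(genes)]
        return LogFCMatrix(self.values[genes], self.padj[genes], self.n_replicates)


@dataclass
class DEGTable:
    """Per-condition sets of up/down differentially expressed genes."""

    up: dict[tuple, frozenset]
    down: dict[tuple, frozenset]

    def __post_init__(self) -> None:
        for cond in self.up:
            overlap = self.up[cond] & self.down.get(cond, frozenset())
            if overlap:
                raise ValueError(f"{cond}: genes both up- and down-regulated: {sorted(overlap)[:5]}")


@dataclass
class ModuleSet:
    """Gene-to-module assignment with eigengene scores and per-gene statistics.

    ``assignment`` maps gene -> integer module id (0 = unassigned);
    ``eigengenes`` is the condition x module score matrix, each column
    normalized to unit variance; ``coreg`` is each gene's correlation with
    its parent module eigengene and ``hub`` the maximizing gene per module.
    """

    assignment: pd.Series
    eigengenes: pd.DataFrame
    coreg: pd.Series
    hub: dict[int, str]
    annotation: dict[int, tuple[str, float] | None] = field(default_factory=dict)
    explained_variance: dict[int, float] = field(default_factory=dict)

    @property
    def module_ids(self) -> list[int]:
        return sorted(m for m in self.assignment.unique() if m != 0)

    @property
    def sizes(self) -> pd.Series:
        a = self.assignment[self.assignment != 0]
        return a.value_counts().sort_index()

    def genes_of(self, module_id: int) -> list[str]:
        return list(self.assignment.index[self.assignment == module_id])


@dataclass
class PreservationResult:
    """Permutation Z statistics quantifying module preservation in a test system."""

    stats: pd.DataFrame
    skipped: list[str]
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        need = {
            "module", "n_genes", "n_shared", "density", "cor_kim", "cor_cor",
            "z_density", "z_connectivity", "z_summary", "median_rank", "preservation_class",
        }
        missing = need - set(self.stats.columns)
        if missing:
            raise ValueError(f"preservation stats missing columns: {sorted(missing)}")


@dataclass
class TraitScreenResult:
    """Module-vs-cell-death correlation records plus selected hits."""

    records: pd.DataFrame
    hits: dict[str, set[int]]
    support: pd.DataFrame
    candidate_genes: pd.DataFrame | None = None


def validate_trait_table(trait: pd.DataFrame) -> pd.DataFrame:
    """Check the cell-death trait table contract and return it.

    Required columns: compound, concentration, death_time_h, death_type,
    fraction.  Fractions must be in [0, 1] and keys unique.
    """
    need = ["compound", "concentration", "death_time_h", "death_type", "fraction"]
    missing = [c for c in need if c not in trait.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    f = trait["fraction"].to_numpy(float)
    if ((f < 0) | (f > 1)).any():
        raise ValueError("cell-death fractions must lie in [0, 1]")
    key = trait[["compound", "concentration", "death_time_h", "death_type"]]
    if key.duplicated().any():
        raise ValueError("duplicate (compound, concentration, death_time_h, death_type) records")
    return trait


def validate_rnai_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the RNAi screen table contract and return it."""
    need = ["target", "compound", "time_h", "death_type", "replicate", "value"]
    missing = [c for c in need if c not in table.columns]
    if missing:
        raise ValueError(f"RNAi table missing columns: {missing}")
    v = table["value"].to_numpy(float)
    if ((v < 0) | (v > 1)).any():
        raise ValueError("cell-death values must lie in [0, 1]")
    strata = table[["compound", "time_h", "death_type"]].drop_duplicates()
    scr = table[table["target"] == "scrambled"]
    have = set(map(tuple, scr[["compound", "time_h", "death_type"]].itertuples(index=False)))
    want = set(map(tuple, strata.itertuples(index=False)))
    if want - have:
        raise ValueError(f"strata without a scrambled control: {sorted(want - have)[:5]}")
    return table
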