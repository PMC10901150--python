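"""Standard synthetic experiments used by the test suite and worked examples.

These fix the study conditions once — sample sizes, module counts, noise
levels and coupling strengths — at values representative of a targeted
RNA-seq dose/time course in a hepatocyte line, and return both the
generated data and the planted ground truth for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, LogFCMatrix, StudyDesign
from .design import generate_design
from .qc import qc_pipeline
from .simulate import (
    ModuleSpec,
    TraitSpec,
    activation_matrix,
    generate_cell_death,
    generate_counts,
    generate_reference_logfc,
    generate_rnai_dataset,
    make_module_spec,
)


def _sub_seed(seed: int, k: int) -> int:
    return (int(seed) * 1009 + k) % (2**31)


@dataclass
class NetworkDataset:
    design: StudyDesign
    spec: ModuleSpec
    counts: CountMatrix
    logfc: LogFCMatrix
    truth_assignment: pd.Series
    truth_activation: pd.DataFrame


def standard_network_dataset(seed: int = 1, qc_defect_rate: float = 0.0) -> NetworkDataset:
    """2,000 genes, 8 planted modules plus background, 240 treated conditions.

    20 compounds across categories x 4 dose levels x {4, 8, 24} h x 3
    replicates in 2 batches; modules respond to random compound subsets
    with Hill dose-response and archetypal time profiles.
    """
    design = generate_design(
        {"DILI": 12, "stress_reference": 4, "cytokine_growth_factor": 2, "negative": 2},
        n_dose_levels=4,
        time_points=(4, 8, 24),
        n_replicates=3,
        n_batches=2,
        seed=_sub_seed(seed, 1),
        n_vehicle_replicates=12,
    )
    spec = make_module_spec(
        design,
        n_genes=2000,
        module_sizes=(120, 110, 100, 90, 80, 70, 60, 50),
        seed=_sub_seed(seed, 2),
    )
    counts = generate_counts(
        design, spec, qc_defect_rate=qc_defect_rate, seed=_sub_seed(seed, 3)
    )
    logfc, _report = qc_pipeline(counts)
    return NetworkDataset(
        design=design,
        spec=spec,
        counts=counts,
        logfc=logfc,
        truth_assignment=spec.assignment(),
        truth_activation=counts.truth["activation"],
    )


@dataclass
class TraitScreenDataset:
    design: StudyDesign
    spec: ModuleSpec
    logfc: LogFCMatrix
    trait_spec: TraitSpec
    trait: pd.DataFrame
    truth_assignment: pd.Series
    truth_activation: pd.DataFrame
    linked_modules: set[int]


def standard_trait_screen(seed: int = 1, link_weight: float = 1.0) -> TraitScreenDataset:
    """12 planted modules, 2 death-linked, 8 DILI + 4 negative compounds, 6 doses.

    The two linked modules are broad DILI-general stress programs (they
    respond to every DILI compound); the other ten respond to at most three
    DILI compounds each, the profile of compound-specific programs.  Cell
    death accumulates through a saturating hazard of the linked modules'
    late-time activation.  ``link_weight=0`` gives the pure-noise negative
    control.
    """
    design = generate_design(
        {"DILI": 8, "negative": 4},
        n_dose_levels=6,
        time_points=(4, 8, 24),
        n_replicates=3,
        n_batches=1,
        seed=_sub_seed(seed, 11),
        n_vehicle_replicates=12,
    )
    spec = make_module_spec(
        design,
        n_genes=800,
        module_sizes=(40,) * 12,
        seed=_sub_seed(seed, 12),
        broad_response_modules=(1, 2),
        narrow_response_max=3,
    )
    counts = generate_counts(design, spec, seed=_sub_seed(seed, 13))
    logfc, _ = qc_pipeline(counts)
    trait_spec = TraitSpec(
        linked_modules={1: link_weight, 2: 0.8 * link_weight},
        noise_sd=0.1,
        rate_scale=0.4,
    )
    trait = generate_cell_death(
        design, counts.truth["activation"], trait_spec, seed=_sub_seed(seed, 14)
    )
    return TraitScreenDataset(
        design=design,
        spec=spec,
        logfc=logfc,
        trait_spec=trait_spec,
        trait=trait,
        truth_assignment=spec.assignment(),
        truth_activation=counts.truth["activation"],
        linked_modules={1, 2} if link_weight > 0 else set(),
    )


@dataclass
class PreservationDataset:
    spec: ModuleSpec
    ref_logfc: LogFCMatrix
    test_logfc: LogFCMatrix
    ref_assignment: pd.Series
    preserved: set[int]
    scrambled: set[int]


def standard_preservation_experiment(seed: int = 1) -> PreservationDataset:
    """Ten 40-gene modules; five preserved in the test system, five scrambled."""
    design = generate_design({"DILI": 6}, n_dose_levels=4, seed=_sub_seed(seed, 21))
    spec = make_module_spec(
        design,
        n_genes=500,
        module_sizes=(40,) * 10,
        seed=_sub_seed(seed, 22),
    )
    all_ids = {m.module_id for m in spec.modules}
    preserved = {1, 2, 3, 4, 5}
    ref = generate_reference_logfc(
        spec, preserved_module_ids=all_ids, n_conditions=80, seed=_sub_seed(seed, 23),
        condition_prefix="H",
    )
    test = generate_reference_logfc(
        spec, preserved_module_ids=preserved, n_conditions=60, seed=_sub_seed(seed, 24),
        condition_prefix="P",
    )
    return PreservationDataset(
        spec=spec,
        ref_logfc=ref,
        test_logfc=test,
        ref_assignment=spec.assignment(),
        preserved=preserved,
        scrambled=all_ids - preserved,
    )


@dataclass
class RNAiScreenDataset:
    table: pd.DataFrame
    targets: list[str]
    protective: set[str]
    enhancing: set[str]
    effect_size: float


def standard_rnai_screen(seed: int = 1, effect_size: float = 3.0) -> RNAiScreenDataset:
    """60 siRNA targets, 6 planted protective and 6 enhancing, 2 DILI compounds."""
    targets = [f"T{i:02d}" for i in range(1, 61)]
    protective = set(targets[:6])
    enhancing = set(targets[6:12])
    table = generate_rnai_dataset(
        targets,
        protective,
        enhancing,
        compounds=("CMPD_A", "CMPD_B"),
        time_points=(24, 48, 72),
        effect_size=effect_size,
        seed=_sub_seed(seed, 31),
    )
    return RNAiScreenDataset(
        table=table,
        targets=targets,
        protective=protective,
        enhancing=enhancing,
        effect_size=effect_size,
    )
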