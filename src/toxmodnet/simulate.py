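"""Synthetic data generators with planted ground truth.

Every downstream stage of the pipeline is exercised on data produced here:
negative-binomial counts with planted co-expression modules whose log-scale
activation depends on compound, dose and time; a second "reference system"
log2FC dataset in which a chosen subset of modules keeps its co-expression
structure; a cell-death trait coupled to designated modules; and an RNAi
screen with planted protective/enhancing knockdown effects.  All generators
are pure functions of their arguments including the seed, and attach the
ground-truth labels needed to brute-force-check downstream filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    CountMatrix,
    LogFCMatrix,
    StudyDesign,
    validate_rnai_table,
    validate_trait_table,
)

# --------------------------------------------------------------------------
# Module specification
# --------------------------------------------------------------------------


@dataclass
class PlantedModule:
    """One planted co-expression module.

    The module's activation over a condition is a Hill function of dose
    level scaled by a per-compound responsiveness and a time-profile
    multiplier; member genes see ``loading * sign * activation`` added to
    their baseline log2 expression.  Loadings lie in [0.3, 1]; a negative
    sign models co-repressed (anti-correlated) members, which an unsigned
    network must still group together.
    """

    module_id: int
    genes: list[str]
    loadings: np.ndarray
    signs: np.ndarray
    amplitude: float
    ec50: float
    hill: float
    time_weights: dict[int, float]
    compound_response: dict[str, float]

    @property
    def size(self) -> int:
        return len(self.genes)

    def activation(self, compound: str, dose_level: int, time_h: int) -> float:
        """Activation in log2-FC units for one (compound, dose, time) cell."""
        resp = self.compound_response.get(compound, 0.0)
        if resp == 0.0 or dose_level <= 0:
            return 0.0
        d = float(dose_level)
        hill = d**self.hill / (d**self.hill + self.ec50**self.hill)
        return self.amplitude * resp * hill * self.time_weights.get(int(time_h), 0.0)


@dataclass
class ModuleSpec:
    """Planted module structure over a synthetic gene universe."""

    n_genes: int
    modules: list[PlantedModule]
    noise_dispersion: float = 10.0  # NB size parameter (median)
    dispersion_sigma: float = 0.5  # log-normal spread of per-gene size
    baseline_mean: float = 5.0  # log2 scale
    baseline_sd: float = 2.5
    #: Module genes start from a lower baseline (stress transcripts are
    #: induced from low/mid expression); this also keeps their share of the
    #: library realistic so induction does not distort everyone else's CPM.
    module_baseline_offset: float = 2.0

    def __post_init__(self) -> None:
        total = sum(m.size for m in self.modules)
        if total > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        for m in self.modules:
            lo, hi = float(m.loadings.min(initial=1.0)), float(m.loadings.max(initial=0.3))
            if lo < 0.3 - 1e-9 or hi > 1.0 + 1e-9:
                raise ValueError(f"module {m.module_id}: loadings must lie in [0.3, 1]")
        if self.modules and not any((m.signs < 0).any() for m in self.modules):
            raise ValueError("at least one module must contain mixed-sign (anti-correlated) members")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def assignment(self) -> pd.Series:
        """Planted gene -> module id labels (0 = background)."""
        lab = pd.Series(0, index=pd.Index(self.gene_ids, name="gene"), name="module")
        for m in self.modules:
            lab.loc[m.genes] = m.module_id
        return lab

    def module_of(self) -> dict[str, int]:
        return self.assignment().to_dict()


_TIME_PROFILES = (
    {4: 0.3, 8: 0.6, 24: 1.0},  # late responder
    {4: 1.0, 8: 0.8, 24: 0.4},  # early responder
    {4: 0.5, 8: 1.0, 24: 0.8},  # intermediate peak
)


def make_module_spec(
    design: StudyDesign,
    n_genes: int = 2000,
    module_sizes: Sequence[int] = (120, 110, 100, 90, 80, 70, 60, 50),
    seed: int = 0,
    amplitude_range: tuple[float, float] = (3.0, 6.0),
    responsive_fraction: float = 0.4,
    mixed_sign_frac: float = 0.25,
    broad_response_modules: Iterable[int] = (),
    narrow_response_max: int | None = None,
) -> ModuleSpec:
    """Draw a :class:`ModuleSpec` with randomized but reproducible parameters.

    Modules listed in ``broad_response_modules`` (1-based ids) respond to
    every non-negative compound with high responsiveness — the profile of a
    general cytotoxic stress program.  Other modules respond to a random
    subset of compounds (``responsive_fraction`` of the responsive pool, or
    at most ``narrow_response_max`` DILI compounds when given) — the profile
    of compound-specific programs.  Negative-control compounds never
    activate modules.
    """
    if sum(module_sizes) > n_genes:
        raise ValueError("module sizes exceed n_genes")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    cat = design.category_of()
    responsive_pool = [c for c in design.compounds if cat[c] not in ("negative", "vehicle")]
    dili_pool = [c for c in design.compounds if cat[c] == "DILI"]
    broad = set(broad_response_modules)
    max_dose = int(design.treated["dose_level"].max())

    cursor = 0
    modules: list[PlantedModule] = []
    for k, size in enumerate(module_sizes, start=1):
        genes = gene_ids[cursor : cursor + size]
        cursor += size
        loadings = rng.uniform(0.3, 1.0, size)
        signs = np.where(rng.random(size) < mixed_sign_frac, -1.0, 1.0)
        if k == 1 and (signs > 0).all():
            signs[-1] = -1.0  # guarantee one anti-correlated member somewhere
        if k in broad:
            # General cytotoxic stress program: engaged by every DILI compound,
            # but only near cytotoxic doses (steep Hill, high midpoint) and
            # late in time — the activation distribution is strongly skewed,
            # with pronounced per-compound peaks.
            response = {c: float(rng.uniform(0.85, 1.0)) for c in responsive_pool}
            amplitude = float(rng.uniform(max(3.5, amplitude_range[0]), amplitude_range[1]))
            time_weights = {4: 0.25, 8: 0.5, 24: 1.0}
            ec50 = float(rng.uniform(0.55, 0.75) * max_dose)
            hill = float(rng.uniform(3.5, 4.5))
        else:
            if narrow_response_max is not None:
                n_resp = min(narrow_response_max, len(dili_pool))
                chosen = list(rng.choice(dili_pool, size=n_resp, replace=False))
                chosen += [
                    c
                    for c in responsive_pool
                    if c not in dili_pool and rng.random() < responsive_fraction
                ]
            else:
                n_resp = max(1, round(responsive_fraction * len(responsive_pool)))
                chosen = list(rng.choice(responsive_pool, size=n_resp, replace=False))
            response = {c: float(rng.uniform(0.7, 1.0)) for c in chosen}
            amplitude = float(rng.uniform(*amplitude_range))
            time_weights = dict(_TIME_PROFILES[rng.integers(len(_TIME_PROFILES))])
            ec50 = float(rng.uniform(1.0, max(1.5, 0.6 * max_dose)))
            hill = float(rng.uniform(1.5, 3.0))
        modules.append(
            PlantedModule(
                module_id=k,
                genes=genes,
                loadings=loadings,
                signs=signs,
                amplitude=amplitude,
                ec50=ec50,
                hill=hill,
                time_weights=time_weights,
                compound_response=response,
            )
        )
    return ModuleSpec(n_genes=n_genes, modules=modules)


def activation_matrix(spec: ModuleSpec, design: StudyDesign) -> pd.DataFrame:
    """True module activation per treated condition (condition x module)."""
    idx = design.condition_index()
    data = {
        m.module_id: [m.activation(c, d, t) for (c, d, t) in idx]
        for m in spec.modules
    }
    return pd.DataFrame(data, index=idx)


# --------------------------------------------------------------------------
# Counts
# --------------------------------------------------------------------------

#: Blend weight keeping a corrupted replicate partially correlated with its
#: condition: r to the within-condition mean lands near 0.92 (fails the 0.95
#: filter) while untouched siblings stay near 0.97 (pass).
_DECORR_RHO = 0.85


def generate_counts(
    design: StudyDesign,
    spec: ModuleSpec,
    library_size_range: tuple[float, float] = (1_000_000, 3_000_000),
    qc_defect_rate: float = 0.0,
    seed: int = 0,
) -> CountMatrix:
    """Negative-binomial counts with planted module structure.

    Log2-scale gene means are ``baseline + loading * sign * activation`` for
    module members; library sizes are drawn uniformly from
    ``library_size_range``.  A ``qc_defect_rate`` fraction of treated
    samples is corrupted to exercise QC — half with library size below
    500,000 and half with a partially decorrelated expression profile — with
    at most one corrupted sample per condition.  Ground truth (planted
    labels, corrupted samples, activation matrix) rides along in ``truth``.
    """
    lo, hi = library_size_range
    if lo <= 0 or hi <= 0 or hi < lo:
        raise ValueError("library sizes must be positive with lo <= hi")
    if not (0 <= qc_defect_rate < 1):
        raise ValueError("qc_defect_rate must be in [0, 1)")
    known = set(design.samples["compound"])
    for m in spec.modules:
        bad = set(m.compound_response) - known
        if bad:
            raise ValueError(
                f"module {m.module_id} activation references unknown compounds: {sorted(bad)[:5]}"
            )

    rng = np.random.default_rng(seed)
    genes = spec.gene_ids
    n_genes = len(genes)
    samples = design.samples
    n_samples = len(samples)

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, n_genes)
    planted = spec.assignment().to_numpy() != 0
    baseline[planted] -= spec.module_baseline_offset
    size_param = spec.noise_dispersion * rng.lognormal(0.0, spec.dispersion_sigma, n_genes)

    # log2 mean matrix: baseline plus planted module effects
    log2mu = np.tile(baseline[:, None], (1, n_samples))
    gene_pos = {g: i for i, g in enumerate(genes)}
    sample_cond = list(zip(samples["compound"], samples["dose_level"], samples["time_h"]))
    for m in spec.modules:
        effect = m.loadings * m.signs
        rows = np.array([gene_pos[g] for g in m.genes])
        acts = np.array([m.activation(c, d, t) for (c, d, t) in sample_cond])
        log2mu[np.ix_(rows, np.arange(n_samples))] += np.outer(effect, acts)

    # choose corrupted samples: at most one per treated condition
    corrupted: dict[str, str] = {}
    treated = samples[samples["category"] != "vehicle"]
    n_bad = int(round(qc_defect_rate * len(treated)))
    if n_bad:
        conditions = list(
            treated.groupby(["compound", "dose_level", "time_h"], sort=True).groups.items()
        )
        order = rng.permutation(len(conditions))
        picked: list[str] = []
        for j in order[:n_bad]:
            _, row_idx = conditions[j]
            pick = rng.integers(len(row_idx))
            picked.append(samples.loc[row_idx[pick], "sample_id"])
        kinds = ["lowlib" if i < (n_bad + 1) // 2 else "decorrelated" for i in range(n_bad)]
        corrupted = dict(zip(picked, kinds))

    sample_ids = list(samples["sample_id"])
    lib_target = rng.uniform(lo, hi, n_samples)
    for j, sid in enumerate(sample_ids):
        kind = corrupted.get(sid)
        if kind == "lowlib":
            lib_target[j] = rng.uniform(100_000, 400_000)
        elif kind == "decorrelated":
            col = log2mu[:, j]
            centered = col - col.mean()
            noise = baseline - baseline.mean()
            noise = noise[rng.permutation(n_genes)]
            log2mu[:, j] = col.mean() + _DECORR_RHO * centered + np.sqrt(
                1 - _DECORR_RHO**2
            ) * noise

    w = 2.0**log2mu
    mean = w / w.sum(axis=0, keepdims=True) * lib_target[None, :]
    p = size_param[:, None] / (size_param[:, None] + mean)
    counts = rng.negative_binomial(size_param[:, None], p)

    values = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=sample_ids)
    truth = {
        "assignment": spec.assignment(),
        "corrupted": corrupted,
        "activation": activation_matrix(spec, design),
        "library_size_range": (float(lo), float(hi)),
    }
    return CountMatrix(values=values, design=design, truth=truth)


# --------------------------------------------------------------------------
# Reference-system log2FC
# --------------------------------------------------------------------------


def generate_reference_logfc(
    spec: ModuleSpec,
    preserved_module_ids: Iterable[int],
    n_conditions: int = 60,
    seed: int = 0,
    attenuation: float = 1.0,
    noise_sd: float = 0.35,
    condition_prefix: str = "R",
) -> LogFCMatrix:
    """Second-system log2FC matrix with a chosen subset of modules preserved.

    Preserved modules keep their within-module co-expression (shared
    per-condition activation, optionally attenuated); non-preserved modules
    have each member's condition profile regenerated independently, which
    destroys the co-expression while keeping the marginal variance.  Gene
    identifiers are shared with the first system so preservation statistics
    can align the two.
    """
    preserved = set(preserved_module_ids)
    known = {m.module_id for m in spec.modules}
    if preserved - known:
        raise ValueError(f"unknown preserved module ids: {sorted(preserved - known)}")
    if n_conditions < 10:
        warnings.warn(
            "fewer than 10 reference conditions: preservation statistics will be unstable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    genes = spec.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    values = rng.normal(0.0, noise_sd, (n_conditions, len(genes)))
    for m in spec.modules:
        act_sd = 0.4 * m.amplitude
        cols = np.array([gene_pos[g] for g in m.genes])
        effect = m.loadings * m.signs
        if m.module_id in preserved:
            act = rng.normal(0.0, act_sd, n_conditions)
            values[:, cols] += attenuation * np.outer(act, effect)
        else:
            act = rng.normal(0.0, act_sd, (n_conditions, m.size))
            values[:, cols] += act * np.abs(effect)[None, :]
    idx = pd.MultiIndex.from_tuples(
        [(f"{condition_prefix}{i + 1:03d}", 0, 0) for i in range(n_conditions)],
        names=("compound", "dose_level", "time_h"),
    )
    df = pd.DataFrame(values, index=idx, columns=pd.Index(genes, name="gene"))
    padj = pd.DataFrame(1.0, index=df.index, columns=df.columns)
    return LogFCMatrix(values=df, padj=padj)


# --------------------------------------------------------------------------
# Cell-death trait
# --------------------------------------------------------------------------


@dataclass
class TraitSpec:
    """Coupling between planted module activations and cell death.

    Death accumulates monotonically in time via a saturating hazard link:
    ``fraction(t) = baseline + (1 - baseline) * (1 - exp(-drive * t / 58))``
    where ``drive`` is the positive part of the noisy weighted sum of the
    late-time (24 h) activations of the linked modules.  With all weights
    and noise zero every fraction equals the baseline.
    """

    linked_modules: Mapping[int, float] = field(default_factory=dict)
    death_types: Sequence[str] = ("apoptosis", "necrosis")
    death_times: Sequence[int] = (8, 24, 48, 58)
    baseline: float = 0.02
    noise_sd: float = 0.1
    rate_scale: float = 0.25
    death_type_scale: Mapping[str, float] = field(
        default_factory=lambda: {"apoptosis": 1.0, "necrosis": 0.7}
    )

    def __post_init__(self) -> None:
        bad = set(self.death_times) - {8, 24, 48, 58}
        if bad:
            raise ValueError(f"death time points must be within {{8, 24, 48, 58}}: {sorted(bad)}")
        if not (0 <= self.baseline < 1):
            raise ValueError("baseline must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_cell_death(
    design: StudyDesign,
    egs_truth: pd.DataFrame,
    trait: TraitSpec,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell-death fractions per (compound, concentration, death time, death type).

    ``egs_truth`` is the condition x module true-activation matrix from
    :func:`activation_matrix`; it must cover every treated (compound,
    dose_level) cell of the design.  Fractions are monotone non-decreasing
    in the death measurement time for a fixed condition, and linked modules
    induce dose-dependent death through their dose-dependent activation.
    """
    rng = np.random.default_rng(seed)
    conc_of = design.concentration_of()
    cells = sorted({(c, d) for (c, d, _t) in design.condition_index()})
    available = set(egs_truth.index)
    late_t = max(t for (_c, _d, t) in available)
    for c, d in cells:
        if (c, d, late_t) not in available:
            raise ValueError(f"egs_truth does not cover condition {(c, d, late_t)}")

    unknown = set(trait.linked_modules) - set(egs_truth.columns)
    if unknown:
        raise ValueError(f"linked modules absent from egs_truth: {sorted(unknown)}")

    max_t = max(trait.death_times)
    rows = []
    for compound, dose in cells:
        act = egs_truth.loc[(compound, dose, late_t)]
        score = sum(w * act[m] for m, w in trait.linked_modules.items())
        for dtype in trait.death_types:
            s = trait.rate_scale * trait.death_type_scale.get(dtype, 1.0) * score
            s += rng.normal(0.0, trait.noise_sd) if trait.noise_sd > 0 else 0.0
            drive = max(0.0, s)
            for t in trait.death_times:
                frac = trait.baseline + (1 - trait.baseline) * (1 - np.exp(-drive * t / max_t))
                rows.append(
                    {
                        "compound": compound,
                        "concentration": conc_of[(compound, dose)],
                        "dose_level": dose,
                        "death_time_h": int(t),
                        "death_type": dtype,
                        "fraction": float(np.clip(frac, 0.0, 1.0)),
                    }
                )
    return validate_trait_table(pd.DataFrame(rows))


# --------------------------------------------------------------------------
# RNAi screen
# --------------------------------------------------------------------------


def generate_rnai_dataset(
    target_genes: Sequence[str],
    protective_set: Iterable[str],
    enhancing_set: Iterable[str],
    compounds: Sequence[str] = ("CMPD_A", "CMPD_B"),
    time_points: Sequence[int] = (24, 48, 72),
    effect_size: float = 3.0,
    seed: int = 0,
    noise_sd: float = 0.05,
    n_replicates: int = 3,
    vehicle: str = "DMSO",
    death_types: Sequence[str] = ("AnV", "PI"),
    clip: bool = True,
) -> pd.DataFrame:
    """Planted RNAi cell-death screen with mock and scrambled controls.

    Protective knockdowns shift death down by ``effect_size * noise_sd``
    under the test compounds (never under the vehicle); enhancing knockdowns
    shift it up.  Every (compound, time, death type) stratum contains mock
    and scrambled control records.
    """
    protective = set(protective_set)
    enhancing = set(enhancing_set)
    if protective & enhancing:
        raise ValueError(f"protective and enhancing sets overlap: {sorted(protective & enhancing)}")
    missing = (protective | enhancing) - set(target_genes)
    if missing:
        raise ValueError(f"effect sets reference unknown targets: {sorted(missing)}")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")

    rng = np.random.default_rng(seed)
    shift = effect_size * noise_sd
    all_targets = list(target_genes) + ["mock", "scrambled"]
    rows = []
    for compound in list(compounds) + [vehicle]:
        is_vehicle = compound == vehicle
        for ti, t in enumerate(time_points):
            for dtype in death_types:
                base = 0.05 if is_vehicle else (0.35 + 0.05 * ti) * (0.8 if dtype == "PI" else 1.0)
                for target in all_targets:
                    delta = 0.0
                    if not is_vehicle:
                        if target in protective:
                            delta = -shift
                        elif target in enhancing:
                            delta = +shift
                    for rep in range(1, n_replicates + 1):
                        v = base + delta + rng.normal(0.0, noise_sd)
                        rows.append(
                            {
                                "target": target,
                                "compound": compound,
                                "time_h": int(t),
                                "death_type": dtype,
                                "replicate": rep,
                                "value": float(np.clip(v, 0.0, 1.0)) if clip else float(v),
                            }
                        )
    table = pd.DataFrame(rows)
    return validate_rnai_table(table) if clip else table
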