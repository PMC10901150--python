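"""Run configuration: defaults, YAML loading and validation.

Every stage parameter lives here with a default equal to the study's
stated value where one exists: 500,000 minimum library size, 0.95
replicate correlation, DEG thresholds .01/.1, eigengene merge at 0.8,
preservation interpretation at Zsummary 2/10, trait criteria .1/0.5/2/>4,
and candidate-gene thresholds .1/2.  The soft power is selected
automatically by default, with 9 documented as the original analysis's
choice.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class SimulateConfig:
    n_compounds_per_category: dict = field(
        default_factory=lambda: {"DILI": 8, "stress_reference": 2, "negative": 2}
    )
    n_dose_levels: int = 6
    time_points: list = field(default_factory=lambda: [4, 8, 24])
    n_replicates: int = 3
    n_batches: int = 1
    n_genes: int = 1000
    module_sizes: list = field(default_factory=lambda: [40] * 8)
    qc_defect_rate: float = 0.0
    linked_modules: dict = field(default_factory=lambda: {1: 1.0, 2: 0.8})
    broad_response_modules: list = field(default_factory=lambda: [1, 2])
    preserved_modules: list = field(default_factory=lambda: [1, 2, 3, 4])
    n_reference_conditions: int = 60
    rnai_n_targets: int = 40
    rnai_n_protective: int = 5
    rnai_n_enhancing: int = 5
    rnai_effect_size: float = 3.0


@dataclass
class QCConfig:
    min_library_size: int = 500_000
    min_replicate_r: float = 0.95
    pseudocount: float = 1.0
    n_top_variable: int = 5000
    leave_one_out: bool = False
    deg_padj_max: float = 0.01
    deg_min_abs_lfc: float = 0.1
    max_missing_frac: float = 0.5
    min_variance: float = 1e-8


@dataclass
class NetworkConfig:
    beta: int | None = None  # None = automatic scale-free selection
    reference_beta: int = 9
    min_module_size: int = 20
    merge_threshold: float = 0.8
    cut_height: float | None = None
    cut_mode: str = "hybrid"
    target_r2: float = 0.85
    gmt: str | None = None


@dataclass
class PreserveConfig:
    n_perm: int = 200
    beta: int = 6
    min_shared_genes: int = 10
    moderate_zsummary: float = 2.0
    high_zsummary: float = 10.0


@dataclass
class TraitConfig:
    death_time_h: int = 58
    padj_max: float = 0.1
    min_r: float = 0.5
    min_eg: float = 2.0
    min_dili_compounds: int = 4  # strictly greater than
    gene_padj_max: float = 0.1
    gene_min_lfc: float = 2.0
    min_points: int = 3
    padj_family: str = "per_death_stratum"


@dataclass
class RNAiConfig:
    z_min: float = 1.0
    k: int = 2
    mode: str = "threshold"
    eps: float = 1e-3


_STAGES = ("simulate", "qc", "network", "preserve", "trait", "rnai")


@dataclass
class RunConfig:
    seed: int = 1
    out: str = "toxmodnet_run"
    stages: list = field(default_factory=lambda: list(_STAGES))
    log_level: str = "INFO"
    inputs: dict = field(default_factory=dict)  # stage -> {name: path} for external data
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    preserve: PreserveConfig = field(default_factory=PreserveConfig)
    trait: TraitConfig = field(default_factory=TraitConfig)
    rnai: RNAiConfig = field(default_factory=RNAiConfig)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        kwargs = {}
        sections = {f.name: f.type for f in fields(cls)}
        for key, val in data.items():
            if key not in sections:
                raise ValueError(f"unknown config key: {key!r}")
            kwargs[key] = val
        for name, sub_cls in (
            ("simulate", SimulateConfig),
            ("qc", QCConfig),
            ("network", NetworkConfig),
            ("preserve", PreserveConfig),
            ("trait", TraitConfig),
            ("rnai", RNAiConfig),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                allowed = {f.name for f in fields(sub_cls)}
                unknown = set(kwargs[name]) - allowed
                if unknown:
                    raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
                kwargs[name] = sub_cls(**kwargs[name])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
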