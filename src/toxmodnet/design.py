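"""Study-design generation for the synthetic toxicogenomics experiment.

Emulates a compound x dose-level x time-point x replicate design with
vehicle controls per batch and time point, mirroring a targeted-sequencing
dose/time course in a hepatocyte cell line: up to six concentrations per
compound, lysis at 4/8/24 h, three biological replicates, and one or two
experiment batches.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CATEGORIES, StudyDesign

_PREFIX = {
    "DILI": "DILI",
    "stress_reference": "STR",
    "cytokine_growth_factor": "CGF",
    "negative": "NEG",
}

#: Severity classes observed for DILI compounds (FDA-derived scale).
_SEVERITIES = (3, 4, 5, 7, 8)


def generate_design(
    n_compounds_per_category: Mapping[str, int],
    n_dose_levels: int = 6,
    time_points: Sequence[int] = (4, 8, 24),
    n_replicates: int = 3,
    n_batches: int = 1,
    seed: int = 0,
    n_vehicle_replicates: int | None = None,
) -> StudyDesign:
    """Build a complete study design, including vehicle samples.

    Parameters
    ----------
    n_compounds_per_category
        Mapping from category (``DILI``, ``stress_reference``,
        ``cytokine_growth_factor``, ``negative``) to the number of synthetic
        compounds to create.  At least one compound overall is required.
    n_dose_levels
        Concentration levels per compound, 1..6, strictly ordered.
    time_points
        Transcriptomic sampling times in hours.
    n_replicates
        Biological replicates per condition (>= 2 so replicate-correlation
        QC is meaningful).
    n_batches
        Compounds are assigned round-robin to batches; each batch gets its
        own vehicle control samples for every time point.
    n_vehicle_replicates
        Vehicle (solvent-control) wells per batch and time point; defaults
        to ``n_replicates``.  Plates often carry extra solvent wells, and a
        larger vehicle pool stabilizes the fold-change denominator.
    seed
        Seeds the concentration grids and severity labels; the same call is
        byte-identical when repeated.
    """
    if not (1 <= n_dose_levels <= 6):
        raise ValueError("n_dose_levels must be in 1..6")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 (replicate QC requires duplicates)")
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    if not time_points:
        raise ValueError("at least one time point is required")
    unknown = set(n_compounds_per_category) - (set(CATEGORIES) - {"vehicle"})
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    counts = {k: int(v) for k, v in n_compounds_per_category.items() if int(v) > 0}
    if not counts:
        raise ValueError("empty category counts: at least one compound is required")

    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    compounds: list[tuple[str, str]] = []
    for category in [c for c in CATEGORIES if c in counts]:
        for i in range(counts[category]):
            compounds.append((f"{_PREFIX[category]}_{i + 1:02d}", category))

    for idx, (compound, category) in enumerate(compounds):
        batch = idx % n_batches + 1
        severity = int(rng.choice(_SEVERITIES)) if category == "DILI" else None
        # Geometric concentration grid with a compound-specific anchor.
        base = float(10 ** rng.uniform(-1.0, 1.5))
        concentrations = base * 2.0 ** np.arange(n_dose_levels)
        for dose in range(1, n_dose_levels + 1):
            for t in time_points:
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{compound}_d{dose}_t{t}_r{rep}",
                            "compound": compound,
                            "category": category,
                            "severity": severity,
                            "dose_level": dose,
                            "concentration": round(float(concentrations[dose - 1]), 6),
                            "conc_unit": "uM",
                            "time_h": int(t),
                            "replicate": rep,
                            "batch": batch,
                            "vehicle_of": f"VEH_{batch}",
                        }
                    )

    n_veh = n_vehicle_replicates if n_vehicle_replicates is not None else n_replicates
    if n_veh < 2:
        raise ValueError("n_vehicle_replicates must be >= 2")
    used_batches = sorted({idx % n_batches + 1 for idx in range(len(compounds))})
    for batch in used_batches:
        compound = f"VEH_{batch}"
        for t in time_points:
            for rep in range(1, n_veh + 1):
                rows.append(
                    {
                        "sample_id": f"{compound}_t{t}_r{rep}",
                        "compound": compound,
                        "category": "vehicle",
                        "severity": None,
                        "dose_level": 0,
                        "concentration": 0.0,
                        "conc_unit": "uM",
                        "time_h": int(t),
                        "replicate": rep,
                        "batch": batch,
                        "vehicle_of": "",
                    }
                )

    df = pd.DataFrame(rows)
    df["severity"] = df["severity"].astype("Int64")
    return StudyDesign(df)
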