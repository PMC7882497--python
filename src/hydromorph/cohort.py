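"""Simulated morphometric cohorts with planted statistical structure.

Each simulated cohort mimics the study design of a two-group infant
sample: a fraction of subjects has enlarged CSF spaces (frontal SAS and
interhemispheric fissure), and in that group the optic nerve is wider,
longer and less tortuous, by configurable effect sizes in SD units.
The binary neurological-complication outcome is generated conditional
on the joint "enlarged CSF + deformed ON" pattern (not on enlargement
alone) with a planted risk ratio, so downstream risk stratification has
a known target.

All default baselines and effect sizes are documented fixtures (see the
methods note); the defaults reproduce the direction and approximate
magnitude of the group contrasts the pipeline is designed to detect
(ON width ~4.6 vs ~3.1 mm, length ~16.7 vs ~10.8 mm, lower tortuosity
in the enlarged group, complication risk ratio ~7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "simulate_cohort", "default_normative_table"]

COHORT_COLUMNS = [
    "subject_id", "age_days", "sex", "group",
    "fsas_mean_mm", "fsas_max_mm", "ihf_mean_mm", "ihf_max_mm",
    "on_width_mm", "on_length_mm", "on_tortuosity_ratio", "complication",
]

# fixture baselines: means/SDs of the normal (non-enlarged) group
_BASE_MEAN = {
    "fsas_mean_mm": 1.94, "ihf_mean_mm": 1.88,
    "on_width_mm": 3.12, "on_length_mm": 10.84, "on_tortuosity_ratio": 1.15,
}
_BASE_SD = {
    "fsas_mean_mm": 0.60, "ihf_mean_mm": 0.60,
    "on_width_mm": 1.00, "on_length_mm": 3.50, "on_tortuosity_ratio": 0.05,
}
# enlarged-minus-normal group shifts in SD units; signs follow the study
# directions: wider CSF spaces, wider and longer but less tortuous nerve
_DEFAULT_EFFECTS = {
    "fsas_mean_mm": 3.05, "ihf_mean_mm": 2.70,
    "on_width_mm": 1.44, "on_length_mm": 1.66, "on_tortuosity_ratio": -2.00,
}


@dataclass
class CohortSpec:
    """Generative parameters of a simulated cohort."""

    n_subjects: int = 34
    fraction_enlarged: float = 23 / 34
    age_range_days: tuple[int, int] = (6, 548)
    effect_sizes: dict = field(default_factory=lambda: dict(_DEFAULT_EFFECTS))
    baseline_means: dict = field(default_factory=lambda: dict(_BASE_MEAN))
    baseline_sds: dict = field(default_factory=lambda: dict(_BASE_SD))
    max_width_offset_mm: float = 1.0  # max width = mean width + offset + noise
    max_width_noise_sd: float = 0.2
    baseline_complication_p: float = 0.073
    planted_rr: float = 7.28
    age_slope_on_length: float = 0.0  # mm of ON length per day of age
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ValueError(f"n_subjects must be >= 4, got {self.n_subjects}")
        if not 0.0 <= self.fraction_enlarged <= 1.0:
            raise ValueError("fraction_enlarged must be in [0, 1]")
        if not 0.0 <= self.baseline_complication_p <= 1.0:
            raise ValueError("baseline_complication_p must be in [0, 1]")
        if self.planted_rr <= 0:
            raise ValueError("planted_rr must be > 0")
        for k, sd in self.baseline_sds.items():
            if sd <= 0:
                raise ValueError(f"baseline SD for {k} must be > 0")


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort; returns (subject table, truth table).

    The subject table has the documented schema (one row per subject, the
    morphometric measures in mm); the truth table records each subject's
    generating group and complication probability.  Identical spec + seed
    give identical tables.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_subjects

    n_enlarged = int(round(spec.fraction_enlarged * n))
    if n_enlarged == 0 or n_enlarged == n:
        raise ValueError(
            f"fraction_enlarged={spec.fraction_enlarged} with n={n} leaves one "
            "group empty"
        )
    group = np.zeros(n, dtype=int)
    group[rng.permutation(n)[:n_enlarged]] = 1

    age = rng.uniform(*spec.age_range_days, size=n)
    sex = rng.integers(0, 2, size=n)  # 0 = male, 1 = female; independent of group

    cols: dict[str, np.ndarray] = {}
    for meas in _BASE_MEAN:
        mu = spec.baseline_means[meas]
        sd = spec.baseline_sds[meas]
        shift = spec.effect_sizes.get(meas, 0.0) * sd
        vals = rng.normal(mu + shift * group, sd)
        if meas == "on_tortuosity_ratio":
            vals = np.maximum(vals, 1.0)  # arch-to-chord ratio cannot dip below 1
        else:
            vals = np.maximum(vals, 0.05)
        cols[meas] = vals
    cols["on_length_mm"] = cols["on_length_mm"] + spec.age_slope_on_length * age

    for region in ("fsas", "ihf"):
        cols[f"{region}_max_mm"] = (
            cols[f"{region}_mean_mm"] + spec.max_width_offset_mm
            + rng.normal(0.0, spec.max_width_noise_sd, size=n)
        )

    p0 = spec.baseline_complication_p
    p = np.where(group == 1, min(p0 * spec.planted_rr, 1.0), p0)
    complication = (rng.uniform(size=n) < p).astype(int)

    subjects = pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n)],
        "age_days": np.round(age).astype(int),
        "sex": np.where(sex == 1, "F", "M"),
        "group": np.where(group == 1, "enlarged", "normal"),
        "fsas_mean_mm": cols["fsas_mean_mm"],
        "fsas_max_mm": cols["fsas_max_mm"],
        "ihf_mean_mm": cols["ihf_mean_mm"],
        "ihf_max_mm": cols["ihf_max_mm"],
        "on_width_mm": cols["on_width_mm"],
        "on_length_mm": cols["on_length_mm"],
        "on_tortuosity_ratio": cols["on_tortuosity_ratio"],
        "complication": complication,
    })[COHORT_COLUMNS]
    truth = pd.DataFrame({
        "subject_id": subjects["subject_id"],
        "true_group": subjects["group"],
        "complication_p": p,
    })
    return subjects, truth


def default_normative_table() -> pd.DataFrame:
    """Fixture normative table of maximal CSF-space widths.

    Stand-in for a published normative sample of healthy infants (the
    original reference values are not reprinted anywhere machine-readable);
    means/SDs are fixtures chosen so that the simulator's enlarged group
    typically exceeds +1.96 SD and the normal group does not.  A single age
    bracket covers the simulated age range.
    """
    return pd.DataFrame({
        "measure": ["fsas_max_mm", "ihf_max_mm"],
        "age_min_days": [0, 0],
        "age_max_days": [750, 750],
        "mean": [2.60, 2.40],
        "sd": [0.90, 0.90],
    })
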