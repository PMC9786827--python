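"""Cohort simulation: ages, groups, prevalence, and inter-eye correlation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from ..config import GeneratorConfig
from .profiles import EyeGroundTruth, make_eye_profile

__all__ = ["GroupSpec", "CohortSpec", "make_cohort"]

Prevalence = Callable[[float], float]


@dataclass
class GroupSpec:
    """One study group with an age-dependent severity prevalence.

    ``prevalence`` maps age (years) to the probability in [0, 1] that a
    patient carries a non-zero severity; a constant may be given instead of
    a callable.
    """

    name: str
    fraction: float  # fraction of patients in this group
    prevalence: Prevalence | float = 0.0

    def prevalence_at(self, age: float) -> float:
        p = self.prevalence(age) if callable(self.prevalence) else float(self.prevalence)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prevalence {p} outside [0, 1] (group {self.name}, age {age:.1f})")
        return p


@dataclass
class CohortSpec:
    groups: list[GroupSpec] = field(default_factory=lambda: [GroupSpec("diabetic", 1.0)])
    inter_eye_correlation: float = 0.65

    def __post_init__(self):
        total = sum(g.fraction for g in self.groups)
        if not np.isclose(total, 1.0):
            raise ValueError("group fractions must sum to 1")


def _latent_rho(target: float) -> float:
    """Gaussian-copula latent correlation giving Pearson correlation
    ``target`` between the two uniform severities (inverse of the classical
    (6/pi)*asin(rho/2) relation)."""
    return float(2.0 * np.sin(np.pi * target / 6.0))


def make_cohort(
    n_patients: int,
    spec: CohortSpec | None = None,
    seed: int = 0,
    pop: GeneratorConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, EyeGroundTruth]]:
    """Draw a two-eyed cohort.

    Affected status is decided per patient from the group's age-dependent
    prevalence; affected patients receive correlated per-eye severities from
    a Gaussian copula so that the sample correlation of the two severities
    matches ``spec.inter_eye_correlation``.  Disc areas are drawn
    independently of severity.

    Returns a table with one row per eye (patient_id, eye, age, group,
    severity, disc_area, ...) and the ground-truth profile of each eye keyed
    by ``patient_id:eye``.
    """
    spec = spec or CohortSpec()
    pop = pop or GeneratorConfig()
    rng = np.random.default_rng(seed)

    fractions = np.array([g.fraction for g in spec.groups])
    group_idx = rng.choice(len(spec.groups), size=n_patients, p=fractions)
    rho = _latent_rho(spec.inter_eye_correlation)

    rows = []
    profiles: dict[str, EyeGroundTruth] = {}
    for i in range(n_patients):
        grp = spec.groups[group_idx[i]]
        age = float(np.clip(rng.normal(pop.age_mean, pop.age_sd), 20.0, 95.0))
        affected = rng.random() < grp.prevalence_at(age)
        if affected:
            z0, z1, z2 = rng.normal(size=3)
            x = np.sqrt(rho) * z0 + np.sqrt(1.0 - rho) * np.array([z1, z2])
            sev = stats.norm.cdf(x)
        else:
            sev = np.zeros(2)
        pid = f"pt{i:06d}"
        for eye, g in zip(("right", "left"), sev):
            gt = make_eye_profile(pop, severity=float(g), seed=rng,
                                  patient_id=pid, eye=eye)
            profiles[f"{pid}:{eye}"] = gt
            rows.append({
                "patient_id": pid,
                "eye": eye,
                "age": age,
                "group": grp.name,
                "severity": float(g),
                "disc_area": gt.disc_area,
                "cup_fraction": gt.cup_fraction,
                "vertical_cd": gt.vertical_cd,
                "scale_mm_per_px": gt.scale,
            })
    return pd.DataFrame(rows), profiles
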