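"""Synthetic digital-mouse cohort generation.

Each animal carries the covariates measured destructively in a CCl4
fibrosis study — Ishak stage, hepatic hydroxyproline (total collagen),
Sirius-Red-positive area, relative ASGP-R protein expression and relative
MMP-9 mRNA — together with the imaging-side quantities (liver volume,
injected dose) and per-animal kinetic parameters.  Receptor density in the
kinetic model is tied to the sampled ASGP-R expression (``R = asgpr_rel``),
so the simulated images carry the receptor signal that the liver-uptake
index is designed to read out.

Covariates are drawn lognormally around group means (moment-matched), so
they remain positive; an SD of zero reproduces the group mean exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import KineticParams

__all__ = [
    "GroupSpec",
    "CohortConfig",
    "AnimalRecord",
    "sample_cohort",
    "cohort_to_frame",
    "cohort_from_frame",
]

# Ishak-stage constraints per canonical group name: fibrous portal
# expansion with short septa (Ishak 2-3) after 4 weeks of CCl4, bridging
# fibrosis with regenerative nodules (Ishak 4-5) by 8-12 weeks; the
# Tan IIA arm regresses to the mild band.
_ISHAK_ALLOWED = {
    "control": {0},
    "ccl4_4wk": {2, 3},
    "ccl4_8wk": {4, 5},
    "ccl4_12wk": {4, 5},
    "ccl4_tanIIA": {2, 3},
}


@dataclass(frozen=True)
class GroupSpec:
    """Distributional description of one experimental group.

    Covariate entries are ``(mean, sd)`` pairs on the natural scale;
    sampling is lognormal with those moments.  ``k_up`` is the group's
    calibrated uptake rate constant at unit receptor density.
    """

    name: str
    ishak_choices: tuple
    asgpr_rel: tuple
    hydroxyproline: tuple
    sirius_red_pct: tuple
    mmp9_rel: tuple
    liver_volume_mL: tuple
    injected_MBq: tuple
    k_up: float

    def __post_init__(self):
        if not self.ishak_choices:
            raise ValueError(f"group {self.name!r}: ishak_choices is empty")
        for s in self.ishak_choices:
            if not 0 <= int(s) <= 6:
                raise ValueError(f"group {self.name!r}: Ishak score {s} outside 0-6")
        for fname in ("asgpr_rel", "hydroxyproline", "sirius_red_pct",
                      "mmp9_rel", "liver_volume_mL", "injected_MBq"):
            mean, sd = getattr(self, fname)
            if mean <= 0:
                raise ValueError(f"group {self.name!r}: {fname} mean must be > 0")
            if sd < 0:
                raise ValueError(f"group {self.name!r}: {fname} SD must be >= 0")
        if self.k_up <= 0:
            raise ValueError(f"group {self.name!r}: k_up must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level configuration: groups, group size, kinetics, seed."""

    groups: tuple
    n_per_group: int = 6
    seed: int = 0
    kinetic_defaults: dict = field(
        default_factory=lambda: dict(
            f_fast=0.6, k_fast=0.35, k_slow=0.04, k_off=0.012, excretion_split=0.7
        )
    )

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError(f"n_per_group must be >= 1, got {self.n_per_group}")
        if not self.groups:
            raise ValueError("at least one group is required")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate group names: {names}")


@dataclass(frozen=True)
class AnimalRecord:
    """One simulated mouse."""

    animal_id: str
    group: str
    ishak: int
    hydroxyproline: float
    sirius_red_pct: float
    asgpr_rel: float
    mmp9_rel: float
    liver_volume_mL: float
    injected_MBq: float
    kinetics: KineticParams

    def __post_init__(self):
        if not 0 <= self.ishak <= 6:
            raise ValueError(f"Ishak score must be in 0-6, got {self.ishak}")
        allowed = _ISHAK_ALLOWED.get(self.group)
        if allowed is not None and self.ishak not in allowed:
            raise ValueError(
                f"group {self.group!r} requires Ishak in {sorted(allowed)}, "
                f"got {self.ishak}"
            )
        for fname in ("hydroxyproline", "sirius_red_pct", "asgpr_rel", "mmp9_rel"):
            if getattr(self, fname) < 0:
                raise ValueError(f"{fname} must be non-negative")
        if self.liver_volume_mL <= 0 or self.injected_MBq <= 0:
            raise ValueError("liver volume and injected dose must be positive")


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size: int):
    """Lognormal samples with the given mean and SD on the natural scale."""
    if sd == 0.0:
        return np.full(size, mean)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def sample_cohort(cfg: CohortConfig, seed: int | None = None) -> list:
    """Draw a seeded, reproducible cohort of :class:`AnimalRecord`.

    The per-animal receptor density equals the sampled ``asgpr_rel``, and
    the uptake constant ``k_up`` is the group's calibrated value, so the
    expected liver fraction scales with receptor expression within and
    across groups.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    animals = []
    n = cfg.n_per_group
    for g in cfg.groups:
        draws = {
            name: _lognormal(rng, *getattr(g, name), n)
            for name in ("asgpr_rel", "hydroxyproline", "sirius_red_pct",
                         "mmp9_rel", "liver_volume_mL", "injected_MBq")
        }
        ishak = rng.choice(np.asarray(g.ishak_choices, dtype=int), size=n)
        for i in range(n):
            kin = KineticParams(
                k_up=g.k_up, R=float(draws["asgpr_rel"][i]), **cfg.kinetic_defaults
            )
            animals.append(
                AnimalRecord(
                    animal_id=f"{g.name}_{i + 1:03d}",
                    group=g.name,
                    ishak=int(ishak[i]),
                    hydroxyproline=float(draws["hydroxyproline"][i]),
                    sirius_red_pct=float(draws["sirius_red_pct"][i]),
                    asgpr_rel=float(draws["asgpr_rel"][i]),
                    mmp9_rel=float(draws["mmp9_rel"][i]),
                    liver_volume_mL=float(draws["liver_volume_mL"][i]),
                    injected_MBq=float(draws["injected_MBq"][i]),
                    kinetics=kin,
                )
            )
    return animals


_KINETIC_COLS = ("f_fast", "k_fast", "k_slow", "k_up", "k_off", "R", "excretion_split")


def cohort_to_frame(animals) -> pd.DataFrame:
    """Flatten a cohort into one row per animal (documented CSV schema)."""
    rows = []
    for a in animals:
        row = {
            "animal_id": a.animal_id,
            "group": a.group,
            "ishak": a.ishak,
            "hydroxyproline": a.hydroxyproline,
            "sirius_red_pct": a.sirius_red_pct,
            "asgpr_rel": a.asgpr_rel,
            "mmp9_rel": a.mmp9_rel,
            "liver_volume_mL": a.liver_volume_mL,
            "injected_MBq": a.injected_MBq,
        }
        row.update({k: getattr(a.kinetics, k) for k in _KINETIC_COLS})
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_from_frame(df: pd.DataFrame) -> list:
    """Rebuild :class:`AnimalRecord` objects from the cohort table."""
    animals = []
    for _, r in df.iterrows():
        kin = KineticParams(**{k: float(r[k]) for k in _KINETIC_COLS})
        animals.append(
            AnimalRecord(
                animal_id=str(r["animal_id"]),
                group=str(r["group"]),
                ishak=int(r["ishak"]),
                hydroxyproline=float(r["hydroxyproline"]),
                sirius_red_pct=float(r["sirius_red_pct"]),
                asgpr_rel=float(r["asgpr_rel"]),
                mmp9_rel=float(r["mmp9_rel"]),
                liver_volume_mL=float(r["liver_volume_mL"]),
                injected_MBq=float(r["injected_MBq"]),
                kinetics=kin,
            )
        )
    return animals
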