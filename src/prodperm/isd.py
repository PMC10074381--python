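"""Inhomogeneous solubility-diffusion (Diamond-Katz) permeation model.

Given a free-energy profile dG(z) across the bilayer (referenced to
bulk water) and a local diffusivity D(z), two scalars characterize the
permeant:

* the membrane/water partition coefficient, taken directly from the
  global minimum of the profile,

      log10 K = -dG(min) / (R T ln 10)

  (a positive minimum -- no favorable region in the membrane -- gives a
  negative log K);

* the steady-state permeability from the depth-integrated resistance

      1 / P = integral over the membrane span of dz / (K(z) D(z)),
      K(z) = exp(-dG(z) / R T)

  evaluated with the composite trapezoid rule on the layer grid (depths
  converted A -> cm, so P is in cm/s).

Multiple membrane snapshots are aggregated as arithmetic mean +- sample
standard deviation on the log10 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .profiles import MembraneProfile

__all__ = ["R_KCAL_PER_MOL_K", "CM_PER_ANGSTROM", "PhysicalSettings",
           "SnapshotValues", "PermeationResult", "DeltaLog",
           "partition_from_profile", "permeability_from_profile",
           "run_snapshots", "delta_log"]

#: universal gas constant in kcal mol^-1 K^-1
R_KCAL_PER_MOL_K = 1.9872e-3
CM_PER_ANGSTROM = 1.0e-8
LN10 = math.log(10.0)


@dataclass(frozen=True)
class PhysicalSettings:
    """Thermodynamic conditions of the calculation."""

    temperature: float = 293.0  # K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")

    @property
    def RT(self) -> float:
        """R*T in kcal/mol."""
        return R_KCAL_PER_MOL_K * self.temperature

    @property
    def decade(self) -> float:
        """Free energy per factor of 10 in K or P: R*T*ln(10), kcal/mol."""
        return self.RT * LN10


def partition_from_profile(
    profile: MembraneProfile, settings: PhysicalSettings = PhysicalSettings()
) -> tuple[float, float]:
    """(log10 K, dG_min): partitioning from the profile's global minimum."""
    dG_min = float(np.min(profile.dG))
    return -dG_min / settings.decade, dG_min


def permeability_from_profile(
    profile: MembraneProfile, settings: PhysicalSettings = PhysicalSettings()
) -> float:
    """log10 of the permeability (cm/s) across the full profile span.

    The resistance integrand exp(dG/RT)/D is integrated by the
    composite trapezoid rule over the supplied grid; bulk-water layers
    at the edges contribute negligibly since there dG ~ 0 and
    D = D_water.
    """
    integrand = np.exp(profile.dG / settings.RT) / profile.D
    resistance = float(np.trapezoid(integrand, profile.z * CM_PER_ANGSTROM))
    if resistance <= 0:  # pragma: no cover - guarded by profile validation
        raise ValueError("non-positive resistance integral")
    return -math.log10(resistance)


@dataclass(frozen=True)
class SnapshotValues:
    snapshot_id: int
    logK: float
    logPerm: float
    dG_min: float


@dataclass(frozen=True)
class PermeationResult:
    """log K and log Perm with snapshot mean +- sample sd.

    ``per_snapshot`` is empty when the result was constructed from a
    published summary table rather than from profiles; ``single_snapshot``
    flags sd values that are zero only because n = 1.
    """

    name: str
    logK_mean: float
    logK_sd: float | None
    logPerm_mean: float
    logPerm_sd: float | None
    dG_min: float | None = None
    per_snapshot: tuple[SnapshotValues, ...] = ()
    single_snapshot: bool = False

    @classmethod
    def from_summary(
        cls,
        name: str,
        logK: float,
        logPerm: float,
        logK_sd: float | None = None,
        logPerm_sd: float | None = None,
    ) -> "PermeationResult":
        return cls(name=name, logK_mean=logK, logK_sd=logK_sd,
                   logPerm_mean=logPerm, logPerm_sd=logPerm_sd)


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd


def run_snapshots(
    profiles: Sequence[MembraneProfile],
    settings: PhysicalSettings = PhysicalSettings(),
    name: str = "",
) -> PermeationResult:
    """Aggregate log K / log Perm over membrane snapshots.

    All profiles must share an identical depth grid (they are snapshots
    of the same membrane).  Mean and sample standard deviation are taken
    on the log10 scale, matching the usual mean +- sd presentation of
    log quantities.
    """
    if not profiles:
        raise ValueError("run_snapshots requires at least one profile")
    z0 = profiles[0].z
    for p in profiles[1:]:
        if p.z.shape != z0.shape or not np.array_equal(p.z, z0):
            raise ValueError("snapshot profiles must share an identical depth grid")
    per = []
    for p in profiles:
        logK, dG_min = partition_from_profile(p, settings)
        logPerm = permeability_from_profile(p, settings)
        per.append(SnapshotValues(p.snapshot_id, logK, logPerm, dG_min))
    logK_mean, logK_sd = _mean_sd([s.logK for s in per])
    logPerm_mean, logPerm_sd = _mean_sd([s.logPerm for s in per])
    return PermeationResult(
        name=name,
        logK_mean=logK_mean,
        logK_sd=logK_sd,
        logPerm_mean=logPerm_mean,
        logPerm_sd=logPerm_sd,
        dG_min=float(np.mean([s.dG_min for s in per])),
        per_snapshot=tuple(per),
        single_snapshot=len(per) == 1,
    )


@dataclass(frozen=True)
class DeltaLog:
    """Parent-minus-prodrug shifts with error propagation."""

    dlogK: float
    dlogPerm: float
    sd_dlogK: float | None
    sd_dlogPerm: float | None


def _propagate(sd1: float | None, sd2: float | None) -> float | None:
    if sd1 is None or sd2 is None:
        return None
    return math.hypot(sd1, sd2)


def delta_log(parent: PermeationResult, prodrug: PermeationResult) -> DeltaLog:
    """Shift (parent mean - prodrug mean) in log K and log Perm.

    Positive values mean the prodrug modification *reduced* the
    quantity.  Standard deviations propagate in quadrature.
    """
    return DeltaLog(
        dlogK=parent.logK_mean - prodrug.logK_mean,
        dlogPerm=parent.logPerm_mean - prodrug.logPerm_mean,
        sd_dlogK=_propagate(parent.logK_sd, prodrug.logK_sd),
        sd_dlogPerm=_propagate(parent.logPerm_sd, prodrug.logPerm_sd),
    )
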