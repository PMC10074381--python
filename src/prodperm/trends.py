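"""Homologous-series trends, inverse chain-length design, adduct scenarios.

For a prodrug family differing only by hydrocarbon chain length, log
Perm (and eventually log K) grows almost linearly with the number of
added carbons.  This module quantifies that growth as per-two-carbon
increments plus a least-squares line, inverts the trend to pick the
chain length that lands a target permeability window, and classifies
the effect of a polar (fructose) adduct on a parent drug into the
permeability-only / partitioning-only / both / neither scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .isd import DeltaLog, PermeationResult, delta_log

__all__ = ["SeriesTrend", "series_increments", "ChainDesign",
           "design_chain_length", "FructoseScenario", "FructoseEffect",
           "fructose_effect"]


@dataclass(frozen=True)
class SeriesTrend:
    """Per-2-carbon increments and linear fit for one homologous series."""

    points: tuple[tuple[int, float], ...]
    increments_per_2C: tuple[float, ...]
    mean_increment: float
    sd_increment: float          # sample sd; 0 when only one increment
    slope: float                 # least-squares slope per carbon
    intercept: float


def series_increments(points: Sequence[tuple[int, float]]) -> SeriesTrend:
    """Increment statistics and least-squares fit over (n_carbons, value).

    Increments between consecutive points are rescaled to per-2-carbon
    units, so unevenly spaced series are handled consistently.  The
    slope/intercept are the ordinary least-squares line in carbons.
    """
    if len(points) < 2:
        raise ValueError("a series trend needs at least 2 points")
    ns = [int(n) for n, _ in points]
    if len(set(ns)) != len(ns):
        raise ValueError("duplicate chain lengths in series")
    if any(b <= a for a, b in zip(ns, ns[1:])):
        raise ValueError("chain lengths must be strictly increasing")
    vals = [float(v) for _, v in points]
    increments = tuple(
        (v2 - v1) / ((n2 - n1) / 2.0)
        for (n1, v1), (n2, v2) in zip(points, points[1:])
    )
    arr = np.asarray(increments)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    slope, intercept = np.polyfit(ns, vals, 1)
    return SeriesTrend(
        points=tuple((int(n), float(v)) for n, v in points),
        increments_per_2C=increments,
        mean_increment=mean,
        sd_increment=sd,
        slope=float(slope),
        intercept=float(intercept),
    )


@dataclass(frozen=True)
class ChainDesign:
    """Outcome of inverse chain-length design."""

    n: int | None          # carbons to add; None when unreachable
    reason: str

    @property
    def reachable(self) -> bool:
        return self.n is not None


def design_chain_length(
    parent_value: float,
    target: tuple[float, float],
    trend: SeriesTrend | float,
    step: int = 2,
    max_carbons: int = 100,
) -> ChainDesign:
    """Smallest chain length whose extrapolated value lands in ``target``.

    Extrapolation is linear in carbon count, anchored at the parent:
    value(n) = parent_value + slope * n, with slope taken per carbon
    from ``trend`` (a :class:`SeriesTrend` or a bare slope).  ``n``
    steps by ``step`` carbons following the series convention; n = 0 is
    returned when the parent already meets the target.
    """
    lo, hi = target
    if not (math.isfinite(lo) and math.isfinite(hi)) or lo > hi:
        raise ValueError(f"invalid target interval {target!r}")
    slope = trend.slope if isinstance(trend, SeriesTrend) else float(trend)
    if lo <= parent_value <= hi:
        return ChainDesign(0, "parent already inside the target interval")
    if slope == 0.0:
        return ChainDesign(None, "zero slope: extrapolation cannot move the value")
    if (slope > 0 and parent_value > hi) or (slope < 0 and parent_value < lo):
        return ChainDesign(None, "slope moves the value away from the target")
    for n in range(step, max_carbons + 1, step):
        value = parent_value + slope * n
        if lo <= value <= hi:
            return ChainDesign(n, f"extrapolated value {value:.3f} inside target")
        if (slope > 0 and value > hi) or (slope < 0 and value < lo):
            return ChainDesign(
                None,
                f"step of {step} carbons overshoots the target interval at n={n}",
            )
    return ChainDesign(None, f"target not reached within {max_carbons} carbons")


class FructoseScenario(str, Enum):
    PERMEABILITY_ONLY = "permeability_only"
    PARTITIONING_ONLY = "partitioning_only"
    BOTH = "both"
    NEITHER = "neither"


@dataclass(frozen=True)
class FructoseEffect:
    scenario: FructoseScenario
    delta: DeltaLog
    perm_significant: bool
    partition_significant: bool


def fructose_effect(
    parent: PermeationResult,
    adduct: PermeationResult,
    k_sigma: float = 2.0,
) -> FructoseEffect:
    """Classify a polar-adduct effect into one of four scenarios.

    A *reduction* (parent minus adduct, positive) in log Perm or log K
    is called significant when it exceeds ``k_sigma`` times the
    propagated snapshot standard deviation.  Requires both results to
    carry standard deviations.
    """
    d = delta_log(parent, adduct)
    if d.sd_dlogK is None or d.sd_dlogPerm is None:
        raise ValueError(
            "fructose_effect needs standard deviations on both results; "
            "recompute from snapshot-level profiles or supply summary sds"
        )
    perm_sig = d.dlogPerm > k_sigma * d.sd_dlogPerm
    part_sig = d.dlogK > k_sigma * d.sd_dlogK
    scenario = {
        (True, True): FructoseScenario.BOTH,
        (True, False): FructoseScenario.PERMEABILITY_ONLY,
        (False, True): FructoseScenario.PARTITIONING_ONLY,
        (False, False): FructoseScenario.NEITHER,
    }[(perm_sig, part_sig)]
    return FructoseEffect(scenario, d, perm_sig, part_sig)
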