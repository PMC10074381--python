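"""Synthetic layered membrane free-energy / diffusivity profiles.

Real permeant free-energy profiles across a phospholipid bilayer show a
bulk-water plateau at zero, an interfacial minimum near +-20 A from the
bilayer center (head-group / glycerol region), and a central barrier at
z = 0 whose height falls and whose wells deepen as lipophilic chains
are added to the permeant.  This module emulates those features with a
few-parameter Gaussian shape

    dG(z) = B exp(-z^2 / 2 w_b^2)
            - m [exp(-(|z|-p)^2 / 2 w_m^2) + exp(-(|z|+p)^2 / 2 w_m^2)]
            - (edge value)            # so dG(+-Z) == 0 exactly

plus optional per-layer Gaussian noise that differs between membrane
"snapshots" (seeded, reproducible).  The diffusivity D(z) interpolates
sigmoidally between a bulk-water value outside the membrane and a
scaled-down value inside; it is strictly positive everywhere.

All depths are in Angstrom, energies in kcal/mol, diffusivities in
cm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = ["ProfileShapeParams", "MembraneProfile", "shape_dG", "shape_D",
           "synth_profile", "synth_snapshot_set", "synth_homologous_series",
           "symmetric_grid"]

EDGE_TOL_NOISE_FREE = 1e-6  # kcal/mol


@dataclass(frozen=True)
class ProfileShapeParams:
    """Shape parameters of a synthetic profile.

    Defaults emulate a poorly permeating polar drug in a gel-phase
    bilayer: a 19 kcal/mol central barrier, no interfacial well, wells
    centred at +-20 A when present, a +-40 A water-to-water span sliced
    into 50 layers.
    """

    barrier_height: float = 19.0   # kcal/mol at z = 0
    barrier_width: float = 8.0     # Gaussian sigma, A
    min_depth: float = 0.0         # magnitude of interfacial well, kcal/mol, >= 0
    min_position: float = 20.0     # well centre, A from bilayer center
    min_width: float = 4.0         # well Gaussian sigma, A
    half_span: float = 40.0        # Z: grid spans [-Z, +Z], A
    layers: int = 50
    noise_sd: float = 0.0          # per-layer snapshot noise, kcal/mol
    seed: int = 0
    D_water: float = 5.0e-6        # bulk water diffusivity, cm^2/s
    D_membrane_scale: float = 0.1  # D inside membrane = scale * D_water
    temperature: float = 293.0     # K, carried as metadata
    composition: str = "DPPC/DPPG/Chol 75:10:15"

    def __post_init__(self) -> None:
        if self.barrier_width <= 0 or self.half_span <= 0 or self.min_width <= 0:
            raise ValueError("barrier_width, min_width and half_span must be positive")
        if self.layers < 3:
            raise ValueError("need at least 3 layers")
        if self.noise_sd < 0 or self.min_depth < 0:
            raise ValueError("noise_sd and min_depth must be non-negative")
        if self.D_water <= 0 or self.D_membrane_scale <= 0:
            raise ValueError("diffusivities must be positive")


@dataclass
class MembraneProfile:
    """Per-layer depth grid with free energy and diffusivity.

    One snapshot of one membrane.  dG is relative to bulk water, so the
    outermost grid values sit at (approximately, under noise) zero.
    """

    z: np.ndarray          # A, strictly increasing, symmetric span
    dG: np.ndarray         # kcal/mol
    D: np.ndarray          # cm^2/s, > 0
    snapshot_id: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.dG = np.asarray(self.dG, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if self.z.size < 3:
            raise ValueError("profile needs at least 3 layers")
        if not (self.z.size == self.dG.size == self.D.size):
            raise ValueError("z, dG and D must have equal length")
        if not np.all(np.diff(self.z) > 0):
            raise ValueError("depth grid must be strictly increasing")
        if abs(self.z[0] + self.z[-1]) > 1e-9 * max(1.0, abs(self.z[-1])):
            raise ValueError("depth grid must span a symmetric interval about z=0")
        if not np.all(self.D > 0):
            raise ValueError("diffusivity must be positive everywhere")
        if not (np.all(np.isfinite(self.dG)) and np.all(np.isfinite(self.z))):
            raise ValueError("profile values must be finite")

    def check_bulk_reference(self, tol: float = 2.0) -> None:
        """Verify the bulk-water zero reference at both grid edges."""
        edge = max(abs(self.dG[0]), abs(self.dG[-1]))
        if edge > tol:
            raise ValueError(
                f"profile edges deviate from the bulk-water reference by "
                f"{edge:.3g} kcal/mol (tolerance {tol})"
            )

    @property
    def span(self) -> float:
        """Full water-to-water thickness 2L of the grid, in A."""
        return float(self.z[-1] - self.z[0])


def symmetric_grid(half_span: float, layers: int) -> np.ndarray:
    """Strictly increasing grid over [-Z, +Z], exactly mirror-symmetric."""
    z = np.linspace(-half_span, half_span, layers)
    return (z - z[::-1]) / 2.0  # force z[i] == -z[-1-i] bit-exactly


def shape_dG(z: np.ndarray | float, params: ProfileShapeParams) -> np.ndarray | float:
    """Noise-free free-energy shape; exactly zero at |z| = half_span."""
    az = np.abs(z)

    def raw(x):
        barrier = params.barrier_height * np.exp(-(x**2) / (2 * params.barrier_width**2))
        wells = params.min_depth * (
            np.exp(-((x - params.min_position) ** 2) / (2 * params.min_width**2))
            + np.exp(-((x + params.min_position) ** 2) / (2 * params.min_width**2))
        )
        return barrier - wells

    return raw(az) - raw(params.half_span)


def shape_D(z: np.ndarray | float, params: ProfileShapeParams) -> np.ndarray | float:
    """Two-region sigmoidal diffusivity: bulk water outside, scaled inside.

    The transition is centred at the interfacial-well position with a
    2 A width; D is strictly positive by construction.
    """
    az = np.abs(z)
    d_in = params.D_water * params.D_membrane_scale
    frac_water = 1.0 / (1.0 + np.exp(-(az - params.min_position) / 2.0))
    return d_in + (params.D_water - d_in) * frac_water


def synth_profile(params: ProfileShapeParams, snapshot_id: int = 1) -> MembraneProfile:
    """Generate one seeded snapshot profile from shape parameters.

    With ``noise_sd == 0`` the profile is exactly mirror-symmetric about
    z = 0 and exactly zero at both edges.  Noise is drawn from a
    generator keyed on (seed, snapshot_id), so identical parameters give
    bit-identical profiles.
    """
    z = symmetric_grid(params.half_span, params.layers)
    dG = np.asarray(shape_dG(z, params), dtype=float)
    if params.noise_sd > 0:
        rng = np.random.default_rng([params.seed, snapshot_id])
        dG = dG + rng.normal(0.0, params.noise_sd, size=z.size)
    D = np.asarray(shape_D(z, params), dtype=float)
    meta = {
        "temperature_K": params.temperature,
        "composition": params.composition,
        "seed": params.seed,
        "snapshot_id": snapshot_id,
        "params": params,
    }
    return MembraneProfile(z=z, dG=dG, D=D, snapshot_id=snapshot_id, meta=meta)


def synth_snapshot_set(
    params: ProfileShapeParams, n_snapshots: int = 5
) -> list[MembraneProfile]:
    """n profiles differing only by seeded per-layer noise (ids 1..n)."""
    if n_snapshots < 1:
        raise ValueError("n_snapshots must be >= 1")
    return [synth_profile(params, snapshot_id=i) for i in range(1, n_snapshots + 1)]


def synth_homologous_series(
    base: ProfileShapeParams,
    n_carbons_list: Sequence[int],
    barrier_decrement_per_2C: float,
    well_deepening_per_2C: float,
    n_snapshots: int = 5,
) -> dict[int, list[MembraneProfile]]:
    """Profiles for a homologous series of increasingly lipophilic permeants.

    Starting from ``base`` (the parent, zero added carbons), each added
    pair of carbons lowers the central barrier by
    ``barrier_decrement_per_2C`` (floored at zero) and deepens the
    interfacial wells by ``well_deepening_per_2C``.  Returns a map
    n_carbons -> snapshot set.
    """
    if barrier_decrement_per_2C < 0 or well_deepening_per_2C < 0:
        raise ValueError("series decrements must be non-negative")
    if len(set(n_carbons_list)) != len(n_carbons_list):
        raise ValueError("duplicate chain lengths in series")
    out: dict[int, list[MembraneProfile]] = {}
    for n in n_carbons_list:
        if n < 0:
            raise ValueError("chain length must be non-negative")
        steps = n / 2.0
        member = replace(
            base,
            barrier_height=max(0.0, base.barrier_height - steps * barrier_decrement_per_2C),
            min_depth=base.min_depth + steps * well_deepening_per_2C,
            seed=base.seed + n,  # decorrelate noise between series members
        )
        out[n] = synth_snapshot_set(member, n_snapshots)
    return out
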