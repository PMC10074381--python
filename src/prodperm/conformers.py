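"""Conformer diversity filtering: energy window + pairwise-RMSD greedy pick.

Keeps at most ``max_n`` conformers lying within an energy window of the
global minimum while enforcing a minimum pairwise RMSD (after optimal
rigid-body superposition) between all kept geometries.  The selection is
greedy in ascending energy, which makes it deterministic and equal to
the lexicographically-first maximal feasible subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["Conformer", "SelectionRecord", "pairwise_rmsd", "select_conformers",
           "select_conformers_with_log"]

ANGSTROM_PER_NM = 10.0


@dataclass(frozen=True)
class Conformer:
    """One molecular geometry with its (relative or absolute) energy.

    coords are in Angstrom, shape (n_atoms, 3); energy in kcal/mol.
    ``elements`` (symbols, same order as coords) enables heavy-atom RMSD
    selection; when absent all atoms are used.
    """

    id: str
    coords: np.ndarray
    energy: float
    elements: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"conformer {self.id!r}: coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"conformer {self.id!r}: non-finite coordinates")
        if self.elements is not None and len(self.elements) != len(coords):
            raise ValueError(f"conformer {self.id!r}: elements/coords length mismatch")
        object.__setattr__(self, "coords", coords)


def _selection_mask(conf: Conformer, atom_selection: str | Sequence[int]) -> np.ndarray:
    n = len(conf.coords)
    if isinstance(atom_selection, str):
        if atom_selection == "all" or conf.elements is None:
            return np.ones(n, dtype=bool)
        if atom_selection == "heavy":
            return np.array([el != "H" for el in conf.elements])
        raise ValueError(f"unknown atom selection {atom_selection!r}")
    mask = np.zeros(n, dtype=bool)
    mask[list(atom_selection)] = True
    return mask


def pairwise_rmsd(
    a: Conformer, b: Conformer, atom_selection: str | Sequence[int] = "heavy"
) -> float:
    """Minimum RMSD between two geometries, in nm.

    Both coordinate sets are centred and optimally superposed (Kabsch
    rotation) over the selected atoms before the deviation is taken, so
    the result is invariant to any rigid motion of either conformer and
    symmetric in its arguments.
    """
    if len(a.coords) != len(b.coords):
        raise ValueError(
            f"atom count mismatch: {a.id!r} has {len(a.coords)}, "
            f"{b.id!r} has {len(b.coords)}"
        )
    mask = _selection_mask(a, atom_selection)
    pa = a.coords[mask] - a.coords[mask].mean(axis=0)
    pb = b.coords[mask] - b.coords[mask].mean(axis=0)
    if len(pa) == 1:
        return 0.0
    _, rssd = Rotation.align_vectors(pa, pb)
    return float(rssd / math.sqrt(len(pa)) / ANGSTROM_PER_NM)


@dataclass(frozen=True)
class SelectionRecord:
    conformer_id: str
    accepted: bool
    reason: str


def select_conformers_with_log(
    conformers: Sequence[Conformer],
    max_n: int = 10,
    window: float = 5.0,
    rmsd_min: float = 0.2,
    atom_selection: str | Sequence[int] = "heavy",
) -> tuple[list[Conformer], list[SelectionRecord]]:
    """Greedy ascending-energy diversity filter, with a per-conformer log.

    Energies are first normalized relative to the set minimum.  Sorted
    by (relative energy, id), a conformer is accepted iff it lies within
    ``window`` kcal/mol (inclusive) of the minimum and its RMSD to every
    already-accepted conformer is at least ``rmsd_min`` nm, stopping at
    ``max_n``.  Output is sorted by ascending energy; the result does
    not depend on the input ordering.
    """
    if not conformers:
        raise ValueError("select_conformers requires a non-empty conformer set")
    e_min = min(c.energy for c in conformers)
    order = sorted(conformers, key=lambda c: (c.energy - e_min, c.id))
    accepted: list[Conformer] = []
    log: list[SelectionRecord] = []
    for conf in order:
        rel = conf.energy - e_min
        if len(accepted) >= max_n:
            log.append(SelectionRecord(conf.id, False, f"max_n={max_n} reached"))
            continue
        if rel > window:
            log.append(
                SelectionRecord(conf.id, False,
                                f"relative energy {rel:.3f} kcal/mol above window {window}")
            )
            continue
        clash = next(
            (k for k in accepted
             if pairwise_rmsd(conf, k, atom_selection) < rmsd_min),
            None,
        )
        if clash is not None:
            log.append(
                SelectionRecord(conf.id, False,
                                f"RMSD to accepted {clash.id!r} below {rmsd_min} nm")
            )
            continue
        accepted.append(conf)
        log.append(SelectionRecord(conf.id, True, "accepted"))
    return accepted, log


def select_conformers(
    conformers: Sequence[Conformer],
    max_n: int = 10,
    window: float = 5.0,
    rmsd_min: float = 0.2,
    atom_selection: str | Sequence[int] = "heavy",
) -> list[Conformer]:
    """As :func:`select_conformers_with_log`, returning only the kept set."""
    return select_conformers_with_log(
        conformers, max_n=max_n, window=window, rmsd_min=rmsd_min,
        atom_selection=atom_selection,
    )[0]
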