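"""File formats: profile TSVs, results CSVs, SMILES files, conformer sets.

Every writer prepends '#'-prefixed provenance lines (package version,
seed, config hash where applicable); readers skip them.  Decimal points
are always '.' regardless of locale, and malformed numeric fields are
rejected with row-numbered errors.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .chem import GeneratedStructure
from .conformers import Conformer
from .isd import PermeationResult
from .profiles import MembraneProfile

__all__ = [
    "write_profile_tsv", "read_profile_tsv",
    "write_results_csv", "read_results_csv",
    "write_smiles_file", "write_manifest_csv",
    "read_conformers_sdf", "write_conformers_sdf",
    "read_conformers_xyz_csv",
]

PROFILE_COLUMNS = ("z_angstrom", "dG_kcal_mol", "D_cm2_s")


def _meta_lines(meta: Mapping) -> list[str]:
    lines = [f"# prodperm_version: {__version__}"]
    for key, value in meta.items():
        if key == "params":
            value = repr(value)
        lines.append(f"# {key}: {value}")
    return lines


def write_profile_tsv(profile: MembraneProfile, path: str | Path) -> None:
    """One snapshot per file: '#' metadata header then three TSV columns."""
    path = Path(path)
    lines = _meta_lines(profile.meta or {"snapshot_id": profile.snapshot_id})
    lines.append("\t".join(PROFILE_COLUMNS))
    for z, dG, D in zip(profile.z, profile.dG, profile.D):
        # float() + repr(): locale-independent, shortest lossless decimal
        lines.append(f"{float(z)!r}\t{float(dG)!r}\t{float(D)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_profile_tsv(path: str | Path) -> MembraneProfile:
    path = Path(path)
    meta: dict = {}
    rows: list[tuple[float, float, float]] = []
    header_seen = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
            continue
        fields = line.split("\t")
        if not header_seen:
            if tuple(fields) != PROFILE_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected header {PROFILE_COLUMNS}, got {fields}"
                )
            header_seen = True
            continue
        try:
            rows.append(tuple(float(f) for f in fields))
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed numeric field in {fields}") from None
    if not rows:
        raise ValueError(f"{path}: no profile data rows")
    arr = np.asarray(rows)
    snapshot_id = int(meta.get("snapshot_id", 1))
    return MembraneProfile(z=arr[:, 0], dG=arr[:, 1], D=arr[:, 2],
                           snapshot_id=snapshot_id, meta=meta)


def write_results_csv(
    results: Sequence[PermeationResult],
    path: str | Path,
    meta: Mapping | None = None,
    extra_columns: Mapping[str, Sequence] | None = None,
) -> None:
    """Aggregated results table mirroring the mean +- sd layout."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        for line in _meta_lines(meta or {}):
            fh.write(line + "\n")
        fieldnames = ["name", "logK", "logK_sd", "logPerm", "logPerm_sd"]
        extra = dict(extra_columns or {})
        fieldnames += list(extra)
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for i, r in enumerate(results):
            row = {
                "name": r.name,
                "logK": repr(r.logK_mean),
                "logK_sd": "" if r.logK_sd is None else repr(r.logK_sd),
                "logPerm": repr(r.logPerm_mean),
                "logPerm_sd": "" if r.logPerm_sd is None else repr(r.logPerm_sd),
            }
            for col, values in extra.items():
                row[col] = values[i]
            writer.writerow(row)


def read_results_csv(path: str | Path) -> list[PermeationResult]:
    path = Path(path)
    results = []
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    data_lines = [l for l in lines if not l.startswith("#")]
    reader = csv.DictReader(data_lines)
    for rowno, row in enumerate(reader, start=2):
        try:
            results.append(PermeationResult.from_summary(
                row["name"],
                float(row["logK"]),
                float(row["logPerm"]),
                logK_sd=float(row["logK_sd"]) if row.get("logK_sd") else None,
                logPerm_sd=float(row["logPerm_sd"]) if row.get("logPerm_sd") else None,
            ))
        except (KeyError, ValueError):
            raise ValueError(f"{path}: malformed numeric value in data row {rowno}") from None
    return results


def write_smiles_file(structures: Sequence[GeneratedStructure], path: str | Path) -> None:
    """One 'SMILES<TAB>name' record per line (.smi convention)."""
    Path(path).write_text(
        "".join(f"{s.smiles}\t{s.name}\n" for s in structures)
    )


def write_manifest_csv(
    structures: Sequence[GeneratedStructure], path: str | Path,
    meta: Mapping | None = None,
) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        for line in _meta_lines(meta or {}):
            fh.write(line + "\n")
        writer = csv.writer(fh)
        writer.writerow(["name", "canonical_smiles", "formula", "modification",
                         "site", "chain_carbons"])
        for s in structures:
            writer.writerow([s.name, s.smiles, s.formula, s.modification,
                             s.site, "" if s.chain_carbons is None else s.chain_carbons])


def read_conformers_sdf(path: str | Path, energy_prop: str = "energy_kcal_mol"
                        ) -> list[Conformer]:
    """Read a multi-record SDF; energies from a named SD property."""
    from rdkit import Chem

    conformers = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"{path}: record {i + 1} does not parse")
        if not mol.HasProp(energy_prop):
            raise ValueError(f"{path}: record {i + 1} lacks property {energy_prop!r}")
        conf = mol.GetConformer()
        coords = np.array([list(conf.GetAtomPosition(a)) for a in range(mol.GetNumAtoms())])
        name = mol.GetProp("_Name") or f"conf{i + 1}"
        conformers.append(Conformer(
            id=name,
            coords=coords,
            energy=float(mol.GetProp(energy_prop)),
            elements=tuple(a.GetSymbol() for a in mol.GetAtoms()),
        ))
    return conformers


def write_conformers_sdf(
    conformers: Sequence[Conformer], template_smiles: str, path: str | Path,
    energy_prop: str = "energy_kcal_mol",
) -> None:
    """Write conformers of one molecule (given as SMILES template) to SDF."""
    from rdkit import Chem
    from rdkit.Chem import AllChem
    from rdkit.Geometry import Point3D

    template = Chem.AddHs(Chem.MolFromSmiles(template_smiles))
    writer = Chem.SDWriter(str(path))
    try:
        for c in conformers:
            mol = Chem.Mol(template)
            if mol.GetNumAtoms() != len(c.coords):
                raise ValueError(
                    f"conformer {c.id!r}: {len(c.coords)} coordinates for a "
                    f"{mol.GetNumAtoms()}-atom template"
                )
            conf = Chem.Conformer(mol.GetNumAtoms())
            for a, (x, y, z) in enumerate(c.coords):
                conf.SetAtomPosition(a, Point3D(x, y, z))
            mol.AddConformer(conf)
            mol.SetProp("_Name", c.id)
            mol.SetProp(energy_prop, repr(c.energy))
            writer.write(mol)
    finally:
        writer.close()


def read_conformers_xyz_csv(xyz_path: str | Path, csv_path: str | Path
                            ) -> list[Conformer]:
    """Read a concatenated multi-XYZ file plus an id,energy CSV.

    The XYZ comment line of each block is the conformer id; the CSV has
    columns conformer_id, energy_kcal_mol.
    """
    energies: dict[str, float] = {}
    df = pd.read_csv(csv_path)
    for rowno, row in enumerate(df.itertuples(), start=2):
        try:
            energies[str(row.conformer_id)] = float(row.energy_kcal_mol)
        except (AttributeError, ValueError):
            raise ValueError(f"{csv_path}: malformed row {rowno}") from None

    conformers = []
    lines = Path(xyz_path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        natoms = int(lines[i])
        cid = lines[i + 1].strip()
        block = lines[i + 2:i + 2 + natoms]
        elements, coords = [], []
        for ln in block:
            sym, x, y, z = ln.split()[:4]
            elements.append(sym)
            coords.append((float(x), float(y), float(z)))
        if cid not in energies:
            raise ValueError(f"{xyz_path}: conformer {cid!r} missing from energy CSV")
        conformers.append(Conformer(
            id=cid, coords=np.array(coords), energy=energies[cid],
            elements=tuple(elements),
        ))
        i += 2 + natoms
    return conformers
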