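"""Packaged reference data: result tables, parent drugs, study catalog.

The two result tables carry the published partitioning/permeation
summary values (log10 scale, mean +- sd over five membrane snapshots)
exactly as printed; they are inputs for trend and adduct-effect
analysis, not quantities this package recomputes.  Integrity of the
packaged files is guarded by SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

from .chem import ParentMolecule, Site, SiteKind
from .isd import PermeationResult

__all__ = ["ResultsTable", "load_fixture", "load_parents", "load_study_catalog",
           "FixtureError"]


class FixtureError(RuntimeError):
    """A packaged fixture is missing or corrupted."""


_CHECKSUMS = {
    "table1.csv": "e29e9ffb93fa03afdada9174e3aea9c4d95b5f575eceb8b3d76e5996e577b0ef",
    "table2.csv": "7e12af866d3ed188c5173cb807a1ddb229346e68c5bd3a3ec8ca129ccad90b25",
}


def _read_data(filename: str) -> bytes:
    ref = resources.files("prodperm.data").joinpath(filename)
    try:
        return ref.read_bytes()
    except FileNotFoundError:
        raise FixtureError(f"packaged fixture {filename!r} not found") from None


@dataclass(frozen=True)
class ResultsTable:
    """A summary table of (name, logK +- sd, logPerm +- sd) rows."""

    name: str
    df: pd.DataFrame

    def result(self, molecule: str) -> PermeationResult:
        rows = self.df[self.df["name"] == molecule]
        if rows.empty:
            raise KeyError(f"{molecule!r} not in fixture {self.name!r}")
        r = rows.iloc[0]
        return PermeationResult.from_summary(
            molecule, float(r.logK), float(r.logPerm),
            logK_sd=float(r.logK_sd), logPerm_sd=float(r.logPerm_sd),
        )

    def series(self, series_name: str) -> list[tuple[int, float]]:
        """(n_carbons, logPerm) points of one homologous series."""
        sub = self.df[self.df.get("series") == series_name].sort_values("n_carbons")
        return [(int(n), float(v)) for n, v in zip(sub.n_carbons, sub.logPerm)]


def load_fixture(table: str) -> ResultsTable:
    """Load a packaged results table ('table1' or 'table2')."""
    if table not in ("table1", "table2"):
        raise FixtureError(f"unknown fixture table {table!r}; use 'table1' or 'table2'")
    filename = f"{table}.csv"
    raw = _read_data(filename)
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[filename]:
        raise FixtureError(
            f"fixture {filename} failed its checksum "
            f"(got {digest[:12]}..., expected {_CHECKSUMS[filename][:12]}...)"
        )
    return ResultsTable(table, pd.read_csv(io.BytesIO(raw)))


def load_parents() -> dict[str, ParentMolecule]:
    """Packaged parent drugs with their annotated derivatization sites."""
    data = yaml.safe_load(_read_data("parents.yaml"))
    parents = {}
    for name, spec in data.items():
        sites = {
            label: Site(kind=SiteKind(s["kind"]), atom_index=int(s["atom_index"]))
            for label, s in spec["sites"].items()
        }
        parents[name] = ParentMolecule(name=name, smiles=spec["smiles"], sites=sites)
    return parents


def load_study_catalog() -> dict:
    """The packaged study design (series ranges, adducts, parent list)."""
    return yaml.safe_load(_read_data("study_catalog.yaml"))
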