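"""Prodrug enumeration by fragment condensation on annotated parent drugs.

A parent drug is a SMILES string plus a table of named derivatization
sites (hydroxyl oxygens, amine nitrogens, aromatic CH carbons).  The
operations in this module generate the classical prodrug families:

* acyl esters      -- O-H  ->  O-C(=O)-(CH2)_{n-2}-CH3   (net +CnH2n-2O)
* acyl amides      -- N-H  ->  N-C(=O)-(CH2)_{n-2}-CH3   (net +CnH2n-2O)
* alkyl chains     -- ring C-H -> C-(CH2)_{n-1}-CH3      (net +CnH2n)
* fructose adducts -- condensation with D-fructose, one water lost
                      (net +C6H10O5)

where ``n`` counts the carbons of the attached acid (ester/amide) or of
the alkyl chain.  All products are returned as canonical SMILES with a
Hill-notation molecular formula; duplicate detection within an
enumerated study set is by canonical SMILES (stereo included where the
inputs define it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

__all__ = [
    "SiteKind",
    "Site",
    "ParentMolecule",
    "GeneratedStructure",
    "DerivatizationError",
    "FRUCTOSYL_BETA_FURANOSE",
    "make_ester",
    "make_amide",
    "make_alkyl",
    "make_fructose_adduct",
    "enumerate_study_set",
]


class DerivatizationError(ValueError):
    """A derivatization request violated a structural precondition."""


class SiteKind(str, Enum):
    """Kind of reactive position on a parent drug."""

    HYDROXYL = "hydroxyl"
    PRIMARY_AMINE = "primary-amine"
    AROMATIC_CH = "aromatic-CH"


@dataclass(frozen=True)
class Site:
    """A named derivatization site: its chemical kind and the atom index
    in the parent's stored SMILES atom ordering."""

    kind: SiteKind
    atom_index: int


#: beta-D-fructofuranosyl fragment, open valence at the anomeric C2
#: (the default attachment atom: condensation through the anomeric
#: hydroxyl makes the +C6H10O5 formula delta exact).
FRUCTOSYL_BETA_FURANOSE = "*[C@]1(CO)O[C@H](CO)[C@@H](O)[C@@H]1O"


def _check_site_atom(mol: Chem.Mol, label: str, site: Site) -> None:
    if not 0 <= site.atom_index < mol.GetNumAtoms():
        raise DerivatizationError(
            f"site {label!r}: atom index {site.atom_index} out of range"
        )
    atom = mol.GetAtomWithIdx(site.atom_index)
    kind = site.kind
    if kind is SiteKind.HYDROXYL:
        ok = atom.GetSymbol() == "O" and atom.GetTotalNumHs() >= 1 and atom.GetDegree() == 1
        what = "an O-H hydroxyl oxygen"
    elif kind is SiteKind.PRIMARY_AMINE:
        # Primary amines carry two hydrogens; amide-like ring N-H sites
        # (one hydrogen) are registered under the same kind because the
        # condensation chemistry is identical (one N-H replaced).
        ok = atom.GetSymbol() == "N" and atom.GetTotalNumHs() >= 1
        what = "a nitrogen carrying at least one hydrogen"
    elif kind is SiteKind.AROMATIC_CH:
        ok = atom.GetSymbol() == "C" and atom.GetIsAromatic() and atom.GetTotalNumHs() == 1
        what = "an aromatic carbon with exactly one hydrogen"
    else:  # pragma: no cover - enum is closed
        raise DerivatizationError(f"unknown site kind {kind!r}")
    if not ok:
        raise DerivatizationError(
            f"site {label!r}: atom {site.atom_index} "
            f"({atom.GetSymbol()}, {atom.GetTotalNumHs()} H) is not {what}"
        )


@dataclass
class ParentMolecule:
    """A parent drug structure with named derivatization sites.

    Parameters
    ----------
    name : str
        Display name, e.g. ``"cytarabine"``.
    smiles : str
        Structure; atom indices in ``sites`` refer to this string's
        atom ordering as parsed.
    sites : mapping of str -> Site
        Unique labels for each registered reactive position.
    """

    name: str
    smiles: str
    sites: Mapping[str, Site] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise DerivatizationError(f"{self.name}: SMILES {self.smiles!r} does not parse")
        for label, site in self.sites.items():
            _check_site_atom(mol, label, site)

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)

    @property
    def formula(self) -> str:
        return rdMolDescriptors.CalcMolFormula(self.mol)

    def site(self, label: str) -> Site:
        try:
            return self.sites[label]
        except KeyError:
            raise DerivatizationError(
                f"{self.name}: unknown site label {label!r}; "
                f"known sites: {sorted(self.sites)}"
            ) from None


@dataclass(frozen=True)
class GeneratedStructure:
    """One enumerated structure: canonical SMILES plus provenance."""

    name: str
    smiles: str
    formula: str
    provenance: str
    modification: str = "parent"
    site: str = ""
    chain_carbons: int | None = None


def _as_generated(parent: ParentMolecule) -> GeneratedStructure:
    mol = parent.mol
    return GeneratedStructure(
        name=parent.name,
        smiles=Chem.MolToSmiles(mol),
        formula=rdMolDescriptors.CalcMolFormula(mol),
        provenance="parent",
    )


def _attach_fragment(
    parent: ParentMolecule,
    label: str,
    expected_kinds: Sequence[SiteKind],
    frag_smiles: str,
    *,
    name: str,
    modification: str,
    chain_carbons: int | None,
) -> GeneratedStructure:
    """Replace one H on the site atom by the fragment (dummy-atom SMILES)."""
    site = parent.site(label)
    if site.kind not in expected_kinds:
        kinds = " or ".join(k.value for k in expected_kinds)
        raise DerivatizationError(
            f"{parent.name}/{label}: {modification} requires a {kinds} site, "
            f"got {site.kind.value}"
        )
    frag = Chem.MolFromSmiles(frag_smiles)
    if frag is None or sum(a.GetAtomicNum() == 0 for a in frag.GetAtoms()) != 1:
        raise DerivatizationError(
            f"invalid attachment fragment {frag_smiles!r}: need exactly one dummy atom"
        )
    combo = Chem.RWMol(Chem.CombineMols(parent.mol, frag))
    dummy = next(a.GetIdx() for a in combo.GetAtoms() if a.GetAtomicNum() == 0)
    attach = combo.GetAtomWithIdx(dummy).GetNeighbors()[0].GetIdx()
    site_atom = combo.GetAtomWithIdx(site.atom_index)
    if site_atom.GetNumExplicitHs() > 0:
        site_atom.SetNumExplicitHs(site_atom.GetNumExplicitHs() - 1)
    combo.AddBond(site.atom_index, attach, Chem.BondType.SINGLE)
    combo.RemoveAtom(dummy)
    product = combo.GetMol()
    Chem.SanitizeMol(product)
    return GeneratedStructure(
        name=name,
        smiles=Chem.MolToSmiles(product),
        formula=rdMolDescriptors.CalcMolFormula(product),
        provenance=f"{modification} of {parent.name} at {label}",
        modification=modification,
        site=label,
        chain_carbons=chain_carbons,
    )


def make_ester(
    parent: ParentMolecule, site: str, n: int, *, name: str | None = None
) -> GeneratedStructure:
    """Esterify a hydroxyl site with the linear saturated n-carbon acid.

    The O-H is condensed with CH3-(CH2)_{n-2}-COOH, eliminating water;
    the net formula change relative to the parent is +CnH2n-2O.
    ``n`` must be at least 2 (the acid needs a carbon tail beyond the
    carbonyl).
    """
    if n < 2:
        raise DerivatizationError(
            f"ester chain_carbons must be >= 2 (acid carbonyl plus tail); got n={n}"
        )
    return _attach_fragment(
        parent,
        site,
        (SiteKind.HYDROXYL,),
        "*C(=O)" + "C" * (n - 1),
        name=name or f"{parent.name}-ester-C{n}",
        modification="ester",
        chain_carbons=n,
    )


def make_amide(
    parent: ParentMolecule, site: str, n: int, *, name: str | None = None
) -> GeneratedStructure:
    """Acylate an amine site with the linear n-carbon acid (amide bond).

    One N-H is replaced by C(=O)-(CH2)_{n-2}-CH3; net formula change
    +CnH2n-2O.  Requires n >= 2.
    """
    if n < 2:
        raise DerivatizationError(
            f"amide chain_carbons must be >= 2 (acid carbonyl plus tail); got n={n}"
        )
    return _attach_fragment(
        parent,
        site,
        (SiteKind.PRIMARY_AMINE,),
        "*C(=O)" + "C" * (n - 1),
        name=name or f"{parent.name}-amide-C{n}",
        modification="amide",
        chain_carbons=n,
    )


def make_alkyl(
    parent: ParentMolecule, site: str, n: int, *, name: str | None = None
) -> GeneratedStructure:
    """Replace an aromatic ring H by a linear n-carbon alkyl chain.

    Net formula change +CnH2n.  Requires n >= 1.
    """
    if n < 1:
        raise DerivatizationError(f"alkyl chain_carbons must be >= 1; got n={n}")
    return _attach_fragment(
        parent,
        site,
        (SiteKind.AROMATIC_CH,),
        "*" + "C" * n,
        name=name or f"{parent.name}-alkyl-C{n}",
        modification="alkyl",
        chain_carbons=n,
    )


def make_fructose_adduct(
    parent: ParentMolecule,
    site: str,
    *,
    attachment: str = FRUCTOSYL_BETA_FURANOSE,
    name: str | None = None,
) -> GeneratedStructure:
    """Condense the parent with D-fructose, losing one water.

    The default attachment fragment is the beta-fructofuranosyl group
    bonded through its anomeric C2 (the anomeric hydroxyl leaves with
    the site hydrogen), so the net formula change is exactly +C6H10O5.
    Any dummy-atom fragment SMILES may be supplied to override the
    regiochemistry.
    """
    return _attach_fragment(
        parent,
        site,
        (SiteKind.HYDROXYL, SiteKind.PRIMARY_AMINE),
        attachment,
        name=name or f"{parent.name}-fru",
        modification="fructose",
        chain_carbons=None,
    )


_SERIES_MAKERS = {"ester": make_ester, "amide": make_amide, "alkyl": make_alkyl}


def enumerate_study_set(
    catalog: Mapping, parents: Mapping[str, ParentMolecule]
) -> list[GeneratedStructure]:
    """Enumerate the full study set described by a catalog.

    The catalog maps the study design onto the operations above::

        parents: [cytarabine, ...]            # included as-is
        series:                               # homologous series
          - {parent, modification, site, name_pattern, chain_carbons: [...]}
        adducts:                              # fructose adducts
          - {parent, site, name}

    Each unique canonical structure is returned exactly once; two
    distinct names mapping to the same canonical SMILES signal a bad
    catalog and raise :class:`DerivatizationError`.
    """
    generated: list[GeneratedStructure] = []
    for pname in catalog.get("parents", []):
        if pname not in parents:
            raise DerivatizationError(f"catalog parent {pname!r} not registered")
        generated.append(_as_generated(parents[pname]))
    for series in catalog.get("series", []):
        parent = parents[series["parent"]]
        maker = _SERIES_MAKERS[series["modification"]]
        for n in series["chain_carbons"]:
            generated.append(
                maker(parent, series["site"], n, name=series["name_pattern"].format(n=n))
            )
    for adduct in catalog.get("adducts", []):
        parent = parents[adduct["parent"]]
        generated.append(
            make_fructose_adduct(parent, adduct["site"], name=adduct["name"])
        )

    unique: dict[str, GeneratedStructure] = {}
    for g in generated:
        seen = unique.get(g.smiles)
        if seen is None:
            unique[g.smiles] = g
        elif seen.name != g.name:
            raise DerivatizationError(
                f"catalog names {seen.name!r} and {g.name!r} describe the same "
                f"canonical structure {g.smiles}"
            )
    return list(unique.values())
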