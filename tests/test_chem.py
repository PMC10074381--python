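"""Prodrug derivatization: formula deltas, canonical uniqueness, errors."""

import re

import pytest
from rdkit import Chem

from prodperm import (
    DerivatizationError, ParentMolecule, Site, SiteKind, enumerate_study_set,
    make_alkyl, make_amide, make_ester, make_fructose_adduct,
)

# ---------------------------------------------------------------- oracle

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_counts(formula: str) -> dict:
    """Independent Hill-formula parser used as the arithmetic oracle."""
    counts: dict = {}
    for el, num in _FORMULA_RE.findall(formula):
        if el:
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    return counts


def formula_delta(parent_formula: str, product_formula: str) -> dict:
    p, q = formula_counts(parent_formula), formula_counts(product_formula)
    return {el: q.get(el, 0) - p.get(el, 0)
            for el in set(p) | set(q)
            if q.get(el, 0) - p.get(el, 0) != 0}


def test_formula_oracle_sanity():
    assert formula_counts("C9H13N3O5") == {"C": 9, "H": 13, "N": 3, "O": 5}
    assert formula_delta("C9H13N3O5", "C11H15N3O6") == {"C": 2, "H": 2, "O": 1}


# ------------------------------------------------- worked formula examples

@pytest.mark.parametrize(
    "op, site, n, expected_formula",
    [
        (make_ester, "O5prime", 2, "C11H15N3O6"),
        (make_ester, "O5prime", 16, "C25H43N3O6"),
        (make_amide, "N4amine", 2, "C11H15N3O6"),
        (make_amide, "N4amine", 10, "C19H31N3O6"),
        (make_alkyl, "C5ring", 2, "C11H17N3O5"),
        (make_alkyl, "C5ring", 10, "C19H33N3O5"),
    ],
)
def test_cytarabine_chain_prodrug_formulas(cytarabine, op, site, n, expected_formula):
    assert op(cytarabine, site, n).formula == expected_formula


def test_amide_is_constitutional_isomer_of_ester(cytarabine):
    ester = make_ester(cytarabine, "O5prime", 2)
    amide = make_amide(cytarabine, "N4amine", 2)
    assert ester.formula == amide.formula
    assert ester.smiles != amide.smiles


@pytest.mark.parametrize(
    "parent_name, site, expected_formula",
    [
        ("cytarabine", "N4amine", "C15H23N3O10"),
        ("fluorouracil", "N1", "C10H13FN2O7"),
    ],
)
def test_fructose_adduct_formulas(parents, parent_name, site, expected_formula):
    adduct = make_fructose_adduct(parents[parent_name], site)
    assert adduct.formula == expected_formula


# --------------------------------------------- formula-delta invariants

@pytest.mark.parametrize("n", [2, 4, 6, 8, 10, 12, 14, 16])
def test_ester_delta_is_CnH2n_minus2_O(cytarabine, n):
    product = make_ester(cytarabine, "O5prime", n)
    assert formula_delta(cytarabine.formula, product.formula) == {
        "C": n, "H": 2 * n - 2, "O": 1}


@pytest.mark.parametrize("n", [2, 4, 6, 8, 10])
def test_amide_delta_is_CnH2n_minus2_O(cytarabine, n):
    product = make_amide(cytarabine, "N4amine", n)
    assert formula_delta(cytarabine.formula, product.formula) == {
        "C": n, "H": 2 * n - 2, "O": 1}


@pytest.mark.parametrize("n", [1, 2, 5, 10])
def test_alkyl_delta_is_CnH2n(cytarabine, n):
    product = make_alkyl(cytarabine, "C5ring", n)
    assert formula_delta(cytarabine.formula, product.formula) == {"C": n, "H": 2 * n}


def test_fructose_delta_is_C6H10O5_for_all_parents_and_sites(parents):
    cases = [("cytarabine", "N4amine"), ("cytarabine", "O5prime"),
             ("abiraterone", "O3beta"), ("fluorouracil", "N1"),
             ("paliperidone", "O9")]
    for pname, site in cases:
        parent = parents[pname]
        adduct = make_fructose_adduct(parent, site)
        assert formula_delta(parent.formula, adduct.formula) == {
            "C": 6, "H": 10, "O": 5}, (pname, site)


# --------------------------------------------------- structure invariants

def test_products_canonicalize_idempotently(cytarabine):
    for product in (make_ester(cytarabine, "O5prime", 4),
                    make_fructose_adduct(cytarabine, "N4amine")):
        recanon = Chem.MolToSmiles(Chem.MolFromSmiles(product.smiles))
        assert recanon == product.smiles


def test_series_members_pairwise_distinct(cytarabine):
    smiles = [make_ester(cytarabine, "O5prime", n).smiles
              for n in range(2, 17, 2)]
    assert len(set(smiles)) == len(smiles)


@pytest.mark.parametrize(
    "op, site, smarts",
    [
        (make_ester, "O5prime", "[CX4]-[OX2]-C(=O)-[CX4]"),    # new ester linkage
        (make_amide, "N4amine", "[NX3]-C(=O)-[CX4]"),          # new amide linkage
        (make_alkyl, "C5ring", "c-[CX4H2]-[CX4]"),             # ring-attached chain
    ],
)
def test_modified_site_carries_expected_substituent(cytarabine, op, site, smarts):
    product = Chem.MolFromSmiles(op(cytarabine, site, 4).smiles)
    assert product.HasSubstructMatch(Chem.MolFromSmarts(smarts))
    assert not cytarabine.mol.HasSubstructMatch(Chem.MolFromSmarts(smarts))


# -------------------------------------------------------------- errors

def test_ester_rejects_one_carbon_acid(cytarabine):
    with pytest.raises(DerivatizationError, match=">= 2"):
        make_ester(cytarabine, "O5prime", 1)


def test_alkyl_rejects_zero_carbons(cytarabine):
    with pytest.raises(DerivatizationError, match=">= 1"):
        make_alkyl(cytarabine, "C5ring", 0)


def test_site_kind_mismatch_is_named(cytarabine):
    with pytest.raises(DerivatizationError, match="hydroxyl"):
        make_ester(cytarabine, "N4amine", 4)
    with pytest.raises(DerivatizationError, match="primary-amine"):
        make_amide(cytarabine, "O5prime", 4)


def test_unknown_site_label(cytarabine):
    with pytest.raises(DerivatizationError, match="unknown site label"):
        make_fructose_adduct(cytarabine, "nope")


def test_parent_validation_rejects_wrong_site_annotation():
    with pytest.raises(DerivatizationError, match="not"):
        ParentMolecule("bad", "CCO",
                       sites={"x": Site(SiteKind.PRIMARY_AMINE, 2)})
    with pytest.raises(DerivatizationError, match="out of range"):
        ParentMolecule("bad", "CCO", sites={"x": Site(SiteKind.HYDROXYL, 99)})


# ----------------------------------------------------------- enumeration

def test_full_study_set_has_26_unique_structures(study_catalog, parents):
    structures = enumerate_study_set(study_catalog, parents)
    assert len(structures) == 26
    assert len({s.smiles for s in structures}) == 26
    names = {s.name for s in structures}
    assert {"cytarabine", "CytO2", "CytO16", "CytN10", "CytC10",
            "Cyt-fru", "Abi-fru", "FU-fru", "Pali-fru"} <= names


def test_ester_series_alone_has_8_structures(study_catalog, parents):
    catalog = {"series": [s for s in study_catalog["series"]
                          if s["modification"] == "ester"]}
    assert len(enumerate_study_set(catalog, parents)) == 8


def test_empty_catalog_gives_empty_list(parents):
    assert enumerate_study_set({}, parents) == []


def test_duplicate_structure_under_distinct_names_is_rejected(parents):
    catalog = {"adducts": [
        {"parent": "cytarabine", "site": "N4amine", "name": "Cyt-fru"},
        {"parent": "cytarabine", "site": "N4amine", "name": "Cyt-fru-again"},
    ]}
    with pytest.raises(DerivatizationError, match="same"):
        enumerate_study_set(catalog, parents)
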