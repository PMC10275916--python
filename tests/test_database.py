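"""Formula parsing, balance checking and universal-database curation."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from gembuild.database import (
    DatabaseError,
    Metabolite,
    Reaction,
    UniversalDatabase,
    check_balance,
    curate_database,
    parse_formula,
)
from gembuild.fixtures import FixtureSpec, make_universal_fixture


@pytest.mark.parametrize(
    "formula, expected",
    [
        ("H2O", {"H": 2, "O": 1}),
        ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
        ("C10H12N5O7P*", None),  # non-alphanumeric character
        ("C6H5(OH)", None),  # parenthesized groups outside the grammar
        ("CHONR", {"C": 1, "H": 1, "O": 1, "N": 1, "R": 1}),  # pseudo-element R
        ("Fe2Se3", {"Fe": 2, "Se": 3}),  # two-letter symbols
        ("", None),
        ("h2o", None),  # lowercase start fails the token grammar
        ("2HO", None),  # leading digit fails the token grammar
        ("CHC", {"C": 2, "H": 1}),  # repeated symbols accumulate
    ],
)
def test_parse_formula(formula, expected):
    assert parse_formula(formula) == expected


@given(
    st.dictionaries(
        st.sampled_from(["C", "H", "O", "N", "P", "S", "Se", "Fe", "R"]),
        st.integers(min_value=1, max_value=99),
        min_size=1,
        max_size=6,
    )
)
def test_parse_formula_inverts_composition(counts):
    """Composing Symbol+count tokens and parsing them is the identity."""
    formula = "".join(f"{el}{n}" for el, n in counts.items())
    assert parse_formula(formula) == counts


def _db(mets, rxns, biomass=None):
    return UniversalDatabase(mets, rxns, biomass_template=biomass)


def _met(mid, formula, charge=0):
    return Metabolite(mid, formula=formula, charge=charge)


class TestCheckBalance:
    def test_identical_formulas_balance(self):
        db = _db([_met("cpd00001_c", "H2O"), _met("cpd00002_c", "H2O")], [])
        rxn = Reaction("rxn00001_c", {"cpd00001_c": -1, "cpd00002_c": 1})
        db.add_reaction(rxn)
        entry = check_balance(rxn, db)
        assert entry.verdict == "balanced" and not entry.exempt

    def test_stoichiometric_multiples_balance(self):
        db = _db(
            [_met("cpd00010_c", "C6H12O6"), _met("cpd00011_c", "C3H6O3")], []
        )
        rxn = Reaction("rxn00002_c", {"cpd00010_c": -1, "cpd00011_c": 2})
        db.add_reaction(rxn)
        assert check_balance(rxn, db).verdict == "balanced"

    def test_element_deltas_reported(self):
        db = _db([_met("cpd00020_c", "CH4"), _met("cpd00021_c", "CO2")], [])
        rxn = Reaction("rxn00003_c", {"cpd00020_c": -1, "cpd00021_c": 1})
        db.add_reaction(rxn)
        entry = check_balance(rxn, db)
        assert entry.verdict == "unbalanced"
        assert entry.element_deltas == {"H": -4, "O": 2}

    def test_missing_formula_is_undetermined(self):
        db = _db([_met("cpd00030_c", None), _met("cpd00031_c", "H2O")], [])
        rxn = Reaction("rxn00004_c", {"cpd00030_c": -1, "cpd00031_c": 1})
        db.add_reaction(rxn)
        assert check_balance(rxn, db).verdict == "undetermined"

    def test_charge_imbalance_detected(self):
        db = _db(
            [_met("cpd00040_c", "H2O", charge=0), _met("cpd00041_c", "H2O", charge=1)],
            [],
        )
        rxn = Reaction("rxn00005_c", {"cpd00040_c": -1, "cpd00041_c": 1})
        db.add_reaction(rxn)
        assert check_balance(rxn, db).verdict == "unbalanced"
        assert check_balance(rxn, db, check_charge=False).verdict == "balanced"

    def test_unknown_charge_is_undetermined(self):
        db = _db(
            [_met("cpd00040_c", "H2O", charge=None), _met("cpd00041_c", "H2O")], []
        )
        rxn = Reaction("rxn00005_c", {"cpd00040_c": -1, "cpd00041_c": 1})
        db.add_reaction(rxn)
        assert check_balance(rxn, db).verdict == "undetermined"

    def test_exchange_and_transport_exempt(self):
        db = _db([_met("cpd00050_e", "CH4"), _met("cpd00050_c", "CH4")], [])
        ex = Reaction("EX_cpd00050_e", {"cpd00050_e": -1}, source="exchange")
        tp = Reaction("rxn00006_c", {"cpd00050_e": -1, "cpd00050_c": 1})
        db.add_reaction(ex)
        db.add_reaction(tp)
        assert check_balance(ex, db).exempt
        assert check_balance(tp, db).exempt  # identity transport

    def test_unresolvable_metabolite_is_hard_error(self):
        db = _db([_met("cpd00060_c", "H2O")], [])
        rxn = Reaction("rxn00007_c", {"cpd00060_c": -1, "cpd00061_c": 1})
        with pytest.raises(DatabaseError, match="cpd00061_c"):
            check_balance(rxn, db)

    def test_verdict_is_order_independent(self):
        rng = random.Random(0)
        mets = [_met(f"cpd{i:05d}_c", f) for i, f in
                [(1, "C2H4O2"), (2, "CH2O"), (3, "CH2O")]]
        db = _db(mets, [])
        items = [("cpd00001_c", -1.0), ("cpd00002_c", 1.0), ("cpd00003_c", 1.0)]
        verdicts = set()
        for _ in range(10):
            rng.shuffle(items)
            rxn = Reaction("rxn00008_c", dict(items))
            verdicts.add(check_balance(rxn, db).verdict)
        assert verdicts == {"balanced"}


class TestCuration:
    def test_removes_exactly_the_seeded_unbalanced_set(self, raw_fixture):
        raw, gt = raw_fixture
        curated, report = curate_database(raw)
        assert report.unbalanced_ids == gt.unbalanced_ids
        assert set(raw.reactions) - set(curated.reactions) == gt.unbalanced_ids

    def test_adds_missing_exchange_with_standard_bounds(self, raw_fixture):
        raw, gt = raw_fixture
        ex_id = f"EX_{gt.missing_exchange_metabolite}"
        assert ex_id not in raw.reactions
        curated, _ = curate_database(raw)
        ex = curated.reactions[ex_id]
        assert (ex.lower_bound, ex.upper_bound) == (-1000, 1000)
        assert ex.source == "exchange"

    def test_every_extracellular_metabolite_has_one_exchange(self, raw_fixture):
        curated, _ = curate_database(raw_fixture[0])
        for met_id in curated.extracellular_metabolites():
            assert f"EX_{met_id}" in curated.reactions

    def test_idempotent(self, raw_fixture):
        once, _ = curate_database(raw_fixture[0])
        twice, report = curate_database(once)
        assert set(once.reactions) == set(twice.reactions)
        assert set(once.metabolites) == set(twice.metabolites)
        assert not report.unbalanced_ids
        assert once.reactions["biomass"].stoichiometry == \
            twice.reactions["biomass"].stoichiometry

    def test_biomass_installed_as_objective_template(self, raw_fixture):
        curated, _ = curate_database(raw_fixture[0])
        assert curated.reactions["biomass"].source == "biomass"

    def test_missing_biomass_template_is_error(self):
        db = _db([_met("cpd00001_c", "H2O"), _met("cpd00002_c", "H2O")], [])
        db.add_reaction(Reaction("rxn00001_c", {"cpd00001_c": -1, "cpd00002_c": 1}))
        with pytest.raises(DatabaseError, match="biomass"):
            curate_database(db)

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_exactness_across_random_fixtures(self, seed):
        rng = random.Random(seed)
        spec = FixtureSpec(
            seed=seed,
            pathway_length=rng.randint(3, 6),
            n_decoy_reactions=rng.randint(2, 6),
            n_unbalanced=rng.randint(0, 4),
        )
        raw, gt = make_universal_fixture(spec)
        _, report = curate_database(raw)
        assert report.unbalanced_ids == gt.unbalanced_ids


class TestSerialization:
    def test_json_roundtrip(self, raw_fixture, tmp_path):
        raw, _ = raw_fixture
        path = tmp_path / "db.json"
        raw.to_json(path)
        loaded = UniversalDatabase.from_json(path)
        assert set(loaded.reactions) == set(raw.reactions)
        assert set(loaded.metabolites) == set(raw.metabolites)
        for rid, rxn in raw.reactions.items():
            other = loaded.reactions[rid]
            assert dict(other.stoichiometry) == dict(rxn.stoichiometry)
            assert (other.lower_bound, other.upper_bound) == (
                rxn.lower_bound, rxn.upper_bound)
        assert loaded.biomass_template.stoichiometry == \
            raw.biomass_template.stoichiometry

    def test_tsv_dictionaries(self, tmp_path):
        mets = tmp_path / "metabolites.tsv"
        rxns = tmp_path / "reactions.tsv"
        mets.write_text(
            "id\tname\tformula\tcharge\n"
            "cpd00001_c\twater\tH2O\t0\n"
            "cpd00002_c\twater prime\tH2O\t0\n"
        )
        rxns.write_text(
            "id\tname\tstoichiometry\tlower_bound\tupper_bound\n"
            "rxn00001_c\tiso\t-1:cpd00001_c;1:cpd00002_c\t0\t1000\n"
        )
        db = UniversalDatabase.from_tsv(rxns, mets)
        assert db.reactions["rxn00001_c"].stoichiometry == {
            "cpd00001_c": -1.0, "cpd00002_c": 1.0}
        assert db.metabolites["cpd00001_c"].formula == "H2O"

    def test_balance_report_tsv(self, raw_fixture, tmp_path):
        _, report = curate_database(raw_fixture[0])
        out = tmp_path / "audit.tsv"
        report.to_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("reaction_id\t")
        assert len(lines) == len(report) + 1


def test_invalid_records_rejected():
    with pytest.raises(DatabaseError):
        Metabolite("cpd00001_x")  # bad compartment suffix
    with pytest.raises(DatabaseError):
        Reaction("rxn00001_c", {"cpd00001_c": -1}, lower_bound=5, upper_bound=1)
    with pytest.raises(DatabaseError):
        Reaction("EX_cpd00001_e", {"cpd00001_e": -2}, source="exchange")
    with pytest.raises(DatabaseError):
        Reaction("rxn00001_c", {"cpd00001_c": -1}, gpr="g1", source="gapfilled")
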