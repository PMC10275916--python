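import cobra
import pytest
from hypothesis import settings

from gembuild.annotation import GeneHit, build_draft, filter_hits, hits_to_evidence
from gembuild.database import curate_database
from gembuild.fixtures import FixtureSpec, make_hit_fixture, make_universal_fixture

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def hits_from_rows(rows):
    """Parse the fixture generator's outfmt-6 rows into GeneHit objects."""
    out = []
    for row in rows:
        c = row.split("\t")
        out.append(GeneHit(c[0], c[1], float(c[2]), float(c[10]), float(c[11])))
    return out


def draft_for(gt, db, drop=frozenset(), media=None):
    """Draft model built from fixture evidence with ``drop`` unevidenced."""
    rows, grm = make_hit_fixture(gt, drop=set(drop))
    evidence = hits_to_evidence(filter_hits(hits_from_rows(rows)), grm)
    return build_draft(evidence, db, media or gt.media)


@pytest.fixture(scope="session")
def simple_fixture():
    """Curated linear-pathway database with full ground truth."""
    raw, gt = make_universal_fixture(FixtureSpec(seed=1))
    db, report = curate_database(raw)
    return db, gt, report


@pytest.fixture(scope="session")
def raw_fixture():
    return make_universal_fixture(FixtureSpec(seed=1))


@pytest.fixture()
def full_draft(simple_fixture):
    db, gt, _ = simple_fixture
    return draft_for(gt, db)


def chain_model(uptake=10.0, internal_ub=1000.0, close_exchanges=False):
    """Hand-built chain EX_A → transport → A→B → biomass with unit yield."""
    model = cobra.Model("chain")
    a_e = cobra.Metabolite("cpd00001_e", compartment="e")
    a_c = cobra.Metabolite("cpd00001_c", compartment="c")
    b_c = cobra.Metabolite("cpd00002_c", compartment="c")
    ex = cobra.Reaction("EX_cpd00001_e", lower_bound=-uptake, upper_bound=1000.0)
    tp = cobra.Reaction("rxn00001_c", lower_bound=0.0, upper_bound=1000.0)
    r1 = cobra.Reaction("rxn00002_c", lower_bound=0.0, upper_bound=internal_ub)
    bm = cobra.Reaction("biomass", lower_bound=0.0, upper_bound=1000.0)
    model.add_reactions([ex, tp, r1, bm])
    ex.add_metabolites({a_e: -1})
    tp.add_metabolites({a_e: -1, a_c: 1})
    r1.add_metabolites({a_c: -1, b_c: 1})
    bm.add_metabolites({b_c: -1})
    model.objective = "biomass"
    if close_exchanges:
        ex.bounds = (0.0, 1000.0)
    return model
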