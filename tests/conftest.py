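import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from semioloc import DatapointRecord, default_region_tree, default_taxonomy


@pytest.fixture(scope="session")
def tree():
    return default_region_tree()


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


def make_record(
    patient="P1",
    article="A1",
    category="Epigastric",
    locs=None,
    text="epigastric rising sensation",
    seizure_free=True,
    concordance=False,
    invasive=False,
    topological="spontaneous",
    age="adult",
    year=2000,
):
    return DatapointRecord(
        patient_id=patient,
        article_id=article,
        year=year,
        semiology_text=text,
        semiology_category=category,
        localizations=locs if locs is not None else {"Mesial Temporal": 1.0},
        gt_seizure_free=seizure_free,
        gt_concordance=concordance,
        gt_invasive=invasive,
        topological=topological,
        age_label=age,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def toy_cohort():
    """Four epigastric units (3 purely temporal, 1 split frontal/temporal)
    plus five tonic units, spanning both study designs."""
    recs = [
        make_record(patient=f"P{i}", category="Epigastric", locs={"Temporal": 1.0})
        for i in range(3)
    ]
    recs.append(
        make_record(
            patient="P3",
            category="Epigastric",
            locs={"Frontal": 1.0, "Temporal": 1.0},
        )
    )
    recs += [
        make_record(
            patient=f"Q{i}",
            article="A2",
            category="Tonic",
            locs={"Frontal": 1.0},
            topological="epilepsy_topology" if i % 2 else "spontaneous",
        )
        for i in range(5)
    ]
    return recs
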