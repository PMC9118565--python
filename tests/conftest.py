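import pytest

from lncscape.classify import (
    apply_identification_filters,
    classification_report,
    classify_transcripts,
)
from lncscape.synthetic import GeneratorConfig, generate_dataset, plant_boundary_cases


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """The default synthetic bundle (seed fixed once for the whole suite)."""
    return generate_dataset(GeneratorConfig(seed=11), tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def boundary(tmp_path_factory):
    return plant_boundary_cases(
        GeneratorConfig(seed=11), tmp_path_factory.mktemp("boundary")
    )


@pytest.fixture(scope="session")
def classified(bundle):
    """Filter + classify the default bundle once; reused by many tests."""
    ftab = apply_identification_filters(bundle.candidates, bundle.flags, bundle.expression)
    pending_ids = set(ftab.loc[ftab["cls"] == "pending", "transcript_id"])
    pending = [t for t in bundle.candidates if t.transcript_id in pending_ids]
    ctab = classify_transcripts(pending, bundle.genes)
    report = classification_report(ftab, ctab).set_index("transcript_id")
    by_class = {
        cls: [t for t in pending if report.loc[t.transcript_id, "cls"] == cls]
        for cls in ("lincRNA", "lncNAT")
    }
    return {"filter": ftab, "report": report, "pending": pending, "by_class": by_class}
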