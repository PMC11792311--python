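import pytest

from toxfindings.normalise import load_default_store
from toxfindings.relate import load_triggers


@pytest.fixture(scope="session")
def store():
    return load_default_store()


@pytest.fixture(scope="session")
def triggers():
    return load_triggers()


def observation_key(o):
    """Comparable projection of an observation (everything but mention
    objects, which CSV and cross-implementation comparisons cannot carry)."""
    return (o.obs_id, o.section, o.domain_code, o.study_test,
            o.manifestation, o.finding, o.specimen, o.sex, o.group,
            o.dose_value, o.dose_unit, o.treatment_related,
            tuple(o.sentence_ids), o.evidence_text,
            tuple(o.noncontrolled_flags))
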