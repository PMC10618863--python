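import numpy as np
import pytest

from stresstherm.io_schema import Dataset, ObservationRecord


def make_record(**overrides) -> ObservationRecord:
    """An ObservationRecord with sensible defaults, overridable per test."""
    base = dict(
        study_id="s1",
        group_id="g1",
        species="mus_musculus",
        family="muridae",
        taxon_class="mammal",
        n_individuals=8,
        tb_baseline=37.5,
        tb_baseline_sd=0.4,
        tb_response=38.4,
        tb_response_sd=0.5,
        design="pre_post",
        air_temp=22.0,
        air_temp_sd=1.5,
        mass=30.0,
        mass_sd=3.0,
        latency=1200.0,
        technique="telemetry",
        age_class=1,
        sex="mixed",
        season="summer",
        pharma_flag=False,
    )
    base.update(overrides)
    return ObservationRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def tiny_dataset() -> Dataset:
    recs = [
        make_record(study_id="s1", group_id="g1"),
        make_record(study_id="s1", group_id="g2", tb_response=36.9,
                    air_temp_sd=None),
        make_record(study_id="s2", group_id="g1", species="parus_major",
                    taxon_class="bird", mass=18.0, mass_sd=None,
                    air_temp=5.0),
    ]
    return Dataset(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)
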