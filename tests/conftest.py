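import logging

import pytest

from rbpmosaic import PipelineConfig, RBPRecord

logging.getLogger("rbpmosaic").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


def make_record(rbp_id="r1", genus="genusA", aa="ACDEFGHIKLMNPQRSTVWY" * 10,
                **kwargs) -> RBPRecord:
    kwargs.setdefault("phage_id", f"{rbp_id}_phage")
    return RBPRecord(rbp_id=rbp_id, genus=genus, aa_sequence=aa, **kwargs)


@pytest.fixture
def record_factory():
    return make_record
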