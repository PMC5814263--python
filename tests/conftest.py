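import numpy as np
import pytest

from clonevo.variant_model import SampleCall, VariantRecord


def make_variant(pos=1, **kw):
    """A variant that passes every default quality filter unless overridden."""
    defaults = dict(
        chrom="chr1", pos=pos, ref="C", alt="T", vaf=0.3, depth=500,
        alt_reads=150, qual=40.0, caller_p=1e-4,
    )
    defaults.update(kw)
    return VariantRecord(**defaults)


@pytest.fixture
def passing_variant():
    return make_variant()


@pytest.fixture
def sample_factory():
    def make(patient_id="p1", timepoint="diagnosis", variants=(), **kw):
        return SampleCall(patient_id=patient_id, timepoint=timepoint,
                          variants=list(variants), **kw)
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20250924)
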