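import pytest

from assayqc.lod import CallPolicy
from assayqc.variants_io import VariantCall, VariantKey


def make_call(chrom="chr7", pos=140453136, ref="T", alt="A", gene="BRAF",
              pct=18.5, depth=1200, alt_depth=None, quality=900.0,
              strand_bias=0.62, filters=()):
    return VariantCall(
        key=VariantKey(chrom, pos, ref, alt, gene),
        observed_pct=pct, depth=depth, alt_depth=alt_depth,
        quality=quality, strand_bias=strand_bias, filters=set(filters),
    )


@pytest.fixture
def braf_call():
    return make_call()


@pytest.fixture
def permissive_policy():
    """A policy no reasonable simulated call fails, for plumbing tests."""
    return CallPolicy(min_depth=1, min_freq_pct=0.0, min_quality=0.0,
                      max_strand_bias=1.0)
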