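import numpy as np
import pytest

import biphasic as bp
from biphasic import simulate as sim


@pytest.fixture(scope="session")
def toy_assembly():
    return bp.load_assembly("toy")


@pytest.fixture(scope="session")
def toy_reference():
    """200 kb x 2 chromosomes of uniform-random sequence, fixed seed."""
    reference, assembly = sim.simulate_reference(20240, n_chrom=2, length_bp=200_000)
    return reference, assembly


@pytest.fixture(scope="session")
def signature_matrix():
    return bp.synthetic_signature_matrix()


def make_profile(segments, sample_id="S1", purity=0.8, ploidy=2.0):
    """Shorthand: segments as (chrom, start, end, total, minor) tuples."""
    return bp.SegmentProfile(
        sample_id,
        [bp.Segment(*s) for s in segments],
        purity,
        ploidy,
    ).canonicalize()


def make_snv(chrom="1", pos=100, ref="A", alt="C", sample="S1", component="bulk",
             t_ref=50, t_alt=50, n_ref=50, n_alt=0, **kw):
    return bp.MutationRecord(
        sample_id=sample, component_id=component, chrom=chrom, pos=pos,
        ref=ref, alt=alt, variant_class="SNV",
        t_ref=t_ref, t_alt=t_alt, n_ref=n_ref, n_alt=n_alt, **kw,
    )
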