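import numpy as np
import pytest

import duptrp as dt
from duptrp.segmentation import CNSegment


@pytest.fixture(scope="session")
def config():
    return dt.SimConfig(seed=1)


@pytest.fixture(scope="session")
def reference(config):
    """Reference sequence and layout built once per session."""
    return dt.build_reference(config)


@pytest.fixture(scope="session")
def duptrp1(reference):
    ref, layout = reference
    hap, truth = dt.apply_architecture(ref, layout, "DUPTRP_1")
    return hap, truth


def truth_to_evidence(truth, chrom, bin_size=500):
    """Render a truth record as the CN segments and calls inference sees."""
    cn = [CNSegment(chrom, s, e, c, c / 2.0, (e - s) // bin_size)
          for s, e, c in truth.truth_cn_profile]
    return cn, list(truth.truth_junctions)


@pytest.fixture(scope="session")
def fig4_partition(reference, duptrp1):
    """The hypothetical-example fixture: stepped 2-3-4-3-2 profile, one
    tail-to-tail distal junction, proximal junction inside the
    inverted-repeat pair."""
    ref, layout = reference
    _, truth = duptrp1
    cn, calls = truth_to_evidence(truth, layout.chrom)
    return dt.partition_segments(cn, calls, [layout.palindrome])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
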