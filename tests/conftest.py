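import numpy as np
import pytest

from bsamap.pipeline import SimulationConfig, simulate_experiment
from bsamap.simgenetics import BulkCall, SiteObservation, VariantSite


@pytest.fixture(scope="session")
def small_genome():
    from bsamap.simgenetics import make_toy_genome

    return make_toy_genome(1, 10_000, 2, seed=3)


@pytest.fixture(scope="session")
def designed_sim():
    """One full simulated experiment under the designed study conditions."""
    return simulate_experiment(SimulationConfig(mean_depth=500.0), seed=11)


def mk_obs(pos, ref="C", alt="T", *, wt, mut, chrom="chr1"):
    """Handy observation builder: wt/mut are (dp, alt_reads, gq) triples."""

    def call(dp, alt_reads, gq):
        gt = "1/1" if dp and alt_reads == dp else ("0/0" if alt_reads == 0 else "0/1")
        if dp == 0:
            gt = "./."
        return BulkCall(dp=dp, ref_reads=dp - alt_reads, alt_reads=alt_reads,
                        gt=gt, gq=gq)

    return SiteObservation(
        VariantSite(chrom, pos, ref, alt), wt=call(*wt), mut=call(*mut)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
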