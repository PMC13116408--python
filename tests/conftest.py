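import pytest

from twinsnv.core import Genotype, GenotypeCall, Locus, ReadSupport
from twinsnv.simulate import SimulationConfig, simulate_twin_pair

DEFAULT_LOCUS = Locus(chrom="chr1", pos=12345, ref_allele="A", alt_allele="G")


def make_call(
    genotype: Genotype,
    ref: int,
    alt: int,
    other: int = 0,
    gq: int = 50,
    locus: Locus = DEFAULT_LOCUS,
) -> GenotypeCall:
    return GenotypeCall(
        locus=locus,
        genotype=genotype,
        support=ReadSupport(ref, alt, other),
        gq=gq,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured simulated case, shared across tests."""
    config = SimulationConfig(
        n_loci=2_000,
        n_postzygotic=(5, 3),
        n_somatic=30,
        seed=7,
    )
    return simulate_twin_pair(config)


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free, difference-free case at saturating depth."""
    config = SimulationConfig(
        n_loci=500,
        n_postzygotic=(0, 0),
        n_somatic=0,
        mean_depth_trace=120,
        mean_depth_reference=120,
        error_rate=0.0,
        seed=3,
    )
    return simulate_twin_pair(config)
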