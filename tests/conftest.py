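"""Shared fixtures: small genomes and crosses generated at test time."""

import pytest

from bulkscan.simulate import CrossConfig, GenomeModel, simulate_f2_population
from bulkscan.io import VariantSite


@pytest.fixture
def toy_genome():
    """Two 2 Mb chromosomes with markers every 50 kb — fast to simulate."""
    return GenomeModel.default(n_chrom=2, length=2_000_000,
                               marker_spacing=50_000, cm_per_mb=4.0)


@pytest.fixture
def toy_cross(toy_genome):
    """~200 F2 individuals, causal locus mid-chr1, fixed seed."""
    config = CrossConfig(n_f2=200, bulk_size=15, causal_chrom="chr1",
                         causal_pos=1_000_000, seed=7)
    return toy_genome, config, simulate_f2_population(toy_genome, config)


def make_site(pos=100, pl=None, st=None, parent=(50, 50), chrom="chr1",
              ref="A", alt="T"):
    return VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt,
                       parent=parent, st=st, pl=pl)


@pytest.fixture
def site_factory():
    return make_site
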