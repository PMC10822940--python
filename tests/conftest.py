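import numpy as np
import pytest

from mrcluster.gwas_io import SummaryPanel, VariantAssociation
from mrcluster.instruments import HarmonizedInstrument


def hi(vid="rs1", bx=0.2, sx=0.02, by=0.1, sy=0.05, action="aligned"):
    return HarmonizedInstrument(vid, bx, sx, by, sy, action)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_instruments(rng):
    """A generic harmonized set with spread in effects and SEs."""

    def make(J=10, theta=0.4, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        bx = r.uniform(0.1, 0.5, J) * r.choice([-1, 1], J)
        sy = r.uniform(0.02, 0.1, J)
        by = theta * bx + r.normal(0, sy)
        return [
            hi(f"rs{i}", bx[i], 0.02, by[i], sy[i]) for i in range(J)
        ]

    return make


def variant(vid, ea="A", oa="G", beta=0.2, se=0.02, pval=1e-8, chrom="1",
            pos=1_000_000, eaf=0.3, n=10_000):
    return VariantAssociation(variant_id=vid, chrom=chrom, pos=pos,
                              effect_allele=ea, other_allele=oa, eaf=eaf,
                              beta=beta, se=se, pval=pval, n=n)


def panel(trait_id, variants, **kw):
    return SummaryPanel(trait_id, variants, **kw)
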