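import numpy as np
import pytest

from imphazard.core import CohortStudy, HaplotypePanel, SiteInfo


def make_sites(n, chrom="1", start=1000, step=500, associated=(), risk="alt"):
    """Evenly spaced biallelic test sites; `associated` lists column indices."""
    return [
        SiteInfo(
            id=f"t{i:03d}",
            chrom=chrom,
            pos_bp=start + i * step,
            ref_allele="A",
            alt_allele="G",
            risk_allele=risk if i in associated else "none",
            is_associated=i in associated,
        )
        for i in range(n)
    ]


@pytest.fixture
def sites4():
    return make_sites(4)


@pytest.fixture
def small_panel():
    alleles = np.array(
        [
            [0, 0, 1],
            [0, 1, 1],
            [1, 0, 0],
            [1, 1, 0],
        ],
        dtype=np.int8,
    )
    return HaplotypePanel(alleles=alleles, sites=make_sites(3))


@pytest.fixture
def tiny_study():
    sites = make_sites(2, associated=(0,))
    cases = np.array([[2, 0], [1, 1], [0, 2]], dtype=np.int8)
    controls = np.array([[0, 0], [0, 1], [1, 2]], dtype=np.int8)
    return CohortStudy(cases=cases, controls=controls, sites=sites)
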