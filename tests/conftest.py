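import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from snpbarcode import GenotypeDataset, dichotomize_by_mean

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def toy_dataset() -> GenotypeDataset:
    """Six subjects over two SNPs, three per phenotype group.

    HIGH genotypes: (1,3), (3,3), (3,3); LOW: (3,3), (2,1), (3,2).
    The barcode {SNP1: 3, SNP2: 3} is carried by 2 HIGH and 1 LOW subject.
    """
    ds = GenotypeDataset(
        subject_ids=[f"S{i}" for i in range(1, 7)],
        phenotype=np.array([100.0, 99.0, 98.0, 80.0, 81.0, 82.0]),
        genotypes=np.array([[1, 3], [3, 3], [3, 3], [3, 3], [2, 1], [3, 2]]),
        snp_names=["snpA", "snpB"],
    )
    return dichotomize_by_mean(ds)
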