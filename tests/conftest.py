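import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from kynscan.datasets import load_kyn_instruments
from kynscan.instruments import GenotypeMatrix
from kynscan.phenome import PhecodeMap

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def kyn_instruments():
    """The six bundled metabolite lead SNPs."""
    return load_kyn_instruments()


@pytest.fixture()
def tiny_phecode_map():
    """Three phecodes: hypertension-like pair sharing an exclusion range,
    plus one sex-restricted phenotype."""
    rows = [
        ("401.1", "ICD9CM", "401.1", "hypertension", 400.0, 405.0, "none"),
        ("I10", "ICD10", "401.1", "hypertension", 400.0, 405.0, "none"),
        ("402.0", "ICD9CM", "402.0", "heart disease", 400.0, 405.0, "none"),
        ("250.2", "ICD9CM", "250.2", "diabetes", 249.0, 251.0, "none"),
        ("618.0", "ICD9CM", "618.0", "uterine prolapse", 617.0, 619.0, "female"),
    ]
    return PhecodeMap(pd.DataFrame(
        rows, columns=["icd", "vocab", "phecode", "label",
                       "exclusion_min", "exclusion_max", "sex"]))


def make_genotypes(dosages, chrom=None, pos=None):
    """Build a GenotypeMatrix from a person x variant array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chrom = chrom or ["1"] * m
    pos = pos or [1000 + 10_000 * j for j in range(m)]
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(m)],
        "chrom": chrom, "pos": pos, "ref": ["A"] * m, "alt": ["G"] * m,
    })
    return GenotypeMatrix(person_ids=[f"P{i}" for i in range(n)],
                          variants=variants, dosages=dosages)
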