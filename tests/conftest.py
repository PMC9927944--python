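import numpy as np
import pytest
from hypothesis import settings

from mprakit.design import DesignParams, VariantRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

BASES = "ACGT"


def random_reference(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(BASES), size=length))


def snv(vid: str, pos: int, reference: str, alt: str | None = None) -> VariantRecord:
    """A biallelic SNV consistent with the reference sequence."""
    ref_base = reference[pos - 1]
    if alt is None:
        alt = BASES[(BASES.index(ref_base) + 1) % 4]
    return VariantRecord(id=vid, chrom="chr1", pos=pos, ref=ref_base, alts=(alt,))


@pytest.fixture
def reference_1kb() -> str:
    return random_reference(1000, seed=42)


@pytest.fixture
def params() -> DesignParams:
    return DesignParams()
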