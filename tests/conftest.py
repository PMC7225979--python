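import pytest

from oamlseq.model import VariantCall
from oamlseq.simulate import CohortConfig, generate_cohort

_BASE_CALL = dict(
    patient_id="P001", sample_id="P001-S1", sample_type="ffpe",
    gene="JAK3", chrom="chr19", pos=100, ref="A", alt="G",
    impact="MODERATE", consequence="missense",
    var_fwd=20, var_rev=20, ref_fwd=30, ref_rev=30, vaf=0.4,
    quality=900.0, known_variant=False, homopolymer_len=0,
)


def make_call(**overrides) -> VariantCall:
    """A valid VariantCall with field overrides (counts must stay
    consistent with vaf if either is overridden)."""
    fields = {**_BASE_CALL, **overrides}
    return VariantCall(**fields)


def make_call_with_vaf(vaf: float, depth: int = 200, **overrides) -> VariantCall:
    """A call whose read counts are derived from the requested VAF."""
    var_total = round(vaf * depth)
    ref_total = depth - var_total
    counts = dict(var_fwd=var_total // 2, var_rev=var_total - var_total // 2,
                  ref_fwd=ref_total // 2, ref_rev=ref_total - ref_total // 2)
    return make_call(vaf=vaf, **counts, **overrides)


@pytest.fixture
def call_factory():
    return make_call


@pytest.fixture
def vaf_call_factory():
    return make_call_with_vaf


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort shared across tests."""
    return generate_cohort(CohortConfig(seed=11))
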