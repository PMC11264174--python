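import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cnvdriver.models import CnvCall, GeneRecord, Locus, SampleTable


@pytest.fixture
def small_loci() -> list[Locus]:
    return [
        Locus("16p11.2", "16", 29_500_000, 30_200_000),
        Locus("22q11.21", "22", 18_900_000, 21_100_000),
        Locus("1q21.1", "1", 146_000_000, 148_000_000),
    ]


@pytest.fixture
def small_samples() -> SampleTable:
    status = {f"case{i}": "case" for i in range(4)}
    status.update({f"ctrl{i}": "control" for i in range(4)})
    return SampleTable(status)


@pytest.fixture
def small_genes() -> list[GeneRecord]:
    return [
        GeneRecord("TBX6", "16", 30_097_000, 30_103_000, 0.97, 0.2),
        GeneRecord("SHANK3", "22", 19_000_000, 19_060_000, 0.99, 0.995),
        GeneRecord("EDGEG", "16", 29_500_000, 30_200_000, 0.9, 0.1),  # spans the whole locus
        GeneRecord("OUTG", "16", 30_150_000, 30_300_000, 0.95, 0.1),  # straddles the boundary
        GeneRecord("NEUTRAL", "1", 146_500_000, 146_550_000, 0.3, 0.4),
    ]


@pytest.fixture
def small_cnvs() -> list[CnvCall]:
    return [
        CnvCall("16", 29_600_000, 30_190_000, "DEL", "case0"),
        CnvCall("16", 29_600_000, 30_190_000, "DEL", "case0"),  # second call, same sample
        CnvCall("chr16", 29_400_000, 29_700_000, "DUP", "case1"),
        CnvCall("22", 18_950_000, 21_000_000, "DEL", "ctrl0"),
        CnvCall("5", 1_000_000, 1_050_000, "DEL", "ctrl1"),
    ]
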