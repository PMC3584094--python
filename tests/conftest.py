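import numpy as np
import pytest

from plastomekit import synthetic_data as sd


@pytest.fixture(scope="session")
def default_genome():
    """Full-size synthetic plastome with planted truth (built once)."""
    return sd.build_plastome(sd.PlastomeSpec(seed=11))


@pytest.fixture(scope="session")
def toy_genome():
    """Scaled-down plastome for end-to-end pipeline tests."""
    spec = sd.PlastomeSpec(
        lsc_len=20_000, ssc_len=6_000, ir_len=8_000,
        n_cds=12, n_trna=6, n_rrna=2,
        planted_tandem=(("TATTGATGAGAGTGACGA", 6, "IR"),),
        planted_dispersed=(
            ("F", "CTACAGAACCGTACATGAGATTTTCACCTCATACGGCTCCT", ("LSC", "SSC")),
        ),
        planted_ssrs=(("A", 10, "LSC"), ("AT", 5, "SSC")),
        seed=21,
    )
    return sd.build_plastome(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n, p=None):
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
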