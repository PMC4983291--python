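import pytest

from conconnmr.mixing import MixingModel
from conconnmr.shiftgen import generate_shifts, random_idp_sequence


@pytest.fixture(scope="session")
def aapaa_shifts():
    """Tiny proline-containing table: P at position 3."""
    return generate_shifts("AAPAA", seed=11)


@pytest.fixture(scope="session")
def idp30_shifts():
    """30-residue IDP-like table with three internal prolines."""
    seq = random_idp_sequence(30, 3, seed=7)
    return generate_shifts(seq, seed=7)


@pytest.fixture(scope="session")
def lossless_model():
    """Mixing model without relaxation: unitary chain transfer."""
    return MixingModel(J_hz=1.0, t_mix_ms=250.0, r600_per_s=0.0)
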