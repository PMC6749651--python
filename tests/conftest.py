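import numpy as np
import pytest

from satkit.seqio import SatelliteCall, make_sat_id


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_call(consensus: str, start: int = 101, replicon_id: str = "rep1",
              n_copies: int = 5, ni: int = 5, score: float = 1.0,
              sequence: str | None = None) -> SatelliteCall:
    """A syntactically valid call whose repeat is `consensus` tiled n times."""
    period = len(consensus)
    if sequence is None:
        sequence = consensus * n_copies
    end = start + len(sequence) - 1
    return SatelliteCall(
        sat_id=make_sat_id(replicon_id, start, end), replicon_id=replicon_id,
        start=start, end=end, period=period, n_copies=n_copies, ni=ni,
        score=score, consensus=consensus, sequence=sequence)


def random_calls(rng: np.random.Generator, n: int) -> list[SatelliteCall]:
    """Valid random calls at non-overlapping coordinates (for I/O round-trips)."""
    calls = []
    pos = 1
    for _ in range(n):
        period = int(rng.integers(10, 60))
        copies = int(rng.integers(4, 12))
        unit = "".join("ACGT"[i] for i in rng.integers(0, 4, period))
        ni = int(rng.integers(int(np.ceil(0.6 * copies)), copies + 1))
        score = round(float(rng.uniform(0.5, 1.0)), 3)
        calls.append(make_call(unit, start=pos, n_copies=copies, ni=ni, score=score))
        pos += period * copies + int(rng.integers(50, 500))
    return calls
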