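import numpy as np
import pytest

from karyodiv.io import ChromosomeRecord, MetaphaseSpread


def make_spread(lengths, cis=None, cell_id="c1", individual_id="i1", pop="P"):
    """Build a spread from total lengths (and optional CIs, default 40)."""
    if cis is None:
        cis = [40.0] * len(lengths)
    records = []
    for k, (length, ci) in enumerate(zip(lengths, cis)):
        short = length * ci / 100.0
        records.append(
            ChromosomeRecord.from_arms(cell_id, f"chr{k}", short, length - short)
        )
    return MetaphaseSpread(cell_id, individual_id, pop, tuple(records))


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)
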