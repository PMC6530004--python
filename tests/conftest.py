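import numpy as np
import pytest

from tehistory import simkit
from tehistory.copyassign import ConsensusSequence, Hit


@pytest.fixture(scope="session")
def two_burst_sim():
    """Two same-species bursts, 300 copies each, masters ~3% apart (kappa=1)."""
    cfg = simkit.SimulationConfig(
        elements=(simkit.ElementModel("E", 200),),
        bursts=(
            simkit.BurstSpec("old", "E", "split_B", 10.0, 300, 0.0),
            simkit.BurstSpec("young", "E", "split_B", 8.0, 300, 3.0),
        ),
        split_divergence=5.0,
        background_genome_bp=150_000,
        read_length_range=(450, 550),
        seed=42,
    )
    readsets, truth, masters = simkit.simulate(cfg)
    return cfg, readsets, truth, masters


def make_gapfree_hit(consensus: str, read: str, offset: int = 0, read_id: str = "r", species: str = "sp") -> Hit:
    """Hit whose read aligns consensus columns offset..offset+len(read)-1 without gaps."""
    from tehistory.seqio import encode

    n = len(read)
    pairs = np.stack([np.arange(offset, offset + n), np.arange(n)], axis=1).astype(np.int32)
    return Hit(
        read_id=read_id,
        species=species,
        consensus_id="c",
        read_start=1,
        read_end=n,
        consensus_start=offset + 1,
        consensus_end=offset + n,
        strand="+",
        pairs=pairs,
        read_codes=encode(read),
        query_coverage=100.0 * n / len(consensus),
        identity=float("nan"),
    )
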