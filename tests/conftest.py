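import pytest

import histodiff as hd
from histodiff import amplification as amp
from histodiff import coverage


# Config for amplification-recovery runs: gene-free uniform background with
# enough depth that the fold-6 implant clears the 5-fold criteria with a
# comfortable sampling margin.
AMP_FIXTURE = dict(
    genome=(("chr1", 250_000),),
    n_genes=0,
    background_depth=0.8,
    gained_gene_frac=0.0,
    lost_gene_frac=0.0,
)


def build_tracks(data):
    """Dedup reads, pile up with the default 50-bp center-ward shift, and
    normalize, for both samples of a simulated dataset."""
    tracks = {}
    for name, reads in (("control", data.reads_control), ("case", data.reads_case)):
        kept, _ = amp.dedup_reads(reads)
        raw = coverage.pileup(kept, coverage.ShiftParams(), data.sizes)
        tracks[name] = coverage.normalize(raw)
    return tracks


def jaccard(a, b):
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    union = (a.end - a.start) + (b.end - b.start) - inter
    return inter / union if union else 0.0


@pytest.fixture(scope="session")
def default_sim():
    """One default-config simulated dataset shared across tests."""
    return hd.simulate(hd.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_tracks(default_sim):
    return build_tracks(default_sim)
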