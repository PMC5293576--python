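"""Shared helpers for the example scripts."""

import histodiff as hd
from histodiff import amplification, coverage


def build_tracks(data):
    tracks = {}
    for name, reads in (("control", data.reads_control), ("case", data.reads_case)):
        kept, _ = amplification.dedup_reads(reads)
        raw = coverage.pileup(kept, coverage.ShiftParams(), data.sizes)
        tracks[name] = coverage.normalize(raw)
    return tracks


def simulate_and_pileup(seed=7):
    data = hd.simulate(hd.SimulationConfig(seed=seed))
    return data, build_tracks(data)
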