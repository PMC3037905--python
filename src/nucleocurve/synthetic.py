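"""Seeded synthetic fixtures with the structure the method assumes.

Every generator is a pure function of its parameters and seed, and
records the planted truth so downstream stages can be scored against
it.  Substreams are derived from (seed, generator id) so adding a
generator never perturbs existing fixtures.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AnchorSite, GenomeSequence, ScoreTrack, CORE_LEN, DYAD_FLANK
from .curvature import CurvaturePattern

# fixed substream ids, one per generator
_STREAM_GENOME = 1
_STREAM_SIGNAL = 2
_STREAM_NUCSEQ = 3
_STREAM_TSS = 4

#: WW phase-grid periods inside a planted core: tighter at the bent
#: ~50-bp ends, looser in the straighter ~47-bp middle.
END_PERIOD = 10.3
MID_PERIOD = 11.1
END_LEN = 50
MID_LEN = 47


@dataclass(frozen=True)
class FixtureTruth:
    """What a generator planted, verbatim, for scoring recovery."""

    dyads: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    labels: tuple = ()
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        dyads = np.asarray(self.dyads, dtype=int)
        if np.any(np.diff(dyads) < 0):
            raise ValueError("truth dyads must be sorted")
        object.__setattr__(self, "dyads", dyads)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


def random_genome(
    length: int,
    gc_fraction: float = 0.5,
    seed: int = 0,
    chrom: str = "synth",
) -> GenomeSequence:
    """i.i.d. random sequence with the given GC fraction (seeded)."""
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = _rng(seed, _STREAM_GENOME)
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                       size=length, p=[at, gc, gc, at])
    return GenomeSequence(chrom, bases.tobytes().decode("ascii"))


def plant_signal_pattern(
    length: int,
    pattern: CurvaturePattern,
    dyads,
    noise_sd: float,
    seed: int = 0,
    chrom: str = "synth",
) -> tuple[ScoreTrack, FixtureTruth]:
    """Zero track + pattern copies (peak amplitude 1) at dyads + noise.

    The pattern is rescaled so its largest absolute value is 1; the SNR
    of the fixture is therefore 1 / noise_sd.
    """
    dyads = np.asarray(sorted(int(d) for d in dyads), dtype=int)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    amp = pattern.values / np.abs(pattern.values).max()
    L = len(amp)
    left, right = pattern.dyad_index, L - pattern.dyad_index
    if np.any(dyads - left < 0) or np.any(dyads + right > length):
        raise ValueError("a dyad is too close to a track end for the pattern")
    if len(dyads) > 1 and np.any(np.diff(dyads) < CORE_LEN):
        raise ValueError("planted dyads must be >= 147 bp apart")
    rng = _rng(seed, _STREAM_SIGNAL)
    values = np.zeros(length)
    for d in dyads:
        values[d - left:d - left + L] += amp
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=length)
    truth = FixtureTruth(
        dyads, params={"length": length, "noise_sd": noise_sd, "seed": seed}
    )
    return ScoreTrack(chrom, 0, values), truth


#: length of the phased A/T homopolymer tract planted at each end-grid
#: point; a tract of 5 spans half a helical turn, so its wedge vectors
#: add coherently and the ends bend strongly
END_TRACT = 5


def _core_cassette(rng: np.random.Generator) -> str:
    """A 147-bp core: phased A/T runs on a G/C background.

    The two 50-bp ends carry 5-bp A (or T) tracts on a 10.3-bp phase
    grid — wedge vectors recurring in helical phase, the composition
    that bends DNA around the histone core — while the 47-bp middle
    carries only single WW dinucleotides on an 11.1-bp grid, whose
    wedges largely self-cancel against the flanking G/C steps.  The
    resulting curvature curve is high over the ends and low over the
    middle, the canonical nucleosomal shape.
    """
    bases = rng.choice(["G", "C"], size=CORE_LEN).tolist()

    def place(pos: int, run: int):
        b = "A" if rng.random() < 0.5 else "T"
        for i in range(pos, min(pos + run, CORE_LEN)):
            bases[i] = b

    k = 0
    while round(k * END_PERIOD) + END_TRACT <= END_LEN:
        place(round(k * END_PERIOD), END_TRACT)
        k += 1
    k = 0
    while END_LEN + round(k * MID_PERIOD) < END_LEN + MID_LEN - 1:
        place(END_LEN + round(k * MID_PERIOD), 2)
        k += 1
    k = 0
    stop = END_LEN + MID_LEN
    while stop + round(k * END_PERIOD) + END_TRACT <= CORE_LEN:
        place(stop + round(k * END_PERIOD), END_TRACT)
        k += 1
    return "".join(bases)


def plant_sequence_nucleosomes(
    length: int,
    dyad_spacing: int = 190,
    seed: int = 0,
    gc_fraction: float = 0.5,
    chrom: str = "synth",
    margin: int = 300,
) -> tuple[GenomeSequence, FixtureTruth]:
    """Random background with phased-WW 147-bp cores at regular dyads."""
    if length < 2000:
        raise ValueError("length must be >= 2000")
    rng = _rng(seed, _STREAM_NUCSEQ)
    background = list(random_genome(length, gc_fraction, seed, chrom).seq)
    dyads = np.arange(margin, length - margin, dyad_spacing, dtype=int)
    for d in dyads:
        cassette = _core_cassette(rng)
        background[d - DYAD_FLANK:d + DYAD_FLANK + 1] = cassette
    truth = FixtureTruth(
        dyads,
        params={"length": length, "dyad_spacing": dyad_spacing,
                "seed": seed, "gc_fraction": gc_fraction},
    )
    return GenomeSequence(chrom, "".join(background)), truth


def tss_class_fixture(
    n_sites: int,
    flank: int = 300,
    seed: int = 0,
    snr: float = 3.0,
    chrom: str = "synth",
) -> tuple[ScoreTrack, list[AnchorSite], FixtureTruth]:
    """Occupied-vs-free TSS fixture for the k-means classifier.

    Half the sites get an occupancy bump of amplitude 1 over
    [-150, +50] (truth label "I"), half a trough of -1 (truth "II"),
    plus Gaussian noise of sd 1/snr everywhere.  Sites are laid out on
    one track far enough apart that windows never overlap.
    """
    if n_sites < 10:
        raise ValueError("n_sites must be >= 10")
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = _rng(seed, _STREAM_TSS)
    pitch = 2 * flank + 250
    length = n_sites * pitch + 2 * flank
    values = np.zeros(length)
    anchors, labels = [], []
    order = rng.permutation(n_sites)  # interleave classes along the track
    for i in range(n_sites):
        pos = flank + i * pitch
        occupied = order[i] < (n_sites + 1) // 2
        lo, hi = pos - 150, pos + 50
        values[lo:hi + 1] += 1.0 if occupied else -1.0
        label = "I" if occupied else "II"
        anchors.append(AnchorSite(chrom, pos, "+", f"TSS-{label}"))
        labels.append(label)
    values += rng.normal(0.0, 1.0 / snr, size=length)
    truth = FixtureTruth(
        labels=tuple(labels),
        params={"n_sites": n_sites, "flank": flank, "seed": seed, "snr": snr},
    )
    return ScoreTrack(chrom, 0, values), anchors, truth
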