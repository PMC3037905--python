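"""Shared domain containers.

Coordinates are 0-based throughout; intervals are half-open. A nucleosome
call is a dyad position plus the 147-bp core obtained by extending 73 bp
on each side (start = dyad - 73, end = dyad + 74).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CORE_LEN = 147
DYAD_FLANK = 73

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: base -> integer code; N and anything unexpected maps to 4 (invalid)
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGTN string (case preserved for ACGTN)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence over {A,C,G,T,N}, uppercase."""

    chrom: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def encode(self) -> np.ndarray:
        """Integer codes A=0 C=1 G=2 T=3, N (or other) = 4."""
        codes = np.full(len(self.seq), 4, dtype=np.int8)
        arr = np.frombuffer(self.seq.encode("ascii"), dtype=np.uint8)
        for base, code in _BASE_CODE.items():
            codes[arr == ord(base)] = code
        return codes

    def reverse_complement(self) -> "GenomeSequence":
        return GenomeSequence(self.chrom, reverse_complement(self.seq))


@dataclass(frozen=True)
class AnchorSite:
    """A genomic anchor (TSS, SNP, miRNA target site, ...)."""

    chrom: str
    pos: int
    strand: str = "+"
    label: str = ""

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"anchor pos must be >= 0, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class ScoreTrack:
    """Per-base signal starting at a 0-based offset, 1-bp step.

    ``mask`` (optional) is True at positions whose value carries no
    evidence (e.g. a curvature window overlapping an N); such values are 0.
    """

    chrom: str
    start: int
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.start < 0:
            raise ValueError("track start must be >= 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("track values must be finite")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask/value length mismatch")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def end(self) -> int:
        return self.start + len(self.values)

    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.end)

    def value_at(self, pos: int) -> float:
        if not self.start <= pos < self.end:
            raise IndexError(f"position {pos} outside track [{self.start}, {self.end})")
        return float(self.values[pos - self.start])


@dataclass(frozen=True)
class PFMRecord:
    """Position frequency matrix: 4 x L counts in row order A, C, G, T."""

    tf_name: str
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError("PFM counts must be a 4 x L matrix with L >= 1")
        if np.any(counts < 0):
            raise ValueError("PFM counts must be non-negative")
        if np.any(counts.sum(axis=0) <= 0):
            raise ValueError("every PFM column must have a positive count sum")

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class NucleosomeCall:
    """A called nucleosome: dyad plus its 147-bp core interval."""

    chrom: str
    dyad: int
    score: float

    @property
    def start(self) -> int:
        return self.dyad - DYAD_FLANK

    @property
    def end(self) -> int:
        return self.dyad + DYAD_FLANK + 1

    def __post_init__(self):
        if not np.isfinite(self.score):
            raise ValueError("call score must be finite")


@dataclass
class CallSet:
    """Nucleosome calls on one chromosome, sorted by dyad."""

    chrom: str
    calls: list[NucleosomeCall] = field(default_factory=list)
    min_distance: int | None = None

    def __post_init__(self):
        self.calls = sorted(self.calls, key=lambda c: c.dyad)
        if self.min_distance is not None and len(self.calls) > 1:
            gaps = np.diff([c.dyad for c in self.calls])
            if np.any(gaps < self.min_distance):
                raise ValueError("consecutive dyads closer than min_distance")

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    @property
    def dyads(self) -> np.ndarray:
        return np.array([c.dyad for c in self.calls], dtype=int)

    @property
    def scores(self) -> np.ndarray:
        return np.array([c.score for c in self.calls], dtype=float)

    @classmethod
    def from_dyads(cls, chrom: str, dyads, scores=None, min_distance=None) -> "CallSet":
        dyads = np.asarray(dyads, dtype=int)
        if scores is None:
            scores = np.zeros(len(dyads))
        calls = [NucleosomeCall(chrom, int(d), float(s)) for d, s in zip(dyads, scores)]
        return cls(chrom, calls, min_distance)


@dataclass
class AnchoredProfile:
    """Signal averaged across anchor sites as a function of offset.

    ``mean_signal`` is NaN at offsets no site covered; ``n_sites`` counts
    the sites contributing at each offset.
    """

    offsets: np.ndarray
    mean_signal: np.ndarray
    n_sites: np.ndarray

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.mean_signal = np.asarray(self.mean_signal, dtype=float)
        self.n_sites = np.asarray(self.n_sites, dtype=int)
        if not (len(self.offsets) == len(self.mean_signal) == len(self.n_sites)):
            raise ValueError("profile arrays must share a length")
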