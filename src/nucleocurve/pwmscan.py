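"""PWM scanning of promoters and cross-TF average binding profiles.

Position frequency matrices are converted to base-2 log-odds weight
matrices (pseudocount 0.5, uniform background by default).  A scan
scores every placement on both strands and keeps the larger; per
(TF, promoter) tracks are min-max normalized to [0, 1] before averaging
so that TFs with different motif information content weigh equally.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import GenomeSequence, PFMRecord, ScoreTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PWM:
    """Log-odds (base 2) position weight matrix, rows A, C, G, T."""

    tf_name: str
    log_odds: np.ndarray
    background: np.ndarray
    pseudocount: float

    def __post_init__(self):
        lo = np.asarray(self.log_odds, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "log_odds", lo)
        object.__setattr__(self, "background", bg)
        if lo.ndim != 2 or lo.shape[0] != 4 or lo.shape[1] < 1:
            raise ValueError("log_odds must be 4 x L with L >= 1")
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 probabilities summing to 1")

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.log_odds, axis=0))


def pfm_to_pwm(
    pfm: PFMRecord,
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> PWM:
    """Counts -> frequencies (with pseudocount) -> base-2 log-odds."""
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    colsums = pfm.counts.sum(axis=0)
    if pseudocount == 0 and np.any(colsums == 0):
        raise ValueError("zero-sum PFM column with pseudocount 0")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    freqs = (pfm.counts + pseudocount) / (colsums + 4 * pseudocount)
    log_odds = np.log2(freqs / background[:, None])
    return PWM(pfm.tf_name, log_odds, background, pseudocount)


def scan_scores(seq: GenomeSequence, pwm: PWM) -> ScoreTrack:
    """Best-strand log-odds score of the motif at every placement.

    The value at position p scores the placement covering bases
    p .. p+L-1: max of the forward-strand sum and the score of the
    placement's reverse complement.  Placements containing a non-ACGT
    base are masked (value 0).
    """
    L = pwm.length
    if len(seq) < L:
        raise ValueError(f"sequence length {len(seq)} < motif length {L}")
    codes = seq.encode()
    n_pos = len(seq) - L + 1
    M = pwm.log_odds
    # reverse strand == scanning with the reverse-complemented matrix
    M_rc = M[::-1, ::-1]
    fwd = np.zeros(n_pos)
    rev = np.zeros(n_pos)
    safe = np.minimum(codes, 3)
    for c in range(L):
        col = safe[c:c + n_pos]
        fwd += M[col, c]
        rev += M_rc[col, c]
    scores = np.maximum(fwd, rev)
    invalid = codes >= 4
    bad = np.zeros(n_pos, dtype=bool)
    for c in range(L):
        bad |= invalid[c:c + n_pos]
    scores[bad] = 0.0
    return ScoreTrack(seq.chrom, 0, scores, mask=bad)


@dataclass
class BindingProfile:
    """Cross-TF, cross-promoter average of normalized binding scores."""

    offsets: np.ndarray
    mean_score: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.mean_score = np.asarray(self.mean_score, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)


def average_binding_profile(
    promoters: list[GenomeSequence],
    pwms: list[PWM],
    tss_offset: int = 0,
) -> BindingProfile:
    """Average min-max-normalized scan tracks over all (TF, promoter) pairs.

    All promoters must share one length; ``tss_offset`` is the 0-based
    position of the TSS within each promoter, so reported offsets are
    placement starts relative to the TSS.  A pair whose track is
    constant contributes a flat 0.5 (with a warning).  Offsets are
    averaged over the pairs defined there (motif lengths may differ).
    """
    if not promoters or not pwms:
        raise ValueError("need at least one promoter and one PWM")
    lengths = {len(p) for p in promoters}
    if len(lengths) != 1:
        raise ValueError(f"promoters have mixed lengths: {sorted(lengths)}")
    plen = lengths.pop()
    total = np.zeros(plen)
    count = np.zeros(plen, dtype=int)
    for pwm in pwms:
        for prom in promoters:
            track = scan_scores(prom, pwm)
            vals = track.values
            ok = ~track.mask if track.mask is not None else np.ones(len(vals), bool)
            if not ok.any():
                continue
            vmin, vmax = vals[ok].min(), vals[ok].max()
            if vmax == vmin:
                logger.warning(
                    "constant scan for %s on %s; contributing flat 0.5",
                    pwm.tf_name, prom.chrom,
                )
                norm = np.full(len(vals), 0.5)
            else:
                norm = (vals - vmin) / (vmax - vmin)
            n_pos = len(vals)
            total[:n_pos] += np.where(ok, norm, 0.0)
            count[:n_pos] += ok
    defined = count > 0
    if not defined.any():
        raise ValueError("no scannable placement on any promoter")
    offsets = np.arange(plen) - tss_offset
    with np.errstate(invalid="ignore"):
        mean = np.where(defined, total / np.maximum(count, 1), np.nan)
    return BindingProfile(offsets[defined], mean[defined], count[defined])
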