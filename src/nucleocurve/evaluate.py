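"""Comparing dyad call sets and quantifying sequence dependence.

A reference dyad "matches" when some predicted dyad lies within a given
deviation; sweeping the deviation from 1 to 60 bp gives the matching
curve.  Sequence dependence is measured by correlating, between two
call sets, the fraction of each hexanucleotide's genomic occurrences
that fall inside called 147-bp cores.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .core import CallSet, GenomeSequence, CORE_LEN

HEXAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=6)]


def overlap_ratio(deviation: float) -> float:
    """Degree of overlap of two 147-bp cores whose dyads differ by ``deviation``.

    Implements the published formula [2*(73 - d) + d] / 147 literally.
    (The geometric overlap of two 147-bp intervals offset by d would be
    (147 - d)/147; the printed form is kept for fidelity — the two agree
    at d = 0 and d = 73 but not between.)
    """
    if not 0 <= deviation <= 73:
        raise ValueError(f"deviation must lie in [0, 73], got {deviation}")
    return (2 * (73 - deviation) + deviation) / CORE_LEN


def matching_ratio(reference_dyads, predicted_dyads, deviation: float,
                   mode: str = "any") -> float:
    """Fraction of reference dyads with a predicted dyad within +/- deviation.

    ``mode="any"`` counts a reference dyad as matched if any prediction
    falls inside its window (one prediction may serve several
    references); ``mode="one_to_one"`` greedily pairs nearest
    reference/prediction pairs, consuming each prediction once.
    """
    ref = np.sort(np.asarray(reference_dyads, dtype=float))
    pred = np.sort(np.asarray(predicted_dyads, dtype=float))
    if len(ref) == 0:
        raise ValueError("reference dyad set is empty")
    if len(pred) == 0:
        return 0.0
    if mode == "any":
        idx = np.searchsorted(pred, ref)
        left = np.abs(ref - pred[np.clip(idx - 1, 0, len(pred) - 1)])
        right = np.abs(ref - pred[np.clip(idx, 0, len(pred) - 1)])
        return float(np.mean(np.minimum(left, right) <= deviation))
    if mode == "one_to_one":
        pairs = [(abs(r - p), i, j) for i, r in enumerate(ref) for j, p in enumerate(pred)
                 if abs(r - p) <= deviation]
        pairs.sort()
        used_r, used_p = set(), set()
        for _, i, j in pairs:
            if i not in used_r and j not in used_p:
                used_r.add(i)
                used_p.add(j)
        return len(used_r) / len(ref)
    raise ValueError(f"unknown matching mode {mode!r}")


@dataclass
class MatchCurve:
    """Matching ratio as a function of allowed dyad deviation."""

    deviation: np.ndarray
    matching_ratio: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"deviation": self.deviation, "matching_ratio": self.matching_ratio}
        )


def match_curve(reference_dyads, predicted_dyads, d_max: int = 60,
                mode: str = "any") -> MatchCurve:
    """matching_ratio swept over deviations 1..d_max."""
    devs = np.arange(1, d_max + 1)
    ratios = np.array(
        [matching_ratio(reference_dyads, predicted_dyads, d, mode) for d in devs]
    )
    return MatchCurve(devs, ratios)


def hexamer_occupancy(genome: GenomeSequence, callset: CallSet,
                      collapse_rc: bool = False) -> pd.DataFrame:
    """Occupancy ratio of every hexanucleotide under a call set.

    Each forward-strand hexamer occurrence (any offset, windows with N
    skipped) is "occupied" iff its 6-bp span lies entirely inside some
    call's 147-bp core.  Returns a frame indexed by hexamer with
    total_count, occupied_count, occupancy_ratio and free_ratio;
    ratios are NaN for hexamers absent from the sequence.
    ``collapse_rc`` pools each hexamer with its reverse complement.
    """
    if callset.chrom != genome.chrom:
        raise ValueError("call set and genome are on different chromosomes")
    codes = genome.encode()
    n = len(codes)
    if n < 6:
        raise ValueError("sequence shorter than a hexamer")
    win = sliding_window_view(codes, 6)
    valid = (win < 4).all(axis=1)
    hex_idx = win.astype(np.int64) @ (4 ** np.arange(5, -1, -1))

    occupied = np.zeros(n - 5, dtype=bool)
    for call in callset:
        lo = max(0, call.start)
        hi = min(n - 5, call.end - 5)  # last start s with s+6 <= call.end
        if hi > lo:
            occupied[lo:hi] = True

    total = np.bincount(hex_idx[valid], minlength=4096)
    occ = np.bincount(hex_idx[valid & occupied], minlength=4096)
    if collapse_rc:
        rc_map = np.array(
            [HEXAMERS.index(_rc6(h)) for h in HEXAMERS], dtype=int
        )
        total = total + np.where(rc_map != np.arange(4096), total[rc_map], 0)
        occ = occ + np.where(rc_map != np.arange(4096), occ[rc_map], 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, occ / np.maximum(total, 1), np.nan)
    return pd.DataFrame(
        {
            "total_count": total,
            "occupied_count": occ,
            "occupancy_ratio": ratio,
            "free_ratio": 1.0 - ratio,
        },
        index=pd.Index(HEXAMERS, name="hexamer"),
    )


def _rc6(hexamer: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(hexamer))


def occupancy_correlation(table_a: pd.DataFrame, table_b: pd.DataFrame) -> float:
    """Pearson correlation of occupancy ratios over shared hexamers."""
    shared = table_a.index.intersection(table_b.index)
    a = table_a.loc[shared, "occupancy_ratio"]
    b = table_b.loc[shared, "occupancy_ratio"]
    ok = a.notna() & b.notna()
    if ok.sum() < 3:
        raise ValueError("fewer than 3 hexamers present in both tables")
    r, _ = stats.pearsonr(a[ok], b[ok])
    return float(r)
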