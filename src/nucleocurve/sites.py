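"""Site-centered (anchored) analyses.

Signals or sequence features are averaged across a set of genomic
anchors (TSSs, SNP sites, miRNA target sites, ...) as a function of
offset from the anchor, with minus-strand sites contributing their
reverse-oriented window.  TSSs can additionally be split into
nucleosome-occupied (class I) and nucleosome-free (class II) groups by
k-means clustering of the per-site signal over [-150, +50].
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .core import AnchoredProfile, AnchorSite, GenomeSequence, ScoreTrack, reverse_complement

logger = logging.getLogger(__name__)

WW = {"AA", "AT", "TA", "TT"}
SS = {"CC", "CG", "GC", "GG"}


def _site_window(track: ScoreTrack, site: AnchorSite, lo: int, hi: int):
    """Values and coverage flags of a site's oriented window [lo, hi].

    Offsets run lo..hi in the site's own orientation (downstream
    positive); minus-strand windows are reversed.  Uncovered offsets are
    flagged False.
    """
    n = hi - lo + 1
    vals = np.zeros(n)
    cov = np.zeros(n, dtype=bool)
    if site.strand == "+":
        genomic = site.pos + np.arange(lo, hi + 1)
    else:
        genomic = site.pos - np.arange(lo, hi + 1)
    inside = (genomic >= track.start) & (genomic < track.end)
    vals[inside] = track.values[genomic[inside] - track.start]
    cov[inside] = True
    return vals, cov


def anchored_profile(
    track: ScoreTrack,
    anchors: list[AnchorSite],
    flank: int,
    scale_mode: str = "none",
) -> AnchoredProfile:
    """Average a track across anchors as a function of offset.

    Per site the window [pos - flank, pos + flank] is extracted
    (reversed for minus-strand sites), optionally z-scored across its
    covered values (``scale_mode="zscore"``), and averaged positionwise;
    offsets outside the track contribute nothing and are excluded from
    the per-offset counts.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if scale_mode not in ("none", "zscore"):
        raise ValueError("scale_mode must be 'none' or 'zscore'")
    n = 2 * flank + 1
    total = np.zeros(n)
    count = np.zeros(n, dtype=int)
    for site in anchors:
        vals, cov = _site_window(track, site, -flank, flank)
        if not cov.any():
            continue
        if scale_mode == "zscore":
            m = vals[cov].mean()
            s = vals[cov].std()
            vals = np.where(cov, (vals - m) / s if s > 0 else vals - m, 0.0)
        total += np.where(cov, vals, 0.0)
        count += cov
    if count.sum() == 0:
        raise ValueError("no anchor overlaps the track")
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return AnchoredProfile(np.arange(-flank, flank + 1), mean, count)


@dataclass
class TssClassAssignment:
    """k-means split of TSSs into occupied (I) and nucleosome-free (II)."""

    sites: list[AnchorSite]
    labels: list[str]  # "I" or "II" per site, aligned with ``sites``

    def of_class(self, label: str) -> list[AnchorSite]:
        return [s for s, l in zip(self.sites, self.labels) if l == label]

    def counts(self) -> dict[str, int]:
        return {l: self.labels.count(l) for l in ("I", "II")}


def classify_tss(
    track: ScoreTrack,
    anchors: list[AnchorSite],
    window: tuple[int, int] = (-150, 50),
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 20,
) -> TssClassAssignment:
    """Cluster TSSs by their occupancy signal over ``window``.

    Sites without full window coverage are excluded.  Clustering is
    k-means (Euclidean, ``n_restarts`` seeded restarts) on the raw
    per-site signal vectors; the cluster whose center has the greater
    mean becomes class I (nucleosome-occupied), the other class II
    (nucleosome-free), so labels do not depend on cluster indexing.
    """
    lo, hi = window
    usable, vectors = [], []
    for site in anchors:
        vals, cov = _site_window(track, site, lo, hi)
        if cov.all():
            usable.append(site)
            vectors.append(vals)
    if len(usable) < 2:
        raise ValueError("need >= 2 sites with full window coverage")
    X = np.asarray(vectors)
    if np.allclose(X, X[0]):
        logger.warning("all site vectors identical; assigning a single class")
        return TssClassAssignment(usable, ["I"] * len(usable))
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    idx = km.fit_predict(X)
    center_means = km.cluster_centers_.mean(axis=1)
    occupied_cluster = int(np.argmax(center_means))
    labels = ["I" if i == occupied_cluster else "II" for i in idx]
    return TssClassAssignment(usable, labels)


def _oriented_window_seq(genome: GenomeSequence, site: AnchorSite, lo: int, hi: int) -> str:
    """Site-oriented bases for offsets lo..hi; '.' where off-chromosome."""
    n = len(genome.seq)
    if site.strand == "+":
        start, stop = site.pos + lo, site.pos + hi + 1
        chunk = genome.seq[max(0, start):max(0, min(n, stop))]
        left_pad = max(0, -start)
        right_pad = max(0, stop - n) if stop > n else 0
        return "." * left_pad + chunk + "." * right_pad
    # minus strand: offset o maps to genomic pos - o, complemented
    start, stop = site.pos - hi, site.pos - lo + 1
    chunk = genome.seq[max(0, start):max(0, min(n, stop))]
    left_pad = max(0, -start)        # pads the hi end after reversal
    right_pad = max(0, stop - n) if stop > n else 0
    oriented = reverse_complement(chunk)
    return "." * right_pad + oriented + "." * left_pad


def dinucleotide_fraction_profile(
    genome: GenomeSequence,
    anchors: list[AnchorSite],
    flank: int,
    dinuc_class: str,
) -> AnchoredProfile:
    """Fraction of sites whose dinucleotide at each offset is WW or SS.

    WW = {AA, AT, TA, TT}, SS = {CC, CG, GC, GG}.  The dinucleotide at
    offset o is the oriented bases at o and o+1; minus-strand sites use
    the reverse complement.  Dinucleotides touching N (or running off
    the chromosome) are excluded from that offset's denominator.
    """
    classes = {"WW": WW, "SS": SS}
    if dinuc_class not in classes:
        raise ValueError("dinuc_class must be 'WW' or 'SS'")
    members = classes[dinuc_class]
    if flank < 1:
        raise ValueError("flank must be >= 1")
    n = 2 * flank + 1
    hits = np.zeros(n)
    count = np.zeros(n, dtype=int)
    for site in anchors:
        w = _oriented_window_seq(genome, site, -flank, flank + 1)
        for i in range(n):
            dinuc = w[i:i + 2]
            if any(b not in "ACGT" for b in dinuc):
                continue
            count[i] += 1
            if dinuc in members:
                hits[i] += 1
    if count.sum() == 0:
        raise ValueError("no anchor window overlaps the sequence")
    with np.errstate(invalid="ignore"):
        frac = np.where(count > 0, hits / np.maximum(count, 1), np.nan)
    return AnchoredProfile(np.arange(-flank, flank + 1), frac, count)


def _polytract_flags(window: str, min_run: int) -> np.ndarray:
    """True where the base sits in a pure A (or pure T) run >= min_run."""
    flags = np.zeros(len(window), dtype=bool)
    i = 0
    while i < len(window):
        b = window[i]
        j = i
        while j < len(window) and window[j] == b:
            j += 1
        if b in "AT" and j - i >= min_run:
            flags[i:j] = True
        i = j
    return flags


def polytract_fraction_profile(
    genome: GenomeSequence,
    anchors: list[AnchorSite],
    flank: int,
    min_run: int = 4,
) -> AnchoredProfile:
    """Fraction of sites inside a poly(dA:dT) tract at each offset.

    A position counts when it lies in a homopolymer run of A, or of T,
    of length >= ``min_run`` within the oriented window (runs truncated
    by the window edge are measured as seen).
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    if flank < 1:
        raise ValueError("flank must be >= 1")
    n = 2 * flank + 1
    hits = np.zeros(n)
    count = np.zeros(n, dtype=int)
    for site in anchors:
        w = _oriented_window_seq(genome, site, -flank, flank)
        flags = _polytract_flags(w, min_run)
        for i, b in enumerate(w):
            if b in "ACGT":
                count[i] += 1
                if flags[i]:
                    hits[i] += 1
    if count.sum() == 0:
        raise ValueError("no anchor window overlaps the sequence")
    with np.errstate(invalid="ignore"):
        frac = np.where(count > 0, hits / np.maximum(count, 1), np.nan)
    return AnchoredProfile(np.arange(-flank, flank + 1), frac, count)
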