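"""Readers and writers for the formats the toolkit touches.

Conventions: all coordinates 0-based, intervals half-open.  Score
tracks come in two dialects — ``two_column`` (position<TAB>score rows,
sorted, gaps zero-filled) and ``fixed_step`` (a ``fixedStep`` header
with a 0-based start, then one value per line).  Calls go out as BED6.
"""
from __future__ import annotations

import logging
import re

import numpy as np
from Bio import SeqIO

from .core import AnchorSite, CallSet, GenomeSequence, NucleosomeCall, PFMRecord, ScoreTrack
from .curvature import CurvaturePattern

logger = logging.getLogger(__name__)

_VALID_SEQ = re.compile(r"^[ACGTN]*$")


class FormatError(ValueError):
    """A file did not conform to its declared dialect."""


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> list[GenomeSequence]:
    """Load FASTA records, uppercasing; alphabet restricted to ACGTN."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not _VALID_SEQ.match(seq):
            raise FormatError(
                f"record {rec.id!r}: illegal character at "
                f"line {_find_bad_line(path, rec.id)}"
            )
        records.append(GenomeSequence(rec.id, seq))
    return records


def _find_bad_line(path, rec_id: str) -> int:
    """Locate the first offending sequence line of a record, for the error."""
    in_rec = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                in_rec = line[1:].split()[0] == rec_id if line[1:].strip() else False
                continue
            if in_rec and not _VALID_SEQ.match(line.strip().upper()):
                return lineno
    return -1


def write_fasta(seqs: list[GenomeSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.chrom}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i:i + width] + "\n")


# --------------------------------------------------------- anchor table

def read_anchor_table(path) -> list[AnchorSite]:
    """TSV of chrom, pos (0-based), strand [+/-], label; strand defaults '+'."""
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"line {lineno}: need at least chrom and pos")
            try:
                pos = int(fields[1])
            except ValueError:
                raise FormatError(
                    f"line {lineno}: position {fields[1]!r} is not an integer"
                ) from None
            strand = fields[2] if len(fields) > 2 and fields[2] else "+"
            label = fields[3] if len(fields) > 3 else ""
            try:
                sites.append(AnchorSite(fields[0], pos, strand, label))
            except ValueError as e:
                raise FormatError(f"line {lineno}: {e}") from None
    return sites


def write_anchor_table(sites: list[AnchorSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom\tpos\tstrand\tlabel\n")
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.strand}\t{s.label}\n")


# ---------------------------------------------------------- score track

def read_score_track(path, dialect: str, chrom: str = "") -> ScoreTrack:
    """Read a per-position score series.

    ``two_column``: rows "position<TAB>score" sorted by position; gaps
    between listed positions are filled with 0.0 (absent rows mean no
    evidence, not missing data).  ``fixed_step``: a header line
    "fixedStep chrom=<c> start=<s> step=1" (start 0-based in this
    dialect) followed by one score per line.
    """
    if dialect == "two_column":
        positions, scores = [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise FormatError(f"line {lineno}: expected 2 columns")
                try:
                    positions.append(int(fields[0]))
                    scores.append(float(fields[1]))
                except ValueError:
                    raise FormatError(f"line {lineno}: malformed row {line!r}") from None
        if not positions:
            raise FormatError("empty two_column track")
        positions = np.asarray(positions)
        if np.any(np.diff(positions) <= 0):
            bad = int(np.flatnonzero(np.diff(positions) <= 0)[0])
            raise FormatError(
                f"positions not strictly increasing near position {positions[bad + 1]}"
            )
        start = int(positions[0])
        values = np.zeros(int(positions[-1]) - start + 1)
        values[positions - start] = scores
        return ScoreTrack(chrom, start, values)
    if dialect == "fixed_step":
        with open(path) as fh:
            header = fh.readline().strip()
            m = re.match(r"fixedStep\s+chrom=(\S+)\s+start=(\d+)\s+step=1", header)
            if not m:
                raise FormatError(f"bad fixedStep header: {header!r}")
            values = []
            for lineno, line in enumerate(fh, 2):
                line = line.strip()
                if not line:
                    continue
                try:
                    values.append(float(line))
                except ValueError:
                    raise FormatError(f"line {lineno}: not a number: {line!r}") from None
        return ScoreTrack(chrom or m.group(1), int(m.group(2)), np.asarray(values))
    raise ValueError(f"unknown score-track dialect {dialect!r}")


def write_score_track(track: ScoreTrack, path, dialect: str = "fixed_step") -> None:
    with open(path, "w") as fh:
        if dialect == "fixed_step":
            fh.write(f"fixedStep chrom={track.chrom or 'track'} "
                     f"start={track.start} step=1\n")
            for v in track.values:
                fh.write(f"{v:.6g}\n")
        elif dialect == "two_column":
            for pos, v in zip(track.positions(), track.values):
                fh.write(f"{pos}\t{v:.6g}\n")
        else:
            raise ValueError(f"unknown score-track dialect {dialect!r}")


# ------------------------------------------------------------ BED calls

def write_calls_bed(callset: CallSet, path) -> None:
    """BED6: start = dyad - 73, end = dyad + 74, scores scaled to 0-1000.

    Calls whose 147-bp core would start before position 0 are dropped
    with a warning (never clipped).
    """
    kept = [c for c in callset if c.start >= 0]
    dropped = len(callset) - len(kept)
    if dropped:
        logger.warning("dropped %d call(s) whose core starts before position 0", dropped)
    with open(path, "w") as fh:
        fh.write("# BED6 nucleosome calls: start=dyad-73, end=dyad+74\n")
        if not kept:
            return
        scores = np.array([c.score for c in kept])
        lo, hi = scores.min(), scores.max()
        if hi > lo:
            scaled = np.round((scores - lo) / (hi - lo) * 1000).astype(int)
        else:
            scaled = np.full(len(kept), 1000, dtype=int)
        for i, (call, s) in enumerate(zip(kept, scaled), 1):
            fh.write(f"{call.chrom}\t{call.start}\t{call.end}\tnuc{i}\t{s}\t.\n")


def read_calls_bed(path) -> CallSet:
    """Re-read BED6 calls; dyad = start + 73 (spans must be 147 bp)."""
    calls = []
    chrom = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: need >= 3 BED columns")
            start, end = int(fields[1]), int(fields[2])
            if end - start != 147:
                raise FormatError(f"line {lineno}: span {end - start} != 147")
            chrom = fields[0]
            score = float(fields[4]) if len(fields) > 4 else 0.0
            calls.append(NucleosomeCall(chrom, start + 73, score))
    return CallSet(chrom, calls)


# ----------------------------------------------------------- JASPAR PFM

def read_jaspar_pfm(path) -> list[PFMRecord]:
    """JASPAR-style PFM text: ">ID NAME" then 4 rows A, C, G, T.

    Row values may be bracketed ("A [ 8 0 ]") or bare; leading base
    letters are optional but, when present, must come in A, C, G, T
    order.  (Parsed here rather than via Bio.motifs to accept both the
    bracketed and bare dialects uniformly.)
    """
    records = []
    name = None
    rows: list[list[float]] = []

    def flush(lineno):
        nonlocal name, rows
        if name is None:
            return
        if len(rows) != 4:
            raise FormatError(f"record {name!r}: expected 4 rows, got {len(rows)}")
        lens = {len(r) for r in rows}
        if len(lens) != 1:
            raise FormatError(f"record {name!r}: ragged matrix columns {sorted(lens)}")
        records.append(PFMRecord(name, np.array(rows)))
        name, rows = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                name = line[1:].split()[0] if line[1:].strip() else f"motif{len(records) + 1}"
                continue
            if name is None:
                raise FormatError(f"line {lineno}: matrix row before any '>' header")
            row = line
            expected = "ACGT"[len(rows)] if len(rows) < 4 else None
            m = re.match(r"^([ACGTacgt])[\s:|]", row)
            if m:
                if expected and m.group(1).upper() != expected:
                    raise FormatError(
                        f"line {lineno}: row order must be A,C,G,T "
                        f"(saw {m.group(1).upper()}, expected {expected})"
                    )
                row = row[1:]
            row = row.replace("[", " ").replace("]", " ")
            try:
                rows.append([float(x) for x in row.split()])
            except ValueError:
                raise FormatError(f"line {lineno}: malformed matrix row {line!r}") from None
    flush(-1)
    return records


# -------------------------------------------------- roll/tilt & pattern

def write_pattern(pattern: CurvaturePattern, path) -> None:
    """Two-column TSV (offset, value) with the dyad index in the header."""
    with open(path, "w") as fh:
        fh.write(f"# curvature pattern, dyad_index={pattern.dyad_index}\n")
        for i, v in enumerate(pattern.values):
            fh.write(f"{i}\t{v:.10g}\n")


def read_pattern(path) -> CurvaturePattern:
    dyad_index = None
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if line.startswith("#"):
                m = re.search(r"dyad_index=(\d+)", line)
                if m:
                    dyad_index = int(m.group(1))
                continue
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"line {lineno}: expected offset<TAB>value")
            values.append(float(fields[1]))
    if dyad_index is None:
        raise FormatError("pattern file lacks a dyad_index header")
    return CurvaturePattern(np.asarray(values), dyad_index)
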