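"""DNA helix curvature from dinucleotide roll/tilt wedges.

The curvature vector over a window of W dinucleotide steps is

    C = (nu0 / W) * sum_{j=0}^{W-1} (rho_j - i * tau_j) * exp(2*pi*i*j / nu0)

where rho/tau are the roll and tilt angles (degrees) of step j, nu0 the
average helical periodicity in bp (10.4 by default) and i the imaginary
unit.  The phase factor advances by one full turn per nu0 steps, so roll
wedges recurring in helical phase add coherently; |C| measures the local
deviation of the helix axis from straight B-DNA.

Sliding this window along a sequence gives the *curvature curve*; cross-
correlating the curve with a canonical nucleosomal *curvature pattern*
(bent ~50-bp ends, straighter ~47-bp middle) gives the *curvature
profile*, whose peaks mark predicted nucleosome dyads.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import GenomeSequence, ScoreTrack

_STEPS = ["".join(p) for p in itertools.product("ACGT", repeat=2)]

DEFAULT_NU0 = 10.4
DEFAULT_WINDOW = 10


class RollTiltTable:
    """Roll/tilt angles (degrees) for the 16 dinucleotide steps."""

    def __init__(self, angles: dict[str, tuple[float, float]]):
        missing = set(_STEPS) - set(angles)
        extra = set(angles) - set(_STEPS)
        if missing or extra:
            raise ValueError(
                f"table must cover exactly the 16 dinucleotide steps "
                f"(missing {sorted(missing)}, unexpected {sorted(extra)})"
            )
        self.angles = {s: (float(r), float(t)) for s, (r, t) in angles.items()}
        for s, (r, t) in self.angles.items():
            if not (np.isfinite(r) and np.isfinite(t)):
                raise ValueError(f"non-finite angle for step {s}")

    def __getitem__(self, step: str) -> tuple[float, float]:
        try:
            return self.angles[step]
        except KeyError:
            raise KeyError(f"unknown dinucleotide step {step!r}") from None

    def roll(self, step: str) -> float:
        return self[step][0]

    def tilt(self, step: str) -> float:
        return self[step][1]

    def complex_wedges(self) -> np.ndarray:
        """rho - i*tau for step codes 0..15 (code = 4*first + second)."""
        w = np.empty(16, dtype=complex)
        for s in _STEPS:
            code = 4 * "ACGT".index(s[0]) + "ACGT".index(s[1])
            r, t = self.angles[s]
            w[code] = r - 1j * t
        return w

    def scaled(self, k: float) -> "RollTiltTable":
        return RollTiltTable({s: (k * r, k * t) for s, (r, t) in self.angles.items()})

    @classmethod
    def from_tsv(cls, path) -> "RollTiltTable":
        angles = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.lower().startswith("step"):
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise ValueError(f"roll/tilt table row needs 3 columns: {line!r}")
                angles[fields[0].upper()] = (float(fields[1]), float(fields[2]))
        return cls(angles)


def default_table() -> RollTiltTable:
    """The bundled dinucleotide wedge-model roll/tilt angles."""
    ref = resources.files("nucleocurve.data") / "dinucleotide_wedge.tsv"
    with resources.as_file(ref) as path:
        return RollTiltTable.from_tsv(path)


@dataclass(frozen=True)
class CurvatureParams:
    """Curvature-sum settings.

    nu0
        Helical periodicity in bp per turn (default 10.4).
    window
        Number of dinucleotide steps summed per curvature value
        (default 10, about one helical turn).
    exp_convention
        ``"helical"`` uses the phase exp(2*pi*i*j/nu0) (one turn per nu0
        steps); ``"literal"`` uses exp(2*pi*i*j*nu0) for comparison.
    """

    nu0: float = DEFAULT_NU0
    window: int = DEFAULT_WINDOW
    exp_convention: str = "helical"

    def __post_init__(self):
        if self.nu0 <= 0:
            raise ValueError("nu0 must be positive")
        if self.window < 2:
            raise ValueError("window must be >= 2 steps")
        if self.exp_convention not in ("helical", "literal"):
            raise ValueError("exp_convention must be 'helical' or 'literal'")

    def phase(self) -> np.ndarray:
        j = np.arange(self.window)
        if self.exp_convention == "helical":
            return np.exp(2j * np.pi * j / self.nu0)
        return np.exp(2j * np.pi * j * self.nu0)


DEFAULT_PARAMS = CurvatureParams()


def curvature_at(steps, table: RollTiltTable, params: CurvatureParams = DEFAULT_PARAMS) -> float:
    """Curvature modulus |C| for one window of dinucleotide steps."""
    steps = list(steps)
    if len(steps) != params.window:
        raise ValueError(f"expected {params.window} steps, got {len(steps)}")
    w = np.array([complex(table[s][0], -table[s][1]) for s in steps])
    c = params.nu0 / params.window * np.sum(w * params.phase())
    return float(abs(c))


@dataclass
class CurvatureCurve(ScoreTrack):
    """Curvature modulus per position; masked where the window hit an N."""


def curvature_curve(
    seq: GenomeSequence,
    table: RollTiltTable | None = None,
    params: CurvatureParams = DEFAULT_PARAMS,
) -> CurvatureCurve:
    """Slide the curvature window over a sequence.

    The value of each window is assigned to the window's center base
    (start + window // 2); the track has ``len(seq) - window`` values.
    Windows containing any non-ACGT base are masked and set to 0.
    """
    if table is None:
        table = default_table()
    W = params.window
    if len(seq) < W + 1:
        raise ValueError(f"sequence length {len(seq)} < window + 1 = {W + 1}")
    codes = seq.encode()
    valid = codes < 4
    step_valid = valid[:-1] & valid[1:]
    step_code = np.where(step_valid, 4 * codes[:-1] + codes[1:], 0)
    wedges = table.complex_wedges()[step_code]
    wedges[~step_valid] = 0.0

    phase = params.phase()
    win = sliding_window_view(wedges, W)
    moduli = np.abs(win @ phase) * (params.nu0 / W)
    mask = ~sliding_window_view(step_valid, W).all(axis=1)
    moduli[mask] = 0.0
    return CurvatureCurve(seq.chrom, W // 2, moduli, mask)


@dataclass
class CurvaturePattern:
    """Canonical 1-D nucleosomal curvature template.

    ``dyad_index`` is the offset of the nucleosome dyad within the
    template.  Patterns are stored zero-mean with unit L2 norm so that
    the matched filter ignores baseline curvature.
    """

    values: np.ndarray
    dyad_index: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pattern values must be finite")
        if not 0 <= self.dyad_index < len(self.values):
            raise ValueError("dyad_index outside the template")

    def __len__(self) -> int:
        return len(self.values)


def _normalize(values: np.ndarray) -> np.ndarray:
    v = values - values.mean()
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("pattern is constant; cannot normalize")
    return v / norm


def _moving_average(values: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(values, kernel, mode="same")


def build_pattern(
    core_seqs: list[GenomeSequence],
    table: RollTiltTable | None = None,
    params: CurvatureParams = DEFAULT_PARAMS,
    smooth: int = 0,
) -> CurvaturePattern:
    """Average the curvature curves of aligned core-DNA sequences.

    All sequences must share one length (146 or 147 bp for crystal
    cores, but any aligned set works).  The positionwise mean curve is
    zero-meaned and L2-normalized; the dyad sits at the template center.
    ``smooth`` > 1 applies a moving average of that width first.
    """
    if not core_seqs:
        raise ValueError("need at least one core sequence")
    lengths = {len(s) for s in core_seqs}
    if len(lengths) != 1:
        raise ValueError(f"core sequences have mixed lengths: {sorted(lengths)}")
    curves = [curvature_curve(s, table, params).values for s in core_seqs]
    mean_curve = np.mean(curves, axis=0)
    if smooth > 1:
        mean_curve = _moving_average(mean_curve, smooth)
    return CurvaturePattern(_normalize(mean_curve), len(mean_curve) // 2)


def idealized_pattern(
    params: CurvatureParams = DEFAULT_PARAMS,
    end_len: int = 50,
    mid_len: int = 47,
    high: float = 1.0,
    low: float = 0.2,
    ramp: int = 5,
    smooth: int = 0,
) -> CurvaturePattern:
    """Piecewise template: strongly bent ends, straighter middle.

    Core DNA bends most over roughly 50 bp at each end of the wrap and
    least over the ~47-bp middle; this builds that shape directly (high
    plateaus at the ends, a low middle, cosine ramps of ``ramp`` bp),
    mirror-symmetric about the dyad, then normalizes as build_pattern.
    """
    L = 2 * end_len + mid_len
    if not 130 <= L <= 160:
        raise ValueError(f"template length {L} far from the 147-bp core")
    raw = np.empty(L)
    for i in range(L):
        d = min(i, L - 1 - i)  # distance from the nearer template end
        if d < end_len:
            raw[i] = high
        elif d < end_len + ramp:
            t = (d - end_len + 1) / (ramp + 1)
            raw[i] = high + (low - high) * (1 - np.cos(np.pi * t)) / 2
        else:
            raw[i] = low
    if smooth > 1:
        raw = _moving_average(raw, smooth)
    return CurvaturePattern(_normalize(raw), L // 2)


def curvature_profile(curve: ScoreTrack, pattern: CurvaturePattern) -> ScoreTrack:
    """Matched-filter the curvature curve with the pattern.

    Each placement's score is the dot product of the pattern with the
    aligned stretch of the curve (masked curve positions contribute 0);
    the score lands on the genomic position aligned with the pattern's
    dyad.  Peaks mark predicted dyads.
    """
    L = len(pattern)
    if len(curve) < L:
        raise ValueError(f"curve length {len(curve)} < pattern length {L}")
    vals = curve.values
    if curve.mask is not None:
        vals = np.where(curve.mask, 0.0, vals)
    scores = sliding_window_view(vals, L) @ pattern.values
    return ScoreTrack(curve.chrom, curve.start + pattern.dyad_index, scores)
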