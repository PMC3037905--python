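# Methods

## Curvature model

The curvature of the helix axis is computed from per-dinucleotide roll
(ρ) and tilt (τ) wedge angles. For a window of W consecutive steps,

C = (ν₀ / W) · Σⱼ₌₀^{W−1} (ρⱼ − i·τⱼ) · exp(2πi·j / ν₀)

and the reported value is |C| in degrees per averaged step. The phase
factor advances by one full turn every ν₀ steps: a roll wedge recurring
in helical phase (period ≈ ν₀) therefore adds coherently and produces
macroscopic bending, while wedges at random phases largely cancel. The
exponent convention matters: `exp_convention="helical"` (the default)
uses j/ν₀; the `"literal"` option uses j·ν₀, which destroys the helical
interpretation and exists only for comparison.

Parameters:

- **ν₀ = 10.4 bp/turn** — the average double-helix periodicity.
- **W = 10 steps** — about one helical turn; the window an individual
  curvature value integrates. Configurable; larger windows average
  phase coherence over several turns.
- **Roll/tilt table** — `data/dinucleotide_wedge.tsv`, a published
  strand-symmetric dinucleotide wedge-model set (reverse-complement
  steps share roll and negate tilt; self-complementary steps have
  tilt 0). Any user table with the same 16-row layout can be
  substituted. The package's unit tests deliberately use explicitly
  constructed tables so they check the algebra, not these numbers.

Windows containing a non-ACGT base are masked to 0 rather than
interpolated: absence of sequence evidence must not fabricate signal.
Masked positions carry zero weight through the matched filter.

## Curvature pattern

The canonical nucleosomal template has high plateaus over ~50 bp at
each end of the wrap and a lower ~47-bp middle, mirror-symmetric about
the dyad. Two constructors exist:

- `build_pattern(core_seqs)` — positionwise mean of the curvature
  curves of aligned core sequences (146/147 bp crystal cores, or any
  aligned set).
- `idealized_pattern()` — the piecewise high/low/high template (high
  1.0, low 0.2, 5-bp cosine ramps), for use when no aligned core set
  is at hand.

Both are zero-meaned and scaled to unit L2 norm, so the matched filter
is insensitive to baseline curvature and its output is comparable
across inputs. An optional moving-average smoothing (`smooth`, default
off) exists for noisy user-supplied core sets.

The profile value at a placement is the dot product of the pattern with
the aligned curve stretch, assigned to the genomic position under the
pattern's dyad index.

## Dyad detection

Dyads are called on a wavelet spectrum of the profile. Mexican-hat CWT
coefficients are computed at scales 25–100 bp (step 5) — bracketing the
half-width of a nucleosome-sized bump — and combined per position by
**averaging across the scale band** (`aggregation="mean"`). The mean
over scales is a single linear band-pass filter: it preserves
linearity (spectrum of k·track = k·spectrum), is exactly invariant to
constant offsets (the track is centred first; the wavelet has zero
mean), and suppresses the matched filter's own autocorrelation side
lobes, which sit ±~98 bp from each true peak where the template's end
plateaus re-align. A plain per-position maximum over scales
(`aggregation="max"`) is retained as an option, but it is dominated by
the smallest scales, which respond to exactly those narrow side lobes:
under the default parameters it produces 12–30% spurious calls on
planted arrays at ~200-bp spacing, versus 0% for the band mean.

Peak acceptance: local maxima of the spectrum (leftmost point of a
plateau wins, so ties are deterministic) that exceed the
`threshold_quantile` (default 0.70) of the spectrum *and* are positive
— a nucleosome bump always has positive wavelet response, so negative
"peaks" are never dyads even on nearly empty tracks. Candidates are
accepted greedily in descending spectrum order subject to
`min_distance` (default 100 bp, below the 147-bp core because
overlapping predicted/reference calls at deviations up to 60 bp are
meaningful). Calls whose 147-bp core would leave the track are dropped.
The threshold is applied to the spectrum, not the profile: the spectrum
is the quantity in which peak height is scale-robust.

## Evaluation statistics

- **Matching ratio** — fraction of reference dyads with ≥1 predicted
  dyad within ±deviation; swept over 1–60 bp. "Any-within" matching is
  the default (one prediction may serve several references); a greedy
  one-to-one mode exists for sensitivity analysis.
- **Overlap ratio** — [2(73−d)+d]/147, implemented literally as
  published. The geometric overlap of two 147-bp intervals offset by d
  would be (147−d)/147; the printed form is kept deliberately.
- **Hexamer occupancy** — forward-strand hexamer occurrences (every
  offset, N-windows skipped) are "occupied" iff the 6-bp span lies
  entirely inside some call's 147-bp core. Full containment is used
  because it is unambiguous and symmetric; reverse-complement
  collapsing is off by default (a `collapse_rc` flag pools each
  hexamer with its reverse complement).

## Site-centered analyses

Anchored profiles average a track across sites as a function of offset,
reversing windows of minus-strand sites. Per-site scaling is either
raw or z-score; z-scoring is the default in the CLI profile command so
tracks in arbitrary units are comparable. Sites truncated by
chromosome ends contribute only their covered offsets (the per-offset
`n_sites` records how many), rather than being discarded.

TSS classification runs k-means (k = 2, Euclidean, 20 seeded restarts)
on the raw per-site signal vectors over [−150, +50]; only sites with
full window coverage participate. The cluster whose center has the
greater mean is class I (occupied), the other class II
(nucleosome-free) — naming follows occupancy ordering, not cluster
index, so labels are stable across seeds. Raw (unscaled) vectors are
used because the within-window *level* is exactly what separates
occupied from free TSSs.

Sequence-composition profiles: WW = {AA, AT, TA, TT},
SS = {CC, CG, GC, GG}; dinucleotides touching N are dropped from that
offset's denominator. Poly(dA:dT) means a homopolymer run of A, or of
T, of length ≥ `min_run` (default 4); mixed A/T runs do not count, and
runs truncated by the window edge are measured as seen.

## PWM scanning

PFMs become base-2 log-odds matrices with pseudocount 0.5 and a uniform
background (both configurable). Scans score every placement on both
strands and keep the larger; placements containing N are masked. For
the cross-TF average, each (TF, promoter) track is min–max normalized
to [0, 1] before averaging — without this, TFs with high-information
motifs would dominate the mean purely through their log-odds range. A
constant track (no discrimination anywhere) contributes a flat 0.5
with a warning. Offsets are placement starts relative to the declared
TSS position.

## Synthetic fixtures

All generators are pure functions of (parameters, seed); substreams
derive from (seed, generator id) so adding a generator never perturbs
existing fixtures.

- `plant_signal_pattern` — zero baseline, pattern copies (peak
  amplitude 1) at given dyads, i.i.d. Gaussian noise; SNR = 1/noise_sd.
  Exercises the matched filter and detector with known truth.
- `plant_sequence_nucleosomes` — random background (GC fraction 0.5)
  with 147-bp cores at regular dyads (default spacing 190 bp, the
  human internucleosome repeat). Core ends carry 5-bp A/T tracts on a
  10.3-bp phase grid; the middle carries single WW dinucleotides on an
  11.1-bp grid. Tracts, not lone dinucleotides, are required at the
  ends: an isolated WW step in G/C context largely cancels against its
  flanking CA/GA wedges (measured cassette curvature fell *below*
  background when single dinucleotides were planted), whereas a 5-bp
  tract spans half a turn and bends coherently. With tracts, cassette
  ends measure ~31°, middles ~12°, background ~15° with the bundled
  table — the canonical high/low/high core shape.
- `tss_class_fixture` — half the sites get a +1 occupancy bump over
  [−150, +50], half a −1 trough, plus Gaussian noise of sd 1/SNR
  (default SNR 3), interleaved along one track.

What the fixtures do *not* emulate: remodeller activity, statistical
positioning against boundaries, linker-length variability, base
composition beyond GC fraction, and experimental coverage noise.
Passing recovery tests on them shows the pipeline detects the curvature
signature it models when that signature is present — not that real
chromatin is this clean. At the planted 190-bp spacing the inter-core
linker flanked by two bent core ends partially mimics the core pattern
itself; a few percent of calls land on linker centers, which is the
main recovery loss in the sequence-level test.

## Problem sizes and numerical choices

The recovery analyses run at 100 kb / 500 dyads (signal level) and
50 kb / ~260 dyads (sequence level), sizes at which the measured
statistics are stable across seeds (recovery varies by ~±3% over ten
seeds) while the whole suite stays fast. Planted dyads sit on a
jittered grid (±20 bp) rather than an exact lattice so results do not
depend on a resonance between spacing and detector parameters.
Spacing statistics are reported over the full call set — the repeat
length a practitioner would measure — with 10-bp histogram bins.

Degenerate inputs: constant patterns cannot be normalized (error);
all-identical TSS vectors yield a single class with a warning; empty
prediction sets give matching ratio 0; calls whose core would start
before position 0 are dropped (never clipped) on BED export with a
warning.

## Known limitations

- The curvature model is first-order wedge superposition; it ignores
  sequence-dependent flexibility and electrostatics.
- Only the curvature modulus is used; bend direction (phase) is
  discarded downstream, so left- and right-handed writhe are
  indistinguishable to the profile.
- Reference score tracks in the two-column dialect are zero-filled at
  unlisted positions; whether a listed position indexes a nucleosome
  start or midpoint is input-dependent and left to the user
  ("position of the score").
- The matched filter's resolution is limited by the 147-bp template:
  closely spaced alternative positionings blur into single peaks.
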