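# Methods

This note documents the models behind each module, the defaults that
matter, and the numerical and design choices made where the assay leaves
the computational side open.

## Codebook construction

Codewords are binary vectors of length `n_bits` with exactly `w_on`
on-bits (one bit per unique readout probe; a circularized probe set
carries four readout sites, so `w_on = 4`).  Between equal-weight words
the Hamming distance is always even and equals `2·(w_on − overlap)`, so
the minimum-distance-4 (MHD4) constraint is equivalent to bounding the
on-bit overlap of any two codewords by `w_on − 2`.  MHD4 yields
single-error correction (a vector at distance 1 from a codeword is at
distance ≥ 3 from every other) and double-error detection.

The search is a lexicographic greedy pass over all C(n_bits, w_on)
weight-`w_on` words (accept a word iff it keeps the pairwise constraint),
followed by seeded randomized augmentation: drop a random tenth of the
current code, greedily refill in a random candidate order, keep the
result if no smaller, repeat for `restarts` rounds (default 20).  The
greedy baseline alone reaches 378 codewords at (24, 4, 4); augmentation
typically grows this to ~410–430.  For n = 4…8 the search attains the
exhaustive optimum (1, 1, 3, 7, 14), which the test suite verifies
against an independent exact maximum-clique oracle.  The generator is a
pure function of its arguments; ties in augmentation are broken only by
the seeded RNG.

Conventions fixed for reproducibility (the assay does not constrain
them):

- Negative-control count: `ceil(fraction · code size)` codewords, sampled
  with the seeded RNG; targets are then assigned to a seeded sample of
  the remainder, one codeword per target.
- 3P/5P split: the two lowest on-bit indices become the 3P (acceptor)
  readout sites, the two highest the 5P (donor) sites.
- Bit-to-slot map: bit *b* is imaged in coding cycle `b // n_channels`,
  channel `b % n_channels`; with landmark cycles enabled the full run is
  landmark, 6 coding cycles, landmark (8 cycles for 24 bits / 4
  channels).

## Synthetic imaging model

`simulate_field` draws per-target RCP counts Poisson(density × area),
positions uniform, and amplitudes/radii log-normal (defaults: median
amplitude 1000 counts, geometric log-sd 0.25; median radius 0.4 µm,
log-sd 0.15 — chosen as plausible camera-count and RCP-size scales; no
measured distributions exist for them).  Two optional constraints serve
fixtures that require every RCP to resolve into its own spot cluster:
`min_separation_um` (sequential dart-throwing with a hard minimum
pairwise distance) and `edge_margin_um` (keeps RCPs off the frame border,
where any detector loses part of the PSF).  Defaults for both are 0,
i.e. pure Poisson/uniform.

Rendering: each RCP is a 2-D Gaussian with peak = amplitude and sigma
`sqrt(psf_sigma² + radius²) / pixel_size` (PSF convolved with the
physical RCP extent), windowed at ±6σ.  Default optics: 0.5 µm pixels,
0.6 µm PSF sigma, background 100 counts, additive Gaussian read noise
sd 2.  A single z-plane is rendered; decoding of the real instrument's
z-stacks is per-slice anyway, so multi-z is modeled as independent
planes, not a 3-D PSF.

Error processes:

- Per-bit dropout (on-bit fails to light) and spurious signal (off-bit
  lights), independent per RCP and bit.  True per-bit error rates of the
  assay are unpublished; the defaults are 0 and the rates are explicit
  knobs for sensitivity studies.
- Stage drift: cycle *c*'s frame is translated by `c · drift_per_cycle_px`
  (linear motion; the real correction is endpoint-to-endpoint, which a
  linear model matches exactly).
- Decoy thinning: an unligatable 3P decoy at fraction *f* of the probe
  pool removes each RCP of the target independently with probability *f*
  — the linear-suppression behaviour the decoy rheostat is designed for.
- ddNTP chain termination: radius and amplitude scale by
  `1 / (1 + c·X)` for dNTP:ddNTP ratio 1:X (monotone decreasing, 1 at
  X = 0; only monotonicity is empirically established, so the map and
  its coefficient are configuration).

The renderer returns the realized per-RCP bit outcomes, which oracle
tests compare against the decoded output.

## Detection, registration, assembly

Spot detection computes the scale-normalized negative
Laplacian-of-Gaussian response at the PSF sigma, keeps local maxima above
`median + k·MAD` of the response map (k default 8 — on pure-noise frames
this keeps the false-positive rate below one call per 512² image), and
refines positions by a separable quadratic fit over the 3×3
neighbourhood.  A numerical guard additionally floors the threshold at
10⁻⁴ of the response range so that the ~10⁻⁸-relative ripples left by
window-truncated rendering on noiseless frames are never called; any
genuine spot is orders of magnitude above it.  Border pixels are
excluded (no full 3×3 neighbourhood).

Drift is estimated from the two landmark cycles: mutual nearest
neighbours within 10 px are matched and the endpoint offset is their
median displacement — robust to ~10 % spurious or missing landmarks —
then interpolated linearly across cycles (zero at the first landmark
cycle).  At least 3 mutual matches are required.

Assembly single-linkage clusters all drift-corrected spots at the
colocalization radius (default 1.5 px ≈ one PSF sigma; the instrument's
value is unpublished) via a KD-tree pair query plus connected
components.  Each cluster becomes one record: bit *b* is set iff the
cluster holds a spot in *b*'s (cycle, channel) slot; landmark spots
anchor position only; the consensus position is the intensity-weighted
mean.  Every spot belongs to exactly one record.

## Decoding and MisID

A record decodes to the unique codeword within Hamming distance
`max_correctable` (default 1, the radius MHD4 guarantees); ties and
larger distances are left unassigned — with 4-on codewords an all-dropout
record (weight ≤ 2) can never be mis-assigned.  Under dropout probability
p with no spurious signal, the decodable fraction is exactly
`(1−p)⁴ + 4p(1−p)³` (0.9477 at p = 0.1), which the end-to-end tests
verify.

MisID convention (the threshold is standard, the formula is this
package's explicit choice): global MisID% is the per-codeword decode rate
of negative-control codewords relative to that of assigned codewords,
`100 · (neg_decodes / n_neg_codewords) / (assigned_decodes /
n_assigned_codewords)`; per-gene MisID% compares the mean
negative-codeword count to the gene's count, and genes above the
threshold (default 25 %) are flagged for removal.  Both views are
reported; flagging is the only false-positive filter — there is no
manual curation step.

Low-plex colocalization scores each configured channel pair by
one-to-one mutual-nearest-neighbour matching within the colocalization
radius (closest pairs consumed first), normalized per cell (DAPI puncta
count).  Under independent uniform channels the expected chance-pair
count is ≈ λ₁λ₂πr²A, which the tests check by Monte Carlo.

## LISH-seq counting and FPNM

References are built per probe set: one perfect junction (3P
target-recognition sequence + 5P sequence) and one mismatch junction per
ordered cross pairing of distinct sets.  Identical junctions from
different pairings raise a collision error rather than merging silently.
Counting is exact windowed matching at a configurable read offset — the
references are short known products, so an aligner adds nothing and
exactness keeps the operation deterministic; one substitution in the
window makes a read unmapped.  Reverse-complement matching is not
attempted (read orientation is fixed by the library's primers).

FM/FPNM: `scaling = total mapped reads / 1e6`; `FM = count / scaling`
(FM sums to exactly 10⁶ over all references); `FPNM(gene) = FM(gene's
perfect references) / n_probes(gene)`.  FPNM is invariant under read
duplication.

## Spatial statistics

Binning uses square bins of side `bin_size_um` (the standard operating
point "50 µm grids" is interpreted as 50 µm × 50 µm squares); transcripts
on the maximum edge fall into the last bin, and counts are conserved.
The bins × genes matrix exports to MatrixMarket + TSV for external
clustering tools; clustering itself is out of scope.

Near-neighbour proximity: for each reference transcript, the distance to
the nearest transcript of gene *g* (excluding the reference point itself
when *g* is the reference gene — self-matches would trivially saturate
the probability); the reported probability is the unconditional fraction
of reference transcripts with that distance ≤ radius (default 60 µm).
The KD-tree fast path is tested for exact equality with an O(nm)
brute-force oracle and for monotonicity in the radius.

Concordance is the Pearson correlation over shared genes, optionally
after log10(x+1) (the appropriate scale depends on the platforms being
compared, so it is a flag, not a default).

## LISH-QC quantification

`fit_standard_curve` least-squares fits Cq = intercept + slope ·
log10(copies/µL) to a dilution series (the synthetic generator defaults
to the 8-point decade series, 10¹…10⁸ copies/µL); efficiency is
10^(−1/slope) − 1, so a perfect doubling per cycle (slope −3.3219) gives
1.0.  `quantify` inverts the curve, multiplies by the elution volume
(explicit parameter, default 100 µL — the collected reaction supernatant
volume), and divides by the tissue area for molecules/mm².  Cq values
outside the calibrated range trigger an extrapolation warning.
Qualification cutpoints are configuration: the pass/caution/fail scale
is an instrument- and tissue-calibrated choice, not a constant of the
assay.

## Fixture sizes and limitations

The standard imaging fixture is 20 targets at 625 RCPs/mm² over a
400 × 400 µm field (≈ 2000 RCPs, 800² px frames, 8 cycles), with 4 µm
minimum RCP separation and a 3 µm edge margin so the exact-recovery
invariants are well-posed; statistical checks pool 3 render seeds or
50–200 lightweight simulation seeds.

The simulator emulates point-source optics with flat background and
white noise.  It does not model tissue autofluorescence texture,
illumination inhomogeneity, chromatic shifts between channels, 3-D PSFs,
RCP overcrowding/merging, or cell morphology — so passing tests
demonstrate the correctness of the coding, detection, registration,
decoding and normalization machinery under controlled error processes,
not performance on real tissue images.  Real-specimen quantities (spots
per cell, inter-platform correlation coefficients, per-gene tissue
densities) depend on biology and instrument properties the simulator
does not claim to reproduce.
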