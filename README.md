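# lishlnr

A simulation, decoding and quantification toolkit for **LISH-LnR**
(Ligation In Situ Hybridization – Lock'n'Roll) spatial transcriptomics,
together with its two companion readouts: sequencing-based ligation-product
counting (LISH-seq) and qPCR-based absolute quantification (LISH-QC).

In a LISH-LnR assay, a pair of short DNA probes (a 3P acceptor and a 5P
donor) anneals contiguously on a target mRNA, is ligated and circularized,
and is amplified in place by rolling circle amplification.  Each rolling
circle product (RCP) carries many repeats of four readout-probe binding
sites, so over successive hybridize–image–strip cycles an RCP lights up in
exactly the (cycle, channel) slots of its target's binary codeword.  This
package implements the computational side of that assay end to end, on
synthetic data it generates itself:

- **`codebook`** — constant-weight error-correcting codebooks: every
  codeword has exactly *w* = 4 on-bits and any two codewords differ in at
  least 4 bits (MHD4), so any single dropped or spurious readout signal is
  correctable and double errors are detectable.  For *n* = 24 bits the
  generator finds ≥ 378 codewords.  Includes negative-control reservation,
  target assignment, 3P/5P readout-site layout and the cycle/channel
  imaging schedule (6 coding cycles of 4 channels, landmark cycles first
  and last).
- **`rcpsim`** — synthetic ground-truth RCP fields and rendered
  multi-cycle multi-channel TIFF stacks with controlled per-bit dropout
  and spurious-signal rates, linear stage drift, decoy-probe thinning of
  chosen targets and ddNTP chain-termination shrinking of RCP size (the
  assay's "molecular rheostats"), plus synthetic FASTQ and qPCR inputs
  for the companion assays.
- **`imgproc`** — Laplacian-of-Gaussian spot detection with a robust
  median + k·MAD threshold and subpixel refinement, landmark-based drift
  estimation, and single-linkage colocalization that assembles per-cycle
  spots into one observed bit vector per RCP.
- **`decode`** — nearest-codeword decoding with single-error correction,
  misidentification (MisID) estimation from negative-control codewords,
  and mutual-nearest-neighbour colocalization scoring for low-plex
  (standard microscope) experiments.
- **`seqcount`** — perfect-match / cross-pair-mismatch ligation-product
  references, exact read counting from FASTQ, and FM/FPNM normalization
  (fragments per million, per probe).
- **`spatialstats`** — square-grid binning (MatrixMarket export for
  external clustering), per-gene densities, near-neighbour proximity
  probabilities, and Pearson concordance between platforms.
- **`lishqc`** — qPCR standard-curve fitting (slope, efficiency
  10^(−1/slope) − 1), conversion of sample Cq values to molecules per
  mm² of tissue, and configurable pass/caution/fail specimen
  qualification.

## Worked example

Generate the full-scale codebook:

```text
$ lnr codebook --bits 24 --weight 4 --mhd 4 --seed 1 -o book24.csv
wrote 420 codewords (42 negative controls) to book24.csv
```

420 is the size of the (24, 4, 4) constant-weight code found by the
lexicographic-greedy-plus-augmentation search — comfortably above the 378
codewords needed for a 378-plex panel — and 42 = ceil(10 % · 420) codewords
are reserved as negative controls for MisID estimation.

Run the demo pipeline (codebook → simulate → detect → assemble → decode →
spatial summaries) on a 16-bit, 8-target synthetic field:

```text
$ lnr run --seed 7 -o demo/
{
  "n_codewords": 140,
  "n_rcps_truth": 118,
  "n_records": 118,
  "n_assigned": 118,
  "n_unassigned": 0
}
```

All 118 simulated RCPs are detected, assembled into bit-vector records and
decoded to the correct gene (the run is noiseless and drift-free, so
recovery is exact; `demo/transcripts.csv` holds positions, genes and
Hamming distances).  The MisID report (`demo/misid.txt`) shows what the
negative controls see:

```text
global MisID: 0.00%
negative decodes: 0 over 14 negative codewords
assigned decodes: 118 over 8 assigned codewords
genes above 25% per-gene MisID: none
```

The same stages are available as library functions
(`lishlnr.codebook.generate_codebook`, `lishlnr.rcpsim.render_stack`,
`lishlnr.imgproc.detect_stack`, `lishlnr.decode.decode_table`, …) and as
individual subcommands (`lnr simulate`, `lnr detect`, `lnr assemble`,
`lnr decode`, `lnr seqcount`, `lnr spatial`, `lnr qc`).

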