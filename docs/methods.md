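# Methods

## System and scope

`prophagedyn` models a temperate, Mu-like transposable prophage resident in a
bacterial chromosome, with three measurable behaviours: hypermutation of a
tail-fiber variable repeat (VR) by a diversity-generating retroelement (DGR),
copy-in-place (replicative) transposition creating new phage–host junctions,
and left-initiated headful DNA packaging that co-packages host DNA at both
ends and may terminate prematurely. The package implements the sequencing
analyses for all three, and a simulator that generates reads from the same
generative models so every estimator can be tested against planted truth.
Wet-lab quantities (droplet PCR, microscopy, expression analysis) and de novo
element discovery are out of scope.

## Synthetic genome and shared reference

`make_genome` draws a uniform-random chromosome (default 50 kb) containing a
prophage interval (default [5000, 45000), i.e. a 40 kb phage, close to the
~43 kb genomes typical of this phage group). The VR (default 120 nt) is
written into the prophage from the TR sequence, so at simulation start the VR
equals the TR and "non-reference" coincides with "DGR-mutated". The default
TR is a synthetic 120-nt, adenine-rich (32.5% A) sequence, giving 39 targeted
and 81 non-targeted positions. Amplicon primers (the 15-nt conserved pair
F `ATATCCACTGCCTCC` / R `GCCAGACGAGAACCG`) are placed immediately flanking
the VR: the forward primer ends at the VR start and the reverse-complemented
reverse primer begins at the VR end. Random 15-mers are expected ~5e-5 times
in a 50 kb genome, so spurious primer hits are negligible; reads with
multiple hits are dropped regardless.

All randomness derives from one master seed; each stage (genome,
transposition, junction reads, amplicons, capsids) uses
`SeedSequence(master, spawn_key=(stage_offset, ...))` with fixed offsets, so
stages are independently reproducible and all emitted files are
byte-identical across runs.

## DGR model and activity statistic

Amplicon reads span `primer_fwd + VR + revcomp(primer_rev)`. Per read, each
targeted (TR-adenine) position is substituted with probability `mu_targeted`
(default 0.02) by a uniform draw from the other three bases; independently,
every position (primers included) is substituted with probability
`eps_background` (default 0.001, a typical high-quality short-read error
rate). Mutagenesis is per read, not per template molecule: no PCR-duplicate
structure is modelled. Half the reads are emitted reverse-complemented.

Analysis anchors reads by exact primer matching in either orientation
(0 mismatches; reads whose primers carry a background error — ~3% at the
defaults — are lost, which mirrors real amplicon filtering), counts alleles
positionally from segments whose length equals the VR reference
(length-discordant segments are indel evidence, discarded and tallied), and
computes per-site diversity π = 1 − Σ f_b². π is 0 at monomorphic sites and
at most 0.75; zero-coverage positions are NaN-flagged and excluded from all
means rather than imputed.

The activity rule is `mean(π, targeted) > mean(π, non-targeted) + 2·sd`,
with the sample standard deviation (n−1 denominator; the denominator is a
free choice and barely matters at 81 non-targeted positions). Calls require
at least `min_spanning` (default 30) full-span reads; with fewer the call
status is `insufficient_coverage`, and with no targeted or fewer than two
non-targeted covered positions it is `not_evaluable`.

Under the generative model the expected non-reference frequency is
`eps·(1−mu) + mu·(1−eps/3)` at targeted positions (a background hit can
revert a targeted substitution with probability 1/3) and `eps` elsewhere, so
the targeted/background fold enrichment has a closed form used as the oracle
in tests. Calibration at the defaults (200 simulated datasets, 100 reads):
the null (`mu=0`) false-call rate is at the percent level — a false call
requires many targeted-position errors while the 81 non-targeted positions
stay quiet — and power at `mu=0.02` is essentially 1.

Only the full-span amplicon route is implemented; a global-mapping route
admitting partial-span reads has a different background structure and is not
normative here.

## Transposition junctions

Planted events are distinct coordinates drawn uniformly outside the prophage
± one read length (clips near the resident locus would recover the native
junction), each with an independent uniform orientation. The junction
coordinate convention is: for `+` orientation the last chromosomal base
before the inserted prophage copy; for `-` the first chromosomal base
adjacent to the prophage start in read orientation. Junction reads are
`flank + prophage_start_sequence` with the flank length uniform in
`clip_length_range` (default 20–40 nt), emitted as prophage alignments at
position 1 with CIGAR `kS mM`. No target-site duplication is modelled (its
length is not established for this phage; Mu's 5 bp would not change the
estimators) and the junction/capsid read channels are error-free by default —
the exact-matching detector is deliberately tested under its own model
assumptions; real data would route through an aligner upstream.

Detection extracts leading soft clips (≥ `min_clip`, default 15 nt) of reads
aligned at prophage position 0 and relocates each clip on the chromosome by
exact full-length matching of the clip and its reverse complement
(overlapping occurrences enumerated) — the string-search equivalent of a
100%-identity, 100%-coverage short-read BLAST. Clips with zero or multiple
placements are tallied and discarded; unique placements inside the resident
locus ± margin are discarded as native. Events are distinct
(coordinate, orientation) pairs; per-event supporting-read counts are
retained, so both locus-level and read-level totals are available. Clips at
the prophage 3′ end are extractable (`side="both"`) but excluded from
junction calling by default. Identical reads are not deduplicated. A 20-nt
flank in a 50 kb random genome is unique with overwhelming probability, so
on simulated data recovery is exact with zero discards; raising `min_clip`
can only remove fragments, so event counts are monotone non-increasing in it
(a property test).

## Headful packaging

Molecule model: each of `n_capsids` molecules starts `Uniform{29..31}` bp
upstream of the prophage 5′ end. Within the first `hazard_region` (15 kb)
of the prophage, packaging terminates independently before each base with
probability `hazard`, so the probability that a molecule reaches prophage
offset x is `(1−h)^min(x+1, 15000)`. The default hazard is
`ln(40)/15000 ≈ 2.46e-4` per base, calibrated so survival of the full hazard
region is 1/40 — the observed left/right coverage asymmetry. Survivors
complete the prophage and append a `Uniform[1000, 2300]` bp 3′ host flank
(the data constrain only the ~1–2.3 kb range; uniform is the least
structured choice consistent with the steadily decaying coverage tail).

Read model (single-end): each molecule contributes one terminus-anchored
read starting at its 5′ end — the terminal sonication fragment, which is
what makes the discrete 29–31 bp host-flank signal directly observable —
plus interior reads with uniform start positions at mean per-base rate
`capsid_read_depth / capsid_read_length`, truncated at the molecule 3′ end
and dropped below 30 bp. Defaults: read length 50 bp, depth 1.0,
n_capsids 15 000 (~1.4 M reads). The short read length is chosen so that the
coverage ramp at molecule termini (~one read length) stays small relative to
the 500 bp end windows of the asymmetry estimator.

Estimators, all on normalized depth (depth / reads mapped in the region,
which makes profiles scale-invariant under read duplication):

* `end_ratio`: mean normalized depth over the first `window` (default
  500 bp) of the prophage divided by the last `window`. Known biases of the
  window estimator relative to the ideal point ratio `(1−h)^(−15000) = 40`,
  derived from the model: averaging the geometric decay over the left window
  (factor `(1 − e^{−500h})/(500h) ≈ 0.94`) and the residual start-ramp and
  terminal-read overshoot (≈ ±3%). The expected estimate at the defaults is
  ~38, and measured values across seeds fall in 37–41 with survivor-count
  noise `≈ 1/sqrt(0.025·n_capsids)` (~5% at the defaults). The window size
  trades decay-averaging bias (grows with window) against ramp bias and
  noise (shrink with window); 500 bp is near the optimum and is
  configurable.
* `five_prime_flanks`: histogram of `prophage_start − alignment_start` for
  reads starting upstream of and overlapping the prophage start.
  Terminus-anchored reads put ~n_capsids/3 counts on each true flank size
  while interior reads scatter a uniform background (~2% of molecules per
  size at the defaults); sizes below `min_frac` (default 0.10) of the modal
  count are filtered from the reported support. The filter is what turns a
  contaminated histogram into the exact planted support; it assumes the
  spike-to-background ratio exceeds ~10, which holds whenever read starts
  are at least ~5× denser at molecule termini than per interior base.
* `three_prime_extent`: the smallest distance past the prophage 3′ end where
  normalized depth falls below `frac_threshold` (default 1%) of the mean
  over the last 100 bp inside the prophage. For a Uniform[1000, 2300] flank
  the tail declines linearly from 1000 to 2300 bp and crosses 1% near
  2290 bp; the estimator therefore reports the upper end of the flank range,
  within [1000, 2500]. If the threshold is never crossed the extent is
  right-censored at the profiled distance and flagged.

## What the simulator does not emulate

Uniform base composition (no GC skew or repeats — real chromosomes have
repeated elements that would inflate multi-placement discards); no
sequencing error in junction/capsid reads (optional in the amplicon channel
only via `eps_background`); no paired-end structure, quality-score
variation, PCR duplicates, coverage bias, or partially packaged/ejected DNA
degradation products. Passing tests therefore validate the estimators under
their stated model assumptions, not robustness to every artifact of real
libraries; the discard tallies and status flags are the designed entry
points for such artifacts.

## Numerical and interface choices

Coordinates are 0-based half-open internally; SAM positions are converted on
ingest (pysam) and emission. Coverage is accumulated from aligned reference
spans (clips excluded; records with deletions are expanded into match
blocks). Prevalence percentages round half away from zero. The pipeline
writes only plain-text formats (FASTA/FASTQ/SAM/BED/TSV/JSON); the run
report contains the config hash, seed and tool version but no timestamps, so
fixed-seed runs are byte-identical end to end. Problem sizes used by the
test suite and the reproduction script (200+200 calibration datasets at
100 reads, 100 junctions × 3 reads, 15 000 capsid molecules, 50 oracle
genomes of 50 kb) are the package's chosen defaults, sized so Monte-Carlo
noise is well inside each check's tolerance.
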