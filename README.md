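# prophagedyn

Analysis toolkit for the dynamics of a Mu-like transposable prophage in a
bacterial host genome, built around three sequencing-based measurements and a
ground-truth read simulator:

1. **DGR hypermutation** — a diversity-generating retroelement (DGR)
   hypermutates the variable repeat (VR) of a target gene at positions that
   are adenines in its template repeat (TR). From full-span amplicon reads the
   package builds a per-position allele matrix, computes per-site nucleotide
   diversity

   π = 1 − (f_A² + f_T² + f_C² + f_G²),

   and calls the DGR active when
   mean(π, A) > mean(π, nonA) + 2·sd(π, nonA),
   where "A" are the TR-adenine (targeted) positions.

2. **Replicative-transposition junctions** — a transposable prophage that
   replicates copy-in-place creates new phage–host joints. Reads aligned to
   the prophage that are soft-clipped at the prophage start carry the new
   chromosomal flank in the clip. Clips ≥ 15 nt are relocated onto the
   chromosome by exact full-length matching (both strands, overlaps allowed);
   uniquely placed clips are aggregated into distinct
   (coordinate, orientation) junction events with supporting-read counts.

3. **Headful-packaging ends** — capsid DNA coverage over the prophage and its
   host flanks. Packaging initiates 29–31 bp upstream of the prophage 5′ end,
   terminates stochastically within the first 15 kb (a per-base hazard *h*
   gives geometric survival (1−h)^x), and fully packaged molecules co-package
   1–2.3 kb of 3′ host DNA. The package reports the left/right end-window
   coverage ratio, the discrete 5′ host-flank size distribution, and the
   3′ host-flank extent.

The simulator (`prophagedyn.simcore`) generates a host chromosome with an
embedded prophage, plants transposition events, emits junction-spanning
reads (FASTQ + SAM + truth BED), VR amplicons with adenine-templated
hypermutation plus background error, and capsid reads from the left-initiated
packaging process — all byte-reproducible from a single master seed, so every
analysis can be validated against planted ground truth.

## Worked example

```sh
prophagedyn run-all --outdir demo --seed 1
prophagedyn report demo/report.json
```

which prints (abridged):

```
[transposition]
  total_events: 100
  total_supporting_reads: 300
  planted_events: 100
  recovered_planted: 100
  false_positives: 0

[dgr]
  n_spanning_reads: 972
  mean_pi_A: 0.0393...
  threshold: 0.0070...
  active: True
  fold_enrichment: 16.9...

[packaging]
  end_ratio: 37.89...
  flank5_support: [29, 30, 31]
  flank3_extent: 2288
```

Reading: all 100 planted transposition junctions were recovered at exact
coordinates with no false positives; the VR is called DGR-active because mean
diversity at TR-adenine positions (0.0393) exceeds the non-targeted mean plus
two standard deviations (0.0070), with mutations ~17-fold enriched at
targeted positions; capsid coverage is ~38-fold higher at the prophage left
end than the right (the planted hazard corresponds to an ideal 40-fold
survival ratio), packaging initiates 29–31 bp upstream of the prophage, and
co-packaged 3′ host DNA extends ~2.3 kb.

Each stage is also available separately (`prophagedyn simulate | dgr |
transpose | package`), consuming/producing plain FASTA/FASTQ/SAM/BED/TSV/JSON;
see `prophagedyn --help` and `docs/methods.md` for the model, parameters and
estimator details.

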