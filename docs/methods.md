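# Methods

## Scope and data model

`chronoswitch` operates on transcript-level TPM quantifications of an
RNA-seq time course with a single sample per time point. The central
container is the `TimeCourseMatrix`: transcripts × strictly increasing
sampling times (hours), with a transcript→gene map. The reference design
it targets — and which the synthetic generator emulates — is 11 samples
3 h apart spanning 30 h of experimental time, with isoform abundances
carrying a ~24 h periodic component. Time is measured from the first
sample; reports can be shifted to an external clock (e.g. zeitgeber
time) with a configurable origin offset, since a fixed offset changes
labels but no statistic.

Quantifications are read in the Salmon `quant.sf` dialect (columns
matched by header name; extras ignored). A transcript missing from some
samples is an error by default; zero-filling is opt-in, because silently
imputing zeros can fabricate expression reversals. Genomic coordinates
are 0-based half-open everywhere inside the package and converted only
at the GTF boundary (1-based inclusive), so the NMD and splice-event
arithmetic lives in a single convention.

## Switch detection

For each unordered isoform pair of a gene, the difference series
`d(t) = exp_i(t) − exp_j(t)` is scanned for strict sign changes between
consecutive samples; exact zeros are never sign changes (a conservative
tie rule that avoids spurious switches on flat profiles). The switch
time is the linear-interpolation root; consecutive crossings partition
the samples into the flanking intervals I₁ and I₂.

Crossing localisation can optionally run on a least-squares polynomial
fit of each series (degree 4 by default — over a ~30 h window a quartic
tracks one full ~24 h cycle while suppressing sample-to-sample jitter).
The five event metrics are always computed from the observed
per-timepoint values, because the magnitude definition is a mean over
sample expressions, not over fitted values:

* `diff` (S₂): sum over both flanks of the mean absolute difference;
* `prob`: fraction of flank samples ordered consistently with the
  switch; ties count against it;
* `pval`: within each flank, a one-sample two-sided t-test of the paired
  differences against zero; the event p-value is the larger of the two.
  Zero-variance flanks resolve by their mean (p = 0 if nonzero, else 1);
  a flank with fewer than 2 samples has no defined p, and the event then
  fails the `min_points` cutoff;
* `cor`: Pearson correlation over all time points (0 by definition for a
  constant series);
* `min_points`: the smaller flank size.

The filter cascade is conjunctive with defaults `prob ≥ 0.5`,
`diff ≥ 1 TPM`, `pval ≤ 0.001`, `min_points ≥ 2`, correlation magnitude
`≥ 0`, and switch time within [0, 30] h. The correlation gate is applied
to |cor|: the archetypal switching pair is antiphase (cor = −1), and a
signed gate at 0 would veto exactly the events the method exists to
find; at the default cutoff 0 the gate is therefore vacuous, matching
the behaviour of the R tooling this reconstructs. No multiple-testing
correction is applied to switch p-values (the raw 0.001 cutoff is the
documented operating point); BH-adjusted filtering can be layered on by
the caller.

### A structural note on the p-value gate

With 3 h sampling and a 24 h period, antiphase sinusoids cross every
12 h, so a flanking interval holds at most 4 samples. Within a flank the
paired differences trace a half-sine, whose mean/sd ratio is ~2
independent of amplitude (the t statistic is scale-invariant). The
maximal attainable |t| is ≈ 4–8, while two-sided p ≤ 0.001 needs
|t| ≥ 12.9 at df 3. Smooth sinusoidal switches therefore cannot pass the
0.001 gate under this design, regardless of noise level — the gate
selects switches whose separation is sustained and flat within flanks
(step-like reversals pass at ~97% under 2 TPM noise; see the acceptance
script's per-archetype recovery numbers). This is an intrinsic property
of the published operating point under single-replicate sampling, and
the package reports it rather than papering over it.

## Switch time peaks

Filtered switch times are binned half-open at the sampling interval
(3 h), aligned to the first sample; out-of-range events go to a reported
overflow bucket. A bin is called an STP when its count (a) strictly
exceeds both neighbours (boundary bins compare to their single
neighbour, adjacent ties resolve to the earlier bin) and (b) reaches
mean + α·sd of all bin counts. The source analyses read peaks off the
histogram by eye; this rule is a deliberate parameter-light
quantification of "one tall bin among ~10", with α (default 1.0) as the
only sensitivity knob — users should expect to tune α on real data. The
rule is invariant under uniform scaling of counts. Kernel-density and
circular (24 h wrap-around) peak calling are out of scope.

## Consequence classification

All gain/loss polarity flows from one definition: the *gained* isoform
is the one dominant after the switch time. Per axis:

* **Coding potential.** Externally computed scores (CPAT-style tables)
  are used verbatim when provided. The built-in score is
  `logistic(1.2·ln(L+1) + 2.0·coverage + 2.0·fickett − 8.0)` with L the
  ORF length (nt), coverage the ORF fraction of the transcript, and
  fickett the Fickett TESTCODE statistic with its published lookup
  tables. A transcript without a complete ORF scores 0. The constants
  are fixed; they place long, high-coverage, codon-biased ORFs well
  above the 0.725 call cutoff and ORF-less or short-ORF transcripts well
  below it. The heuristic exists so the pipeline is self-contained; it
  is not a CPAT replacement, and real scores plug in unchanged.
* **ORF.** The longest ATG-initiated forward-frame ORF ending at a stop
  codon (ties to the 5'-most; N-containing codons never match). Pairs
  are "similar" when the relative length difference is ≤ 0.1, otherwise
  longer/shorter; absence on one side is a complete gain/loss.
* **NMD.** The canonical 50-nt rule: sensitive when the stop codon ends
  more than 50 nt upstream of the last exon–exon junction (junction
  positions from cumulative exon lengths in transcript coordinates,
  strand-aware). Single-exon transcripts are never sensitive.
* **Splice events.** Pairwise genomic comparison: differing outermost
  5'/3' transcript boundaries → alternative TSS/TTS (strand-aware); an
  exon of one isoform inside an intron of the other → exon skipping; an
  exon spanning an entire intron of the other plus both flanking exon
  ends → intron retention; a shared exon differing at one internal
  boundary → alternative 5'/3' splice site, except when that boundary is
  already explained by a retention relationship (otherwise every
  retained intron would double-report as an alternative donor).
* **Domains.** Literal/regex motif patterns scanned over the predicted
  protein, overlapping hits included. Adequate for planted-truth
  recovery and for user-supplied curated motifs; explicitly not a
  profile-HMM (PFAM) replacement.
* **ORF similarity.** Jaccard overlap of the genomic base intervals
  covered by the two ORFs (0 when either is absent; "similar" at ≥ 0.9).

Per STP, gains vs losses on each axis are tested with a two-sided exact
binomial test against 0.5 (unchanged pairs excluded) plus a 95%
Clopper–Pearson interval for the gain fraction; an axis with no gains or
losses is reported as not applicable. Whether the source analyses used a
binomial or proportion test is not documented; the exact binomial is
this package's choice and matches enumeration for all n ≤ 12 in the
test suite. Pairs lacking a model or sequence are skipped with a logged
reason, never dropped silently.

## Enrichment

Over-representation uses the exact hypergeometric upper tail (integer
summation, so tiny tails are exact) per gene set with at least one query
overlap; only tested sets enter the Benjamini–Hochberg denominator. The
universe defaults to the union of all collection members and is
overridable; query genes outside it are dropped with a logged count.
Defaults: p ≤ 0.05 and BH q ≤ 0.2 (q ≤ 0.5 in disease-ontology mode), at
most 10 terms, ranked by adjusted then raw p. "BH" is read as
Benjamini–Hochberg; plain Bonferroni is available as an option rather
than assumed.

## Synthetic data

The generator is the package's study-condition stand-in, not a tuning
surface. Defaults: 11 time points 3 h apart, period 24 h, baseline
10 TPM, amplitude 5 TPM, uniform noise of amplitude 2 TPM
(`value + U(−2, 2)`, clamped at 0 — mirroring jitter-style noise
injection for a single-replicate design), seed-deterministic throughout.

Switching pairs are planted as antiphase waveforms `B ± A·w(t)` with
archetypes: `sinusoid` (smooth ~24 h oscillation; crossings at the sine
zeros, recorded analytically in the truth), `square` (same zeros, flat
flanks), `step` (one crossing, flat flanks) and `ramp` (one linear
crossing). Non-switching isoforms are proportional rhythmic profiles at
0.15× scale steps, which cannot cross one another or the planted pair.
Gene models come from four structural archetypes (coding→noncoding via
alternative stop, NMD via a retained intron carrying an in-frame
premature stop, domain loss via alternative TSS past the first start
codon, and codon-aligned exon skipping), engineered so each planted
property is provable by construction: coding bodies are NNC codons (no
stop codons and no ATG in any frame), untranslated and intronic sequence
is scrubbed of ATG, so the planted ORF is the unique complete ORF.

What the generator does *not* emulate: quantification uncertainty,
count-based (negative-binomial) noise, correlated noise across
time, partial/leaky switching, overlapping genes, and realistic human
codon usage. Passing recovery tests therefore demonstrate correctness of
the detection and classification logic under the stated design, not
performance on real libraries.

## Problem sizes and numerics

The default verification runs use 5–40 genes per replicate over 100–200
seeded replicates for recovery/specificity, 230 genes (~207 pairs) for
consequence truth, and 2,000 replicates for the enrichment null
calibration (universe 60, set size 12, query 5 — chosen because the
attainable discrete level of the hypergeometric test there, 0.0499, sits
next to the nominal 0.05, making the calibration check informative).
Switch-magnitude agreement with its brute-force definition is exact to
1e-12 relative; polynomial smoothing reproduces degree ≤ 4 inputs to
1e-8 relative. Pipeline runs are bit-reproducible under a fixed seed;
the global seed fans out to per-stage seeds via SHA-256 so stages can be
rerun in isolation.

## Known limitations

* The switch p-value construction (max of two within-flank one-sample
  t-tests) reconstructs undocumented internals of the originating R
  tool; with replicated designs a replicate-aware test would be
  preferable and is out of scope.
* The STP rule is a reconstruction; α needs user calibration on real
  histograms.
* Isoform-fraction (relative-usage) switches, rhythmicity testing and
  period estimation are deliberately not implemented.
* The coding-potential heuristic and motif scanner are self-contained
  stand-ins wired for external CPAT/PFAM outputs to replace.
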