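# chronoswitch

Time-course isoform switch analysis for transcript-level RNA-seq
quantifications. `chronoswitch` detects reversals in the relative
abundance of transcript isoforms of the same gene across a sampled time
course (e.g. a circadian design with one sample every 3 h), locates
*switch time peaks* (STPs) — time bins in which switching events
concentrate — classifies the predicted functional consequences of each
switching isoform pair, and tests switching-gene sets for pathway
over-representation.

It is aimed at transcriptomics researchers who quantify time-course
RNA-seq at the transcript level (Salmon `quant.sf` tables in TPM) and
want to ask *when* isoform usage flips and *what it does* to the coding
product — without replicates, which is common in dense time-course
designs.

## The statistic

For isoforms *iso_i*, *iso_j* of one gene, a candidate switch is a sign
change of the expression difference between consecutive time points. Each
switch at time *t* splits the neighbouring samples into a flanking
interval before (*I₁*) and after (*I₂*), bounded by the adjacent
crossings. The switch magnitude is

    S₂(iso_i, iso_j | I₁, I₂) = d(iso_i, iso_j | I₁) + d(iso_i, iso_j | I₂)

    d(iso_i, iso_j | I_k) = (1/|I_k|) Σ_{m ∈ I_k} | exp_i(m) − exp_j(m) |

i.e. the sum over both flanks of the mean absolute TPM difference of the
pair. Each event also carries the fraction of flank samples consistent
with the switch (`prob`), the larger of the two within-flank one-sample
t-test p-values of the paired differences (`pval`), the Pearson
correlation of the two series (`cor`), and the smaller flank size
(`min_points`). Events are filtered conjunctively (defaults: `prob ≥ 0.5`,
`S₂ ≥ 1` TPM, `p ≤ 0.001`, `min_points ≥ 2`, `|cor| ≥ 0`, switch time in
[0, 30] h). Filtered switch times are binned at 3 h; a bin is an STP when
it is a strict local maximum of the histogram and exceeds
mean + α·sd of the bin counts.

For each switching pair the isoform gaining dominance is compared to the
one losing it: coding potential (external CPAT-style scores, or a
built-in logistic score over ORF length, ORF coverage and the Fickett
TESTCODE statistic; cutoff 0.725), ORF length (relative difference
cutoff 0.1), NMD sensitivity (50-nt rule), intron retention and the
generating splice event, domain content (motif library), and ORF
genomic-overlap similarity. Per STP, gains vs losses on each axis get a
two-sided exact binomial test and 95% Clopper–Pearson interval. Gene-set
over-representation uses the hypergeometric upper tail with
Benjamini–Hochberg correction (p ≤ 0.05, q ≤ 0.2; q ≤ 0.5 for
disease-ontology-style collections; top 10 terms reported).

## Worked example

Everything below is synthetic — the package ships a generator that
plants expression reversals with known crossing times:

```python
import chronoswitch as cs
from chronoswitch.synthetic_data import SimulationConfig, simulate_profiles

cfg = SimulationConfig(n_genes=12, fraction_switching=0.5, noise_amount=2.0,
                       seed=42, profile_archetype="step")
matrix, truth = simulate_profiles(cfg)
events = cs.score_all_genes(matrix)
kept = cs.filter_switches(events)
print(f"{len(events)} candidate events, {len(kept)} pass the filter")
for e in kept[:3]:
    print(f"{e.gene_id}: {e.iso_i} -> {e.iso_j} at t={e.switch_time:.1f} h "
          f"(S2={e.diff:.1f} TPM, prob={e.prob:.2f}, p={e.pval:.2e})")
hist = cs.bin_switch_times(kept, bin_width=3.0, origin=0.0, t_max=33.0)
for s in cs.detect_stps(hist, alpha=1.0):
    print(f"{s.name}: bin [{s.bin_start:g}, {s.bin_end:g}) h with {s.count} events")
```

prints

```
6 candidate events, 6 pass the filter
G0002: G0002.T1 -> G0002.T2 at t=12.7 h (S2=20.2 TPM, prob=1.00, p=4.73e-05)
G0005: G0005.T1 -> G0005.T2 at t=13.7 h (S2=19.0 TPM, prob=1.00, p=3.06e-04)
G0006: G0006.T1 -> G0006.T2 at t=12.9 h (S2=21.6 TPM, prob=1.00, p=1.29e-04)
STP1: bin [12, 15) h with 6 events
```

Six isoform pairs were planted with a dominance reversal at 13.5 h; all
six are detected near the true time, survive the filter cascade, and
concentrate in a single switch time peak spanning 12–15 h. The same flow
runs from the shell (`chronoswitch simulate`, `detect`, `stp`,
`consequences`, `enrich`, or `run --config run.yaml` for the whole
pipeline with a hashed output manifest).

A companion helper makes the gene-vs-isoform distinction concrete:
`gene_expression_change(matrix, gene, t0, t1)` sums a gene's isoform
TPMs at two times — a gene whose total moves only from 773.27 to
804.55 TPM (+4.05%) can still hide a complete reversal of its isoforms,
which is the phenomenon this package is built to expose.

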