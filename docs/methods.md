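# Methods

## The measurement problem

A polymerase used for one-step RT-PCR introduces substitutions while
reverse-transcribing RNA and while copying DNA.  Deep sequencing of the
amplified product cannot distinguish those *pre-amplification* errors from
the far more numerous sequencing and library-amplification artifacts, and a
raw error count is also unfair to an enzyme that simply amplified more.
The pipeline in this package addresses both problems the way the
UMI-consensus fidelity assays in the molecular-diagnostics literature do:

1. **Molecular tags (UMIs).**  After RT-PCR, each product molecule receives
   a random oligonucleotide tag before a final high-fidelity amplification.
   All reads sharing a tag ("a family") trace back to one molecule, so a
   true polymerase error is present in essentially every read of its
   family, whereas a sequencing error is private to one read.  A family
   scores an error (1) at a reference position only when at least 90% of
   its covering reads carry the *same* non-reference base; families need
   more than 3 reads (>= 4) to vote, and at least that many reads covering
   the position.  The per-position raw rate is errored families over
   qualifying families.
2. **Doubling-number normalization.**  With A = n(after PCR)/n(input RNA)
   and D = ln(A)/ln(2), dividing each position's raw rate by D converts a
   cumulative error frequency into a rate per base per population doubling,
   comparable across enzymes with different amplification activity.  Only
   the ratio of the two quantities matters, so copies and moles are equally
   acceptable units.
3. **Windowed averaging.**  The average substitution error is taken over
   the primer-free interior of the amplicon (bases under the primers are
   dictated by the synthetic oligos).  One position — by default the
   3'-most reference T inside the window — is excluded as a clear outlier,
   mirroring how such positions behave in real libraries.  Positions with
   no qualifying families are omitted rather than imputed as zero.

Reported units are percent per doubling: 0.07 means 7 substitutions per
10,000 bases per doubling.

## Upstream read processing

* **Phred transform.**  Base-call error probability P = 10^(−Q/10).
* **Merging.**  Mates of a ~100-nt amplicon read into each other
  (2 × 75 bp).  Read 2 is reverse complemented and placed at the offset
  implied by the expected amplicon length; offsets within ±3 nt are scored
  by overlap matches and the best wins (ties to the offset closest to
  expected).  In the overlap the base with the higher Phred score is taken
  (ties to Read 1, which typically has the better early-cycle quality);
  the merged quality is the maximum of the two scores.  A merge is rejected
  below 60% overlap identity — mates that disagree that much are not from
  the same template.
* **Alignment.**  Global (Needleman–Wunsch, affine gaps) against the
  reference: match +1, mismatch −1, gap open −2, gap extend −1.  The
  misalignment fraction of a read is (mismatch columns + gap columns) /
  reference length; reads above 24% (strict) are removed.  In simulated
  libraries this removes adapter-dimer-like junk at the expected ~0.5%
  while keeping every genuine read.
* **Frameshift handling.**  Sequencer phasing/pre-phasing slips the cycle
  register by one, which appears as a single isolated 1-nt indel with the
  downstream segment intact at the shifted offset.  The affine-gap
  alignment already re-anchors the downstream base calls; the read is
  flagged *frameshift corrected* when the pattern holds (one interior 1-nt
  indel, downstream identity >= 90%, tolerating one further 1-nt indel
  within 3 columns of a sequence end — the junk base that the register
  slip pushes off the read's end).  The indel is charged as one gap
  column, never as mismatches, so such reads survive the 24% filter.

Design choices that the published workflow leaves open — the misalignment
metric, the minimum overlap identity, the inclusive 90% boundary computed
over covering reads, the same-alternative-base requirement ("carry *the*
misincorporation"), exact-match UMI grouping without edit-distance merging
— are implemented as stated defaults, are configurable, and are pinned by
boundary tests.

## The synthetic-data generator

`amplifid.simulate` emulates the fidelity experiment end to end with exact
bookkeeping of the truth:

* **RT-PCR as a branching process.**  Every input RNA is reverse-transcribed
  once; each PCR cycle duplicates each molecule with the per-cycle
  efficiency.  Substitutions are deposited per *new strand synthesis* at
  the per-base rate ε: the RT step, and both products of every duplication
  event, since each daughter duplex contains exactly one newly synthesized
  strand.  Mutations are inherited along lineages.  Under this model the
  population-mean burden grows by ε·L·(2e/(1+e)) per cycle (e = per-cycle
  efficiency), i.e. by ≈ ε·L per population doubling, which is exactly
  what dividing by D removes.  The expected recovery is therefore

      E[estimate] ≈ ε · (1 + c·2e/(1+e)) / (c·log2(1+e)),

  ≈ 1.06–1.11 · ε at the default conditions (c = 12 cycles, e = 0.9) — a
  small upward bias caused by the +1 RT synthesis and by lineage size
  biasing (molecules that duplicated more often have more descendants).
  The recovery tests budget for this.
* **Desk-scale population cap.**  The physical pool is truncated by uniform
  subsampling at `population_cap` (default 20,000); uniform subsampling
  leaves the burden distribution unbiased.  The untruncated population
  size is still tracked exactly with one binomial draw per cycle, so the
  recorded A = n(after)/n(input) is a realized count unaffected by the cap.
* **Tagging and sequencing.**  `n_umi_molecules` molecules are sampled
  without replacement and given random tags (collisions possible and
  recorded).  Family read counts are Poisson distributed — deliberately
  producing the 0–3-read families the >3-read rule must discard.  Each
  read pair derives from one post-tagging amplification copy (post-UMI
  errors are shared by the mates, as in a real library); mates then get
  independent per-base qualities (normal around Q30, sd 3, clipped to the
  printable Phred+33 range), call errors at 10^(−Q/10), and optional ±1
  phasing shifts.  Adapter-dimer-like contaminants are random inserts of
  amplicon length with self-consistent mates and a random tag: they merge
  cleanly and are removed by the misalignment filter, as junk is in real
  data.  UMIs ride in the read name by default; an inline mode (first k
  bases of Read 1) is available.
* **Determinism.**  One seeded NumPy generator drives every stage;
  identical configurations produce byte-identical FASTQ.

Default conditions mirror the assayed libraries: 10^4 input RNA copies of
a 100-nt N1-region amplicon, 12 PCR cycles at 90% per-cycle efficiency
(the bench protocol runs more cycles on more material; 12 cycles at 10^4
copies keeps the molecule pool at desk scale while preserving a realistic
doubling number of ~11), ~2,400 tagged families of mean size 10, 2×75 bp
reads, 0.5% contaminants, 0.2% phasing shifts.  The packaged default
reference is the 5' 100 nt of the SARS-CoV-2 nucleocapsid gene
(reconstructed from the N protein coding sequence; it contains the CDC N1
primer/probe region), with the terminal 20 nt on each side treated as
primer-binding sites.

What the generator does *not* model — and hence what passing tests do not
demonstrate about real libraries: polymerase indel errors (the statistic is
substitutions only), PCR chimeras, sequence-context-dependent error
hotspots, instrument-specific quality ladders, and UMI synthesis errors
(tag errors would split families rather than create false consensus).  The
per-doubling quantification step of the bench protocol whose product is
doubled ("results were multiplied by two") is ambiguous in the source
description and is not modelled.

## qPCR and library analytics

* **Standard curves.**  Replicate Cq values are averaged per concentration
  (matching how such curves are reported), then ordinary least squares of
  Cq on log10(concentration) gives slope m, intercept and R²; efficiency
  E = 10^(−1/m) − 1.  The perfect-doubling slope −1/log10(2) gives exactly
  100%.
* **LOD comparison.**  LODs (lowest reliably detected copy number) are
  taken as given; the fold change is their ratio.  Whether "reliably"
  means one or both replicates is an upstream decision this package does
  not make.
* **Library coverage.**  2^n genotypes over n on/off mutation sites.  With
  V equiprobable variants and N picks, the expected covered fraction is
  1 − (1 − 1/V)^N; the probability of full coverage uses inclusion–
  exclusion computed in log space with terms truncated below 1e−15
  (numerically safe at V = 256), falling back to seeded Monte Carlo for
  V > 10,000.  Equiprobable sampling follows from the equimolar synthesis
  of the plasmid pool; a weight vector can be supplied where that fails.
* **Enrichment.**  Per-site mutation frequency and mutation-load histogram
  within active and inactive variants; frequencies are order-invariant and
  load histograms sum to the group sizes by construction.

## Numerical and statistical notes

* The standard error attached to the windowed average treats per-position
  family tallies as independent binomials; families span many positions,
  so this is an approximation (slightly anticonservative for clustered
  errors).
* Alignment tie-breaks follow the pairwise aligner's first-reported
  optimum; scoring constants are fixed and recorded in the run metadata.
* A<1 (net loss of material) yields a negative doubling number and is
  reported as a warning-level condition rather than an error; normalization
  itself requires D > 0.
* Simulation-facing tests compare against independent oracles (count-only
  branching re-simulation, burden lineage walks, occupancy closed forms,
  an exhaustive affine-gap DP, exact Stirling-number occupancy
  probabilities) rather than against the code paths they check.

## Problem sizes used in the shipped checks

The recovery runs use the default study conditions above (~24,000 read
pairs, ~2,370 qualifying families per run); consensus-suppression checks
use ~2,100 families of mean size 8.  These sizes put the sampling error of
the recovered average at roughly 3% relative, an order of magnitude below
the 30% acceptance band for parameter recovery.
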