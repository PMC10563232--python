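# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limits of what the test suite demonstrates.

## Study design being emulated

The pipeline targets a two-condition bulk RNA-seq design: two tissue states
("TPS", pre-fiber-growth, and "MPS", fiber-growing stem bark) with three
biological replicates each, profiled for mRNAs and lncRNAs (one library
type) and for miRNAs (a small-RNA library type). Analysis proceeds:
consensus lncRNA identification → normalization → differential expression →
miRNA targets → lncRNA targets → ceRNA triads/networks → GO enrichment.
Read alignment, transcript assembly and miRNA annotation are upstream of
this package: its inputs are transcript models (GTF), sequences (FASTA),
raw count matrices and a design table (TSV).

## Consensus coding-potential classification

A transcript is confirmed as a lncRNA iff its length is ≥ `min_lnc_length`
(200 nt, the conventional long-ncRNA floor, applied first: shorter
transcripts are labelled `too_short` and skip voting) and at least
`min_votes` (3) of four scorers vote noncoding.

Built-in scorers and their thresholds (config keys):

| scorer  | statistic                                  | coding iff |
|---------|--------------------------------------------|------------|
| orf     | longest ATG→stop ORF, 3 forward frames, nt | ≥ 300      |
| fickett | TESTCODE position/content table statistic  | ≥ 0.74     |
| hexamer | mean log₂ LLR of in-frame hexamers of the longest ORF (whole sequence if no ORF) | > 0 |
| domain  | membership in a supplied protein-domain hit table | any hit |

The ORF length includes the stop codon; an ORF running off the 3′ end
counts to the last complete codon. Ambiguous bases (N) are skipped in
Fickett counts and hexamer windows rather than raising. The Fickett lookup
tables are the classic published position/content bins. The hexamer tables
are derived *analytically* from the same generative sequence models the
simulator uses (codon-pair products for coding, first-order chain marginals
for noncoding, pseudocount 1e-9), so no training corpus ships with the
package. When a table of external tool scores is supplied instead, votes
use the conventional thresholds: CPC > 0, CNCI > 0, txCdsPredict ≥ 500
(inclusive), any PFAM hit.

Judging a transcript's hexamer statistic on a short spurious ORF is noisy;
on ~2 kb AT-rich background sequence the Fickett and hexamer scorers
jointly misvote a few percent of the time. The consensus absorbs this (the
domain and ORF votes are stable), which is exactly the rationale for the
3-of-4 rule.

## Normalization

FPKM = count / ((length/10³)(library/10⁶)) with effective length = sum of
exon lengths (no fragment-length model) and library sizes defaulting to
column sums. TPM divides counts by length, then rescales each sample to
10⁶; for miRNA tag counts length is fixed at 1, i.e. a pure depth
normalization of clean-tag counts. Column sums of TPM equal 10⁶ whenever
the column is not all-zero (all-zero columns stay zero and are logged).
Transcript-level lengths are used for FPKM; the expression matrices are
transcript-level throughout.

## Differential expression

The MA-plot random-sampling statistic is a two-library test, so replicates
are pooled by summing counts within each group; the fold-change criterion,
by contrast, uses the ratio of per-replicate group means of the normalized
matrix (MPS mean / TPS mean). Under the binomial sampling null the delta
method gives Var(M) = [(1−c₁/N₁)/c₁ + (1−c₂/N₂)/c₂]/ln²2 and
z = (M − log₂(N₁/N₂))/√Var; the formula was validated against a binomial
Monte-Carlo null (empirical P(p<0.05) = 0.048 on 10⁴ draws at c≈100) rather
than against any external implementation. Zero counts receive a +0.5
continuity correction before logs; a feature with both pooled counts zero
is reported z = 0, p = 1. BH adjustment is the standard step-up
(statsmodels' `fdr_bh` behind the module surface; an independent
brute-force oracle lives in the tests).

A deliberate property of this design: with biological replicates the pooled
binomial null is anti-conservative (overdispersion), so many null features
attain small Q values. Specificity comes from the *dual* criterion — the
fold filter (≥ 2 in either direction) removes essentially all of them,
since the sampling spread of a 3-vs-3 mean ratio at NB dispersion 0.05 is
far below two-fold. Fold changes of x/0 are +∞ (the call then follows the
Q criterion alone); 0/0 is not called.

## miRNA target prediction

The penalty aligner performs a gapped antiparallel alignment of the miRNA
(5′ position 1) against a target window by dynamic programming: mismatch
1.0, G:U wobble 0.5, indel 1.0, each doubled at miRNA positions 2–13 (the
plant-convention "seed"); target overhangs beyond the aligned region are
free, so scores are invariant under extending a window with non-pairing
flanks. Indel weighting: a deleted miRNA base is charged at its own
position; an unpaired target base is charged at the following miRNA
position (the pairing it disrupts). Ties in the traceback prefer pairing
moves.

The duplex-energy criterion reuses that alignment: energy = Σ over paired
positions of {G:C −3, A:U −2, G:U −1} kcal/mol, ratio = energy / perfect
duplex energy of the miRNA. These per-pair energies are a simplified
monotone surrogate for nearest-neighbor stacking; a full thermodynamic
table is a documented extension point. An edge is emitted only when
penalty ≤ 4.0 AND ratio ≥ 0.7 (both config keys), one best site per
(miRNA, transcript) pair.

Scanning every window with the Python DP is infeasible, so a vectorized
ungapped pre-scan runs over all window starts (transcripts concatenated
with unalignable separators) and the gapped DP rescans only candidates
within `score_cutoff + 2` penalty units, with ±3 nt of context for bulges.
A site that *requires* a bulge to come within that margin at every ungapped
offset would be missed; the generator plants substitution-only sites, for
which the pre-scan is exact.

## lncRNA target prediction

Pairs are gated on signed Spearman ≥ 0.6 and Pearson ≥ 0.6 across all six
samples (one coefficient per pair; n = 3 per group is too coarse for
group-wise rank correlation). `correlation_gate` computes Pearson on the
values it is given; the pipeline feeds it log₂(FPKM+1) by default
(`log_pearson`), because raw-scale Pearson over six samples of lognormal-ish
expression is dominated by single extreme values — Spearman is rank-based
and unaffected. Zero-variance vectors make both coefficients undefined: the
pair fails and is flagged, never passed silently.

Cis classification uses 0-based half-open genomic spans: intersecting spans
→ `cis_overlap` (antisense iff strands differ); otherwise the gap between
nearest span edges decides, gap ≤ 10 000 bp inclusive → `cis_nonoverlap`;
different chromosome or larger gap → trans candidate.

Trans candidates are kept when the best local antiparallel duplex energy
reaches −30 kcal/mol (inclusive), computed by a Smith–Waterman-style
minimization with the per-pair energies above and a penalty per mismatched
or looped-out position. That penalty defaults to **8.0 per position**: with
the −3/−2/−1 pair energies, any penalty below ~6 makes the expected step
cost of random pairing negative (random bases pair with probability ≈ 0.4),
putting the local alignment in its linear phase, where every kilobase-scale
pair drifts far past any threshold and the criterion loses all meaning. At
8.0 the background optimum of random 1.2 kb × 1.5 kb pairs sits near
−28 kcal/mol, so −30 selects genuine complementary stretches (a planted
30-nt complement scores ≈ −65) while still letting occasional strong random
matches through — duplex-based trans prediction at this threshold is
intentionally permissive, not a high-specificity filter. The row-recurrence
is vectorized (the in-row gap chain is folded in with a running minimum),
making the scan of a few hundred candidate pairs a matter of seconds.

## ceRNA triads, networks, enrichment

A triad is (DE miRNA m, DE lncRNA l, DE mRNA g) with edges m→l and m→g; per
miRNA the DE targets combine as a cartesian product. lncRNA→mRNA edges are
*not* required inside a triad — competition is defined by shared miRNA
targeting — and are reported as annotation. Networks are connected
components of the union graph of triad edges only (DE nodes only), sorted
by size then smallest node id. Enrichment is the exact hypergeometric upper
tail P(X ≥ k) per GO term over an annotated universe, with no
multiple-testing correction by default (a BH flag exists, off) and
enrichment called at P < 0.05.

## Synthetic-data generator

The generator is first-class, tested code. Defaults (all config keys):

* 80 mRNA, 60 lncRNA, 100 miRNA features; 8 disjoint planted triads;
  16/8/24 extra-plus-triad DE features per class (miRNA DE fraction ≈ 24%),
  with planted folds of 4 alternating up/down so compositional
  normalization (TPM/FPKM totals) stays near-neutral;
* negative-binomial counts, baseline mean 500, dispersion 0.05, per-feature
  lognormal baseline spread (sd 1.0 log₂), per-sample depth factors
  (sd 0.1 log₂); dispersion 0 degrades to Poisson;
* correlated lncRNA–mRNA pairs (6 antisense-overlapping, 6 within-10-kb
  neighbors, 6 distal, plus 2 distal controls) coupled via a shared
  per-sample latent factor on the log₂ scale: scale 2.5, latent correlation
  0.95, passed through a tanh squash bounded at ±3 log₂ units. The squash
  is monotone (rank-preserving, so Spearman is untouched) and exists to
  keep single wild features from dominating library sizes and distorting
  everyone else's FPKM. The scale is set so biological co-variation
  dominates counting noise: at n = 6, even noise-free bivariate normal data
  at ρ = 0.9 passes a 0.6 Spearman threshold only ~91% of the time, which
  is the binding constraint on gate recall, not the count model;
* coding sequences: ATG + 100–400 codons from a GC3-biased positional codon
  model + stop, flanked by background-chain UTRs; noncoding sequences: an
  AT-rich first-order chain, resampled until the built-in consensus calls
  the sequence noncoding. That rejection is the operational class
  definition — a real lncRNA catalog *is* the output of the same consensus
  — and makes planted class labels true by construction;
* planted miRNA sites: reverse-complement insertions with a configurable
  number of substitutions placed at non-pairing bases, preferring non-seed
  positions; triad mRNA sites go in the 3′ UTR so the planted ORF is
  untouched;
* distal correlated pairs carry a 30-nt complementary stretch copied from
  the partner (energy ≈ −65, always detected); control pairs are verified
  to *fail* the trans criterion (≈ 30% of random kb-scale pairs would pass
  it, so absence of complementarity must be enforced, not assumed);
* one chromosome (2 Mb default); loci are placed in shuffled order with
  inter-locus gaps of 10.3–12.5 kb so unrelated loci never fall inside the
  cis window; antisense partners overlap their mRNA on the opposite strand,
  neighbors sit 0.5–8 kb downstream; ~15% of unconstrained lncRNA genes get
  a second (truncated) isoform for the transcripts-per-gene summary;
* GO: ten terms with plant cell-wall-flavored names; one term is planted
  enriched among DE mRNAs (P(assign)=0.8 vs 0.05); domain hits cover 95% of
  mRNAs and no lncRNAs.

Identical config + seed give a byte-identical bundle (all writers sort on
stable keys; sub-generators are spawned from a single seed sequence).
`validate_truth` checks truth-file closure: every referenced id exists in
the GTF/FASTA/matrices and every triad member is in the DE sets and target
lists.

### What the generator does not emulate

Read-level artifacts (mapping bias, multimapping, positional coverage),
isoform-level expression deconvolution, genome-wide sequence composition
(transcript sequences are not tied to the genomic coordinates except where
a planted relation requires it), GC/length expression biases, batch
effects, and real miRNA biogenesis. Passing tests therefore demonstrate
that the statistical machinery recovers structure *of the kind planted*,
under an NB count model with lognormal heterogeneity — not performance on
real sequencing data.

## Problem sizes and runtime

The default bundle (≈ 145 transcripts, 100 miRNAs, 6 samples) runs the full
pipeline in ~20 s on one core; the test suite (including two full
end-to-end runs, the 500-case alignment-enumeration oracle, a 10⁴-feature
null calibration, 20-seed power and pair-recovery sweeps, and a dense
hypergeometric enumeration) completes in about a minute. These sizes were
chosen so planted-structure recovery is statistically comfortable (pooled
counts in the thousands put planted 4-fold changes many standard errors
from both thresholds) while keeping every oracle exhaustive where it claims
to be.

## Known limitations

* The pooled MA-plot test ignores replicate dispersion by design; it should
  not be read as a calibrated replicate-aware test (use an NB GLM for
  that). Its calibration claim holds only under the binomial null.
* The duplex energies are not thermodynamic free energies; the −30 kcal/mol
  threshold is meaningful only relative to this simplified scale and the
  loop penalty documented above.
* The ungapped pre-scan can miss bulged miRNA sites (see above).
* The correlation gate is signed; anticorrelated regulatory pairs (a
  repressive antisense lncRNA, say) are invisible to it. An absolute-value
  variant would be a one-line change but is not the default because the
  positive-gate convention is what the pipeline's downstream counts assume.
* With six samples, Spearman ≥ 0.6 has limited resolution; gate recall on
  truly coupled pairs plateaus around 93–95% regardless of count depth.
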