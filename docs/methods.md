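# Methods

This note records the statistical model, the parameter defaults and why
they hold, the numerical choices, what the synthetic data emulate, and
the known limitations. It documents what the code does; every empirical
statement here is recomputed by the test suite or `scripts/acceptance.py`.

## Junction databases

Coordinates are 0-based half-open internally; junction ids
(`chrom:pos5:pos3:strand`) and reports use 1-based splice-site
positions. Exons identical in (chrom, start, end, strand) across
transcripts are collapsed before pairing, which avoids duplicate
junction sequences. Every same-strand exon pair whose start coordinates
lie within the window (default 1 Mb, measured between exon starts)
yields one linear and one scrambled junction; each exon yields one
scrambled self-junction. Pairs crossing gene boundaries within the
window are kept and flagged `cross_gene`, since backsplices do not
respect gene models and the window — not the gene — defines the search
space.

Each reference is 150 nt per side (`pad_side`); shorter exon sides are
N-padded **distal** to the boundary, keeping the boundary at index 150
so offsets are computed identically for every junction. Fixed-length
references remove the alignment-length bias against circles of short
exons. Reference Ns match any read base at no penalty, mirroring the
near-zero N penalty needed when aligning reads against padded
references.

## Read-pair classification

Defaults: minimum boundary overlap 10 nt (user-configurable); score
threshold equivalent to 4 mismatches per 100 nt (mismatch penalty 6, so
`min_score = −0.24 × aligned_len`); circle-region buffer 15 nt for
annotated junctions and 50 nt for de novo candidates (mates there were
located only to 50-nt bins), applied symmetrically on both ends of the
region; maximum concordant fragment span 1000 nt.

R1 with any high-scoring genome or rRNA alignment is discarded; a
linear-junction alignment takes unconditional precedence over a
scrambled one (conservative: a read explicable by the linear
transcriptome is never circular evidence). R2 takes the highest
alignment score, ties broken genome > linear > scrambled > de novo.
Categories: a linear anchor with a mate on the opposite strand within
the fragment bound is `linear`; a scrambled anchor is `circular` when
the projected mate lies entirely inside the buffered circle region
(junction alignments are projected through their exons back to the
genome) and `decoy` otherwise, including other-chromosome and
same-orientation mates. The circle region spans the full min-to-max
coordinates of the two junctional exons because the circle may retain
or lose any interior introns/exons.

## The two-step GLM and junction statistics

Predictors (R1 only): intercept, boundary offset, alignment score,
mapping quality. Step 1 gives every read weight `1/|class|`, then all
weights are rescaled to sum to the number of training reads: the
*relative* weighting (equal class influence) is what the procedure
defines, while the total scale keeps the quasi-likelihood information at
sample size so Wald inference is meaningful — with weights summing to a
constant instead, standard errors inflate by ~√(n/2) and the
conservative-bound rule below degenerates. Step 2 sets linear-read
weights ∝ p̂ and decoy-read weights ∝ 1 − p̂ (renormalized per class), so
reads whose features contradict their mate-geometry label lose
influence, and refits.

Scored reads receive a conservative probability: the 95 % Wald CI bound
on the linear predictor mapped through the logistic link, lower bound
when p̂ ≥ 0.5 and upper bound when p̂ < 0.5 (shrinking toward ½), clamped
to (10⁻⁶, 1 − 10⁻⁶) before log-space products. The per-junction
posterior is computed in log space as P = σ(−Σ lᵢ) with
lᵢ = log((1−pᵢ)/pᵢ).

Linear junctions: the null moments μ, σ² of lᵢ are estimated once per
dataset over all decoy and linear reads (per-read averaging), and
z_n = (Σlᵢ − nμ)/√(nσ²) gives a one-sided p via Φ(z). The normal
approximation is asymptotic in n; junctions with very few reads inherit
CLT error, so the uniformity check conditions on n ≥ 5. Circular
junctions: the printed two-point artifact null (p̂ = 0.1 with 95 %
probability, 0.9 with 5 %) with μ = log 9, var = n·log²9, evaluated at
the minimum reportable posterior 0.9, reduces exactly to z = −2√n.
That variance is the second moment, not the central variance, of the
stated two-point law; the formula is implemented as defined since the
FDR machinery depends on it. BH correction is applied within junction
class. The naive single-end scorer sums mismatches over a junction's
reads and takes the **upper** Poisson tail P(X ≥ observed) at 1 %/base:
a low p flags excess mismatches, i.e. a likely false positive; only
this direction is consistent with the test's use for flagging
artifacts.

Report defaults: posterior ≥ 0.9 and ≥ 2 reads (configurable to 1 for
shallow libraries); naive-mode verdicts use p ≥ 0.9.

Degenerate fits: perfect or quasi-separation (divergent coefficients,
or median Wald SE of the training linear predictor > 4) triggers a
ridge-penalized IRLS fallback with predictors standardized internally,
unit ridge on that scale, and a near-free intercept, with a logged
`SeparationWarning`. Small, highly separable datasets routinely take
this path; the coefficients stay finite and the conservative bounds
stay ordered, at the cost of some shrinkage.

Known limitation: step-2 coefficient p-values are anti-conservative
under the null (the weights are functions of the same data; measured
~29 % nominal-5 % rejection in the symmetry simulation) while step-1
p-values are calibrated (~5 %). Junction-level inference does not use
coefficient p-values, so posteriors are unaffected; coefficient
significance should be read from the step-1 fit (`step1_beta`,
`step1_cov`).

## De novo discovery

Segment length defaults to read length − 65 (the classic trimming for
~100-nt reads); each segment must place uniquely with ≤ 2 mismatches,
same chromosome and strand, 3′ segment upstream of the 5′ segment in
transcript orientation. Bin size 50 nt; ≥ 3 distinct stacking offsets
(duplicate offsets are PCR-duplicate-like and carry no independent
evidence). The consensus score S sums the per-column non-consensus
fraction over columns with ≥ 2 reads; its null expectation is (number
of multi-covered columns) × error rate — ≈ 1 for ~100 columns at 1 % —
and candidates require S < 5 (strict). Consensus ties break
lexicographically (logged at debug level). Groups are rejected as
multi-breakpoint mixtures when more than one column of depth ≥ 3 has a
minority fraction > 1/3 — a formalization chosen because a second
breakpoint displaces a contiguous block of well-supported disagreeing
columns, whereas sequencing error scatters isolated ones.

Breakpoint refinement tests every consensus split with both fragments
≥ 20 nt against the genome within ±500 nt of each bin (≤ 1 mismatch);
among mappable splits a GT-AG-flanked one is preferred, then the U12
signature (donor `TATCCT` one nt downstream, or AT-AC termini), because
the donor-side `ag-GT` consensus makes the exact breakpoint ambiguous
at canonical sites. Candidates with no mappable split are dropped.
Junctions are named by a gene within 1 kb, else `UNAN`. Final filters
after realigning all unaligned pairs to the consensus index: naive
p > 0.9, decoy/circle ratio < 0.1, bin separation > 200 nt (interpreted
as bin-pair distance, the knob is exposed), then collapse to unique
chromosomal breakpoints.

The built-in matcher is a pigeonhole-seeded, ungapped, full-length
placement engine intended for toy genomes (tens of kb); real data
should supply precomputed segment alignments.

## Induction statistics

Depth constants: per-sample median count among junctions with > 5
counts. Exterior splices: a linear junction is exterior to a circle
when at least one splice site lies outside the circle's span; with
multiple circles above `k_min` counts (default 10; 0 for shallow data)
the exterior set is the intersection. The age contrast o is the age
vector centered to zero sum then scaled to unit 2-norm (in that order).
The z denominator is the plug-in Poisson variance of the contrast,
var⟨o, y⟩ = Σᵢ oᵢ² xᵢ/cᵢ, which makes z approximately standard normal
under exchangeability — the property the statistic exists for; a
variant that drops the oᵢ² weighting deflates z by ~√n and was
rejected on that calibration ground. z is reported missing when all
counts are zero. JRPKM uses the effective junction window
2 × (read_len − min_overlap) = 180 nt for 100-nt reads.

Two-timepoint comparisons use non-overlap of 95 % binomial CIs on the
circle fraction (Wilson by default for small-count coverage;
Clopper–Pearson selectable). The outlier analysis computes the
MLE-centered z_n and the OLS-residual z_o as printed (OLS of the circle
fraction on depth-normalized exterior linear counts, unweighted),
divides z_o by the median per-gene standard deviation to absorb Poisson
overdispersion, refers the result to t(n−2), and controls FDR at 0.001.
OLS-fitted fractions outside (0,1) are clamped with a warning. Both the
maximum and the median exterior z are available to callers; neither is
privileged.

## Synthetic data

The generator produces the study conditions the pipeline is tested
under, not a dial to tune: four 4-exon genes (300-nt exons, 500-nt
introns) on a single chromosome, GT-AG intron signals, one single-exon
circle per gene, 100-nt pairs from ~250-nt fragments, 1 %/base
substitution errors (no indels, matching the ungapped-alignment
design), 60 linear and 40 circular fragments per gene.

Two genes carry a nearly identical exon 2/3 pair (divergence d = 2,
substitutions at fixed quarter positions so each junction flank holds
exactly one discriminating base within read range — uniform placement
can make the true and artifact junction references identical, an
unresolvable geometry rather than a statistical failure). Because a
read tied between a linear and a scrambled junction is always assigned
to the linear one, an artifact circular read exists only when its
linear-junction alignment fails the 4-per-100 score threshold while the
scrambled one passes: one substitution at the discriminating position
plus exactly four extra errors. The generator plants such fragments
directly (30 per homolog gene, half with distant mates, becoming
decoys); a fraction draws fewer extra errors and remains linear,
providing the class overlap real data have. At 1 %/base such reads are
far too rare to arise spontaneously at desk scale, but they are the
mechanism by which deeply sequenced, highly expressed homologous genes
generate artifact circles.

Count tables use Poisson means base × (1 + slope × age) over ages 10–21
weeks, slopes planted on circular junctions only (default 0.05/week).
Feature tables draw (offset, score, mapq) directly per category — true
reads with offsets 10–50, near-zero scores, high mapq; decoys skewed to
offsets ≤ 15, depressed scores, low mapq — with a switch that collapses
both classes onto one distribution for null checks.

What passing these tests does *not* show about real data: no indels,
no quality-score structure, no fragment-length biases, uniform
expression within isoform class, one chromosome, a single homology
motif, and artifact reads with a fixed error count. The simulations
validate the statistical machinery and the decision rules, not aligner
behavior or library-preparation artifacts.

## Problem sizes

Deliberately desk-scale: ~15-kb genomes with ~400–460 read pairs per
end-to-end replicate (20 replicates), 10 000 junctions for null
calibration checks, 100 replicates at 5 000 reads/class for coefficient
recovery, and 10 000 depth-2 stacks for the consensus-score
expectation. The whole suite runs in minutes on one CPU.
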