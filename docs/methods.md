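# Methods

## The problem

Pooled single-cell CRISPR screens deliver dual-guide lentiviral vectors to
cells at low multiplicity of infection (MOI), then read out which guide each
cell received from a separate guide-capture sequencing library. Two physical
facts make the readout statistical rather than a lookup: (i) ambient guide
transcripts released during cell or nuclei preparation end up captured in
droplets whose cell never carried the guide, so every cell shows low-level
counts for essentially every guide; and (ii) cells that do carry a guide
express it at high but variable copy number. `guidecall` separates these two
populations per guide and turns the result into per-cell perturbation
assignments.

## Read extraction

A guide molecule is identified in a read when the read contains both a
library protospacer and the constant capture-sequence anchor (CS1,
`GCTTTAAGGCCGGTCCTAGCAA`), each within a configurable Hamming distance
(default d_max = 1; `N` bases always count as mismatches). Matching is a
direct sliding-window Hamming scan, reporting the leftmost qualifying
offset; protospacer and anchor are searched independently anywhere in the
read, and when several protospacers qualify the one with the fewest
mismatches wins (ties discard the read). An optional strict-layout mode
(`ReadLayout(strict_layout=True)`) instead requires the protospacer to sit
immediately 5′ of the matched anchor, for libraries where the geometry is
known exactly. Cell barcode (default 16 bp) and
UMI (default 12 bp, per the capture RT-primer design) are sliced from
configurable stream/offset positions; extra sequencing cycles beyond the
sliced window are ignored.

Captured barcodes are matched to the cell whitelist exactly, or corrected to
the unique whitelist entry at Hamming distance 1 (ambiguity drops the read).
An optional translation table maps captured (ATAC-space) barcodes to
canonical (GEX-space) barcodes before matching, since the two barcode spaces
differ per gel bead on the Multiome platform.

Counts are distinct UMIs per (cell, guide). Two collapse modes exist:
`exact` (distinct UMI strings — the default) and `directional`, which merges
UMIs within Hamming distance 1 into the higher-count UMI (ties absorb into
the lexicographically smaller), the standard adjacency treatment for
sequencing-error UMIs. Exact mode is order-invariant by construction; use
directional mode when per-base error is non-negligible, because a single UMI
substitution otherwise creates a spurious extra molecule.

## The guide-calling mixture

For one guide, let x_c be the UMI count in cell c. The model is a
two-component mixture

    P(x) = (1 − π) · ZINB(x; w₀, μ_lo, r_lo) + π · NB(x; μ_hi, r_hi)

with the negative binomial in mean/size form,
NB(x; μ, r) = Γ(x+r)/(Γ(r)·x!) · (r/(r+μ))^r · (μ/(r+μ))^x, and
ZINB(x) = w₀·1[x=0] + (1−w₀)·NB(x; μ_lo, r_lo). The ZINB component absorbs
ambient background (including the cells with zero counts, which are kept as
observations); the plain NB is the expressing population. Identifiability is
maintained by constraining μ_hi > μ_lo: the expressing component is, by
definition, the one with the larger mean.

### Estimation

Maximum likelihood, in two stages:

1. **EM** over the three expanded latent components (point mass at zero with
   weight (1−π)w₀, background NB with weight (1−π)(1−w₀), expressing NB with
   weight π). The M-step is exact: the NB mean MLE is the
   responsibility-weighted mean for any r, and r then solves the weighted
   score equation by bisection on log r over [−10, 10] (weighted variance ≤
   mean caps r at e¹⁰, an effectively Poisson fit). If an M-step produces
   μ_hi ≤ μ_lo the two NB components are swapped and the weights relabelled;
   the relabelled three-component density is identical, so the
   log-likelihood is unchanged and EM monotonicity is preserved while the
   constraint always holds. Three initializations split the sorted counts at
   the 0.80/0.85/0.90 quantile and moment-match each part; the best final
   likelihood wins. Convergence: |Δℓ| < 1e−6, at most 500 iterations.
2. **Quasi-Newton polish.** The likelihood has a near-flat ridge trading the
   zero-inflation weight against a small-mean, low-size background NB; EM
   alone needs thousands of iterations to walk it. After EM, an L-BFGS-B
   step on the unconstrained reparameterisation
   (logit π, logit w₀, log μ_lo, log r_lo, log(μ_hi−μ_lo), log r_hi)
   finishes the climb. The polished point is accepted only if it improves
   the likelihood, so the recorded optimisation trace is non-decreasing end
   to end.

### Degenerate guides

Two situations yield `status = "degenerate_fallback"` with no mixture
parameters. First, fewer than `min_positive` (default 5) nonzero counts:
there is nothing to fit. Second, a BIC one-population guard: the fitted
mixture must beat a single background ZINB (3 parameters fewer) by
(3/2)·ln n in log-likelihood. Without this guard, a guide that no cell
received gets its ambient background split into two pseudo-components and
every ambient-positive cell would be called expressing; with real signal
present the margin is cleared by orders of magnitude. Fallback guides are
called by a simple count threshold (`x ≥ fallback_min_count`, default 3),
with no posterior reported.

### Calling

The posterior probability that cell c expresses the guide is

    p(x) = π·NB(x; μ_hi, r_hi) / [π·NB(x; μ_hi, r_hi) + (1−π)·ZINB(x; w₀, μ_lo, r_lo)]

computed in the log domain. A cell is called as expressing the guide iff
p > 0.5 strictly; a tie at exactly 0.5 is *not* a call.

## Assignment

Per cell, the called guide set determines one of four categories:
`unassigned` (no calls), `singlet_1ps` (one call), `singlet_2ps` (≥2 calls,
all with one target — typically both protospacers of one dual-guide vector),
`doublet` (≥2 calls spanning ≥2 targets). Congruence is judged on the target
gene, not the vector, so two same-gene protospacers from different vectors
are congruent. Singlet categories are retained for downstream analysis.
Each non-targeting vector carries its own target label in the shipped
synthetic library, so two distinct NT vectors in one cell read as a doublet;
screens that prefer to pool NT controls can simply give them one label in
the library table. Cohort summaries report category fractions over all cells
on the matrix axis, the median total guide UMIs per cell (over cells with
≥1 guide UMI, the rank-plot convention; configurable to all cells), and both
"assigned" conventions — with and without doublets — since the field uses
both.

## The synthetic cohort generator

The generator emulates the statistical structure the caller assumes, not any
particular deposited dataset. Per cell, k ~ Poisson(MOI) vectors are taken
up without replacement (default MOI 0.1, the low-MOI pooled-screen regime);
each protospacer of a received vector contributes NB(μ_hi = 100, r_hi = 5)
UMIs; every (cell, guide) pair additionally receives ZINB(w₀ = 0.7,
μ_lo = 0.5, r_lo = 1) ambient counts, i.i.d. across guides. The default
library has the dual-guide screen shape: 20 gene-targeting vectors plus 6
non-targeting pairs, 52 guides in all, with random distinct protospacers.
Ambient defaults were chosen once to produce well-separated components at
a realistic sparsity (≈30% of cell×guide pairs ambient-positive, ambient
mean well below one UMI); they are not calibrated to any specific deposited
accession.

Read-level output realizes each UMI as 1 + geometric reads (mean
`reads_per_umi`, default 3 — typical PCR duplication; the minimum is one
read) and assembles barcode and guide reads per the layout with i.i.d.
per-base substitution errors at rate ε. Output FASTQ is gzipped with a
pinned mtime so identical configurations give byte-identical files.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: pool-abundance-proportional ambient contamination
(ambient here is i.i.d. across guides), barcode-sharing artifacts between
droplet multiplets, guide-specific capture efficiency, indel sequencing
errors (substitutions only), and cell-quality covariates. End-to-end
recovery rates on synthetic cohorts are therefore an internal-consistency
check of the pipeline under its own model, not an external accuracy claim.

## Numerical choices

- All pmf arithmetic in the log domain via log-gamma; mixtures via
  log-sum-exp. Posteriors are exact pmf ratios, not thresholded heuristics.
- EM operates on the guide's distinct count values with multiplicities, so
  one iteration costs O(#distinct values), not O(#cells).
- Component weights are clamped away from exact 0/1 (1e−10) to keep the log
  domain finite; a component with vanishing responsibility keeps its
  previous parameters rather than collapsing.
- Dispersion estimates live in r ∈ [e⁻¹⁰, e¹⁰]; the upper cap is the
  Poisson-like regime for underdispersed samples.
- Problem sizes used by the validation suite and the acceptance script —
  20 cohorts of 20,000 counts for parameter recovery, a 5,000-cell cohort
  for end-to-end classification, ≈5,000 reads for extraction fidelity — were
  chosen as the smallest sizes at which the measured quantities are stable
  across seeds.

## Known limitations

- One mixture is fitted per protospacer; pooling the two protospacers of a
  vector into one fit is not implemented.
- The directional UMI collapse uses the simple absorb-into-larger rule, not
  the count-ratio (2n−1) refinement some deduplicators apply.
- The BIC one-population guard is conservative for guides with very few
  genuinely expressing cells (single-digit); such guides fall back to
  count-threshold calling rather than posterior calling.
- Extraction is substitution-aware only; indels in the protospacer or anchor
  defeat the Hamming match.
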