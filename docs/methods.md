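# Methods

## Occupancy model

A motif of width *m* is a 4×*m* probability matrix; after adding a
pseudocount *c* (default 0.01) and renormalising, p̃ = (p + c)/(1 + 4c),
it becomes a binding energy matrix in kT units. A window *S* binds with
Fermi–Dirac probability P(S) = 1/(1 + exp(E·S − μ)); total occupancy of a
sequence sums P over all windows on both strands (2·(N − m + 1) windows
for sequence length N). The model assumes independent positions (no
dinucleotide terms), strand-symmetric binding, and no interaction between
overlapping windows. In the limit μ ≪ E·S the Fermi–Dirac form reduces to
the Maxwell–Boltzmann form P ≈ exp(μ)·exp(−E·S); the `boltzmann` option
evaluates exp(−E·S) directly (clipped to 1).

`N` bases contribute the column's mean energy, so window counts do not
depend on sequence content. Probabilities are evaluated with the logistic
sigmoid, which saturates to the 0/1 limits instead of overflowing
(window energies can reach ≈ 4.6·m with the default pseudocount).

### Energy anchoring

Only E·S − μ is physical: the zero point of the energy scale and the
chemical potential are defined jointly. Both standard anchorings are
provided and the choice matters:

- **consensus** (default): every column's best base scores exactly 0 and
  mismatches are positive. The per-motif offset between this scale and an
  absolute one is absorbed into μ, which is what makes a *single shared μ
  grid* meaningful across a heterogeneous PWM collection — each motif is
  probed at the same distance from its own saturation point. The variant
  ranking pipeline uses this anchoring. Its cost: with E ≥ 0 everywhere,
  all grid potentials below about −6 operate in the Maxwell–Boltzmann
  regime, so absolute concentration information is gone.
- **background**: E = −ln(p̃/0.25), signed, with strong sites of typical
  informative motifs at −5 to −25 kT. This pins the gauge absolutely and
  is required when μ itself is estimated from occupancy data; the
  chemical-potential fit uses it. It is the wrong choice for scanning a
  mixed collection at a shared grid: at μ = 0 every real site saturates
  on both alleles while the near-zero-energy windows of weak motifs sit
  at the sigmoid's inflection, so uninformative motifs generate the
  largest score noise precisely at high concentration.

Under either anchoring the mismatch penalty between two bases in a column
is the log-ratio ln(p̃_best/p̃_other), and a uniform column scores 0 for
every base.

## Differential binding affinity and the direct-binding filter

dbA is the occupancy of the true sequence minus the mean occupancy over R
mononucleotide shuffles (position permutations, composition-preserving).
R defaults to 100: the add-one empirical P-value
p = (1 + #{shuffle occupancy ≥ true occupancy})/(R + 1) then resolves to
≈ 0.0099 granularity, adequate for the α = 0.05 filter. The P-value is
exact under exchangeability, hence super-uniform under the null by
construction. Design choices where the procedure was open:

- Shuffles are *paired* across alleles (one permutation set per variant,
  applied to both windows), which cancels most of the background term in
  δdbA = dbA(ref) − dbA(mut) and makes the allele swap an exact negation.
- A motif passes the filter when *either* allele's P-value is below α:
  motif-creating variants have no site on the reference, and would
  otherwise always be filtered away.
- Shuffling is mononucleotide, not dinucleotide-preserving.
- The weight coefficient w multiplies dbA linearly; it cancels in
  P-values and within-grid rankings and defaults to 1.
- The filter flag is evaluated per (motif, μ); a motif is retained in the
  integration matrix if it passes in at least `min_direct` grid columns
  (default 1), and the per-column flags are preserved in the output so a
  caller can apply stricter rules.

## Score integration

Retained δdbA values form the matrix D_ij = Sig[δdbA(motif_i, μ_j)] with
Sig(x) = ln(|x| + 1)·sign(x) (natural log, odd, compressive). The
integrated scores are the projections Dε where ε is the unit top
eigenvector of the *uncentered* Gram matrix DᵀD, computed via the SVD of
D. Numerical conventions: ε's global sign is fixed by requiring a
non-negative dot product with D's column-sum vector; each motif's final
sign is then sign(mean raw δdbA over the grid), with zero-mean motifs
scoring 0 and joining neither list; ties in |score| break
lexicographically by motif id. Positive score means binding is higher on
the reference allele (the variant destroys a site); a CLI flag flips the
reported labels for users who prefer "positive = creation".

The working hypothesis is that δdbA profiles across the grid are
correlated motif-to-motif — the score cloud lies near a line in μ-space —
so the most-perturbed motif is the most extreme along the first principal
axis. Exactly in that rank-1 regime, the ranking is invariant to global
rescaling of δdbA and to duplicating a grid column; for generic matrices
these hold only approximately (the Sig nonlinearity and the Gram spectrum
both react), which the tests assert as exact invariance for collinear
profiles and high rank-correlation otherwise.

Baselines for comparison: `median_delta` (signed median over the grid),
`median_rank` (per-column ranks by |δdbA|, scored by the negated median
rank, signed by the mean δdbA), and `single_mu` (one stated grid column).
All reduce to the same ordering as the PCA on a one-column grid.

Motif→TF collapse takes the best rank per TF name, case-insensitively.
The per-variant functional-mutation score is the mean of the per-motif
grid-averaged |δdbA| over the union of the top-20 positive and top-20
negative motifs (all of them when fewer exist). Cumulative accuracy at
rank r is the fraction of benchmark cases whose true TF appears at rank
≤ r, in the direction-matched list when a direction is given and in the
better of the two lists otherwise.

## Chemical-potential estimation

Given peak sequences with enrichment signals, the model
signal_k ≈ scale·occupancy(S_k; μ) + offset is fitted by profiled least
squares: for each candidate μ the optimal (scale ≥ 0, offset) is the
closed-form regression, leaving a 1-D residual profile over μ. The
profile is evaluated on a grid (step 0.25 over [−30, 0]) and refined
around the grid minimum by bounded scalar minimisation to 0.01
tolerance; if refinement fails to improve, the grid point stands. This
point estimate replaces a full Bayesian nonlinear regression — the
posterior machinery adds nothing to parameter recovery on this model,
and the residual profile is exposed in `MuFit.grid` for inspection.
Degenerate inputs are handled explicitly: occupancies constant across
all peaks at every candidate μ (e.g. a flat motif) raise an
"uninformative motif" error; constant signals fit with scale 0 and are
flagged. Constancy is detected by exact peak-to-peak comparison, since
floating-point variance of a constant vector is nonzero dust.

Identifiability requires sites whose energies bracket the probed
potentials: a site far below μ is saturated at probability 1 and one far
above contributes only an overall exp(μ) factor that the free scale
absorbs. The recovery study therefore uses a width-16, 1.9-bit/column
motif (consensus site ≈ −21 kT, background anchoring), whose
Boltzmann-sampled site energies spread across the −25…−10 range and
constrain μ throughout {−18, −12, −6}.

## Synthetic data

The generator emulates three kinds of input. (1) Random PWMs: columns
drawn from a symmetric Dirichlet whose concentration is solved (via the
closed-form expected Dirichlet entropy) so the expected per-column
information content hits a target; draws are rejected until the realised
mean is within 0.2 bits. (2) Planted variant scenarios: a 61 bp window
of i.i.d. background (GC fraction 0.5 by default, adjustable) with the
true motif's consensus site placed so its most informative column sits
at the variant position; `destroy` substitutes that base with the
column's least favourable one on the mutant allele, `create` mirrors
this, `neutral` plants nothing. The true motif has mean IC ≥ 1.5
bits/column and width 8–12; decoys are drawn independently at width 6–14
and IC 0.8–1.6, roughly the spread of curated human collections, and may
resemble the true motif by chance — the benchmark reports this rather
than preventing it. (3) Simulated ChIP peaks: 200-mers with one site per
peak sampled base-by-base from the motif's Boltzmann weights at a random
offset; signals are scale × occupancy(μ_true) plus Gaussian noise with
sd equal to a stated fraction of the mean clean signal, floored at 0.

What passing on these fixtures does *not* show about real data: flanks
are compositionally uniform (no repeats, CpG structure or GC skew), each
peak carries exactly one site, signals are linear in occupancy with
homoscedastic noise, and decoy motifs are independent of the true one —
all optimistic relative to genomes and real ChIP enrichments. The
planted benchmark measures the pipeline's discrimination machinery, not
genome-scale specificity.

## Pipeline engineering

Variants come from VCF (via pysam; multi-allelic records expand, non-SNVs
are skipped and counted) or TSV; windows of 2·flank + 1 bases (61 bp
default) are cut from an indexed FASTA with 0-based half-open coordinates
internally and 1-based coordinates in all interfaces. A genome/REF
disagreement is flagged and the genome base wins; windows truncate at
chromosome ends with a warning. Each variant's shuffle seed is the global
seed plus a CRC-32 of its id (mod 2³¹), so results are bit-identical
across input orderings and worker counts; per-variant failures are
recorded in the summary without stopping the batch. Window energies are
computed once per (motif, allele) for the whole shuffle stack and reused
across the μ grid, which is what keeps the 200-motif × 6-μ × 101-sequence
scan at ~0.5 s per variant.

## Study sizes used by the tests and acceptance script

Planted benchmark: 50 destroy cases, 1 true + 199 decoys, R = 100, full
six-potential grid (the package's desk-scale benchmark). Null
calibration: 200 replicates at R = 100. Potential recovery: 20 seeds per
true μ at 200 peaks, 10% noise. Oracle comparisons: 20 random instances
each. These sizes give binomial/median estimates tight enough for the
documented thresholds while keeping a full run in tens of seconds.

## Known limitations

Only SNVs (no indels, MNVs or haplotypes); independent-position energy
model; mononucleotide shuffle null; the direct-binding filter's α is not
multiplicity-adjusted across motifs; chemical-potential estimates are
point estimates with no uncertainty interval; TF-name collapse trusts
the names in the PWM headers.
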