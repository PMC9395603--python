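# Methods

## Scope and model

`cubkit` treats a cohort of protein-coding DNA sequences as draws from a
codon-level process in which three forces shape synonymous codon choice:
background mutational pressure (captured by third-position composition,
which is nearly free of amino-acid constraint), compositional/GC constraint
(captured by first+second-position composition and by GC3 regressions), and
translational selection (captured by CAI, P2 and the preference structure of
the RSCU matrix). None of the statistics requires an alignment or a
phylogeny; genes are treated as independent observations.

## Qualification criteria

A sequence qualifies when its length is a triplet multiple and at least
150 nt, it contains only A/C/G/T (IUPAC degenerate codes fail rather than
being resolved), and no stop codon occurs before the final position. A final
stop codon is permitted and excluded from all codon statistics, so
composition, RSCU, SCS, CAI, P2 and the dinucleotide ratios all operate on
the identical amino-acid-coding codon set. All thresholds are configurable
(`min_len`, RSCU and odds-ratio class boundaries) but default to the values
above.

## Per-gene statistics

* **RSCU.** rscu(c) = n_c / (n_F / d_F) within each synonymous family F of
  degeneracy d_F. Families never observed in a gene yield missing values,
  not zeros, and are excluded pairwise from correlations (they are set to 0
  in correspondence analysis, where a missing profile entry and a zero
  contribution coincide). Classification: over-represented strictly above
  1.6, under-represented strictly below 0.6; boundary values are "random".
* **Scaled chi-square.** Summed family χ² against equal usage divided by N.
  N defaults to the codons of multi-codon families — the same codons whose
  χ² values are summed — with a `denominator="peptide"` toggle that divides
  by all counted codons instead. The two differ only through Met/Trp
  content.
* **CAI.** Geometric mean of w over informative codons (Met, Trp, stops are
  uninformative and ignored). w is within-family frequency over the family
  maximum in the reference set; a reference codon with zero frequency
  receives the floor 0.5/(family maximum) so log w stays finite. The
  embedded human reference table carries frequencies per thousand; since w
  and reference RSCU are within-family ratios, frequencies and raw counts
  give identical weights.
* **P2.** Codons are classified on the mRNA alphabet into WWC, SSU, WWY, SSY
  (W=A/U, S=C/G, Y=C/U; positions 1,2 determine W/S, position 3 the C/U
  class) and P2 = (WWC+SSU)/(WWY+SSY). The numerator classes are subsets of
  the denominator classes, so per-gene P2 ≤ 1 by construction. Cohort-level
  P2 is reported three ways — per-gene values, their mean, and the
  pooled-count ratio — because aggregation conventions differ between
  tools and the variants need not agree.
* **Dinucleotide odds ratios.** Counted over all overlapping positions of
  the stop-trimmed CDS, spanning codon boundaries: the CpG/TpA depletion
  processes of interest (methylation-deamination, RNase targeting) act on
  the nucleotide sequence, not on within-codon pairs. ρ is missing when a
  mononucleotide frequency is zero.
* **Protein indices.** GRAVY, AROMA, the instability index and pI use the
  published Kyte–Doolittle, Guruprasad DIWV and Bjellqvist-style pKa tables
  as implemented in Biopython's ProtParam (pinned by the worked-example
  tests: GRAVY("GGGG") = −0.4, II("AA") = 5.0, pI("G") = 5.525). The
  aliphatic index is Ikai's 100·(X_A + 2.9·X_V + 3.9·(X_I + X_L)). The
  residue partition for the class fractions is not standardized across web
  tools, so it is configurable; defaults: acidic {D,E}, basic {K,R,H},
  neutral the rest, hydrophobic {A,V,L,I,M,F,W,C}.

## Cohort analyses

All composition variables are kept on the 0–100 percent scale; the
neutrality slope is scale-free only when both axes share a scale, and that
invariance is asserted by test. Regressions are ordinary least squares
(two-sided t-test p-values); correlations are Pearson with pairwise
deletion of missing values and raw-p significance stars (no multiple-testing
correction by default — Benjamini–Hochberg can be applied downstream — since
the star convention is reported alongside exact p-values).

Correspondence analysis is the plain χ²-metric SVD of the genes × 59 RSCU
matrix: standardized residuals S = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}, principal
coordinates from the SVD of S, axis inertias = squared singular values.
Axes below 1e-12 singular value (including the trivial dimension) are
dropped. A within-amino-acid variant was considered and not adopted: the
plain variant is the common default of codon-usage tools and keeps the
inertia decomposition interpretable against the full matrix.

Codon clustering uses correlation distance (1 − Pearson r between codon RSCU
profiles) with average linkage; both are configurable. Constant codon
columns have undefined correlation to everything and are dropped with a
warning. The merge tree is exported as Newick with non-negative branch
lengths derived from merge heights.

## Synthetic data

The generator emulates the endpoint composition of a real gene panel, not
evolutionary dynamics. Genes start with ATG, end with a stop, contain no
internal stops, and draw internal codons from the 18 multi-codon amino
acids. Controls:

* **GC3**: third-position class (GC-ending vs AT-ending synonymous codon) is
  a Bernoulli(target) coin; every multi-codon family contains both classes,
  so the expected GC3 equals the target exactly.
* **GC12**: when a GC12 target is set, amino-acid sampling weights are
  exponentially tilted (weights ∝ exp(λ·e_a), with e_a the family-mean
  first+second-position GC fraction; λ solved by bisection) so the expected
  per-codon prefix GC equals the target. By the A↔G/T↔C third-position
  symmetry of the code, e_a does not depend on the GC3 coin, so the two
  controls do not interfere.
* **family bias**: an explicit probability vector per family overrides the
  coin (e.g. all-CTG leucine gives RSCU(CTG)=6 by construction).
* **dinucleotide depletion**: when appending a codon, each newly introduced
  dinucleotide (junction + two internal) that is listed in the depletion map
  survives a retention coin; the codon is resampled on failure, bounded at
  100 retries.

Cohorts draw per-gene GC3 uniformly from a range (default 0.30–0.87,
matching the spread observed in human gene panels) and set the GC12 target
to slope·GC3 + intercept + Gaussian noise (defaults: 47 genes, slope 0.25,
intercept 30, sd 2 percent units, lengths 100–600 codons — desk-scale
stand-ins for genes of 150–15,000 nt). Every operation is a pure function
of its spec's seed.

What the generator does **not** emulate: real amino-acid composition
(uniform over the 18 multi-codon residues by default; a biased vector can
be supplied via `family_bias` plus tilting), isochore structure, splice/UTR
context, and any correlation between CAI and expression. Passing tests
therefore demonstrate that the statistics and regressions are computed
correctly and recover planted structure — not that any biological
conclusion about a real gene panel is reproduced.

## Numerical choices and degenerate inputs

* Undefined ratios (zero denominators: skews, parity axes, P2, odds ratios,
  unobserved RSCU families) are NaN and propagate as missing, never coerced
  to 0; the pipeline logs a warning rather than failing.
* Realized GC12 carries codon-sampling noise of order
  sqrt(0.125/L)·100 percent points for an L-codon gene; with zero planted
  noise the neutrality r² approaches 1 only as genes lengthen, which is why
  the zero-noise recovery test uses 1500–2000-codon genes.
* Classification boundaries (RSCU 0.6/1.6, odds 0.78/1.23) use strict
  inequalities; boundary values classify as "random".
* Constant predictors raise errors in regressions; zero-variance variables
  in the correlation battery yield flagged NaN results instead, so one
  degenerate column cannot abort a cohort report.
* Cumulative skew profiles use non-overlapping 30-nt windows by default; a
  window with zero denominator contributes 0 to the running sum so the
  profile stays defined.

## Problem sizes

The test suite and the acceptance script run the pipeline on synthetic
cohorts of 47 genes (the design case) and parameter-recovery simulations at
n = 100–200 genes, 200 replicates for odds-ratio calibration at 5 kb per
replicate — sizes chosen so the statistical tolerances (3·SE binomial
bounds, OLS standard-error bounds) are meaningful while the whole suite
completes in well under a minute per module.

## Known limitations

* Cohort-level P2 printed by some legacy tools can exceed 1, which the
  per-gene formula cannot produce; this package reports the three defined
  variants and leaves reconciliation with legacy output to the user.
* The pI model is the standard Henderson–Hasselbalch composition model;
  structure-dependent pKa shifts are out of scope.
* `fetch` extracts the longest annotated CDS of a RefSeqGene record; other
  transcript choices will change downstream numbers, and no claim is made
  that this matches any particular published panel's transcript selection.
* Cumulative skew profiles are provided for diagnostics only; origin-of-
  replication scans are out of scope.
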