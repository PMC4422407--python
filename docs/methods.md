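# Methods

## The conservation index

For a motif *m* and a set of genomes *G* with human as the reference, the
conservation index of *m*'s phosphosites is

    CI(m) = Σ_{q ∈ G} (C_q − R_q)

- **C_q** — the number of *m*'s human sites whose motif window is
  conserved in genome *q*, divided by the number of *m*'s human sites.
  A window is conserved when, for **some** ortholog of the protein in
  *q*, the residues in the alignment columns of the human window are all
  non-gap and satisfy the motif's residue sets position by position
  (wildcards accept any non-gap residue).
- **R_q** — the background conservation of the acceptor residue type:
  the fraction of S/T/Y residues across the phosphoprotein set whose
  aligned residue in *q* is the identical amino acid (the same gap and
  missing-ortholog rules as C).  For motifs whose acceptor can be S or T,
  the motif-level R_q is the count-weighted mixture over the motif's
  actual acceptor composition.

The reference genome has C = R = 1 and contributes exactly zero, so with
nine study genomes CI ∈ [−8, +8].  Known sites are curated phosphosites;
potential sites are all S/T/Y residues of the same proteins, matched
against the motif the same way.

## Conventions and analysis decisions

Positions are 1-based on ungapped sequences; alignment columns 1-based;
the only gap character is `-` (`.` is normalised on read).  Decisions
where the analysis admits more than one defensible reading, with the
choice made here:

1. **Denominator** (`denominator=all`, default): every motif-matching
   human site stays in every genome's denominator; a missing ortholog
   counts as not conserved.  The same rule applies to R, so the missing-
   ortholog penalty largely cancels inside C − R.  `aligned_only`
   instead drops a site from genome *q*'s denominator when *q* has no
   ortholog.
2. **Conservation call** (`rematch=strict_columns`, default): the
   ortholog must satisfy the motif at the human window's columns; any
   gap ⇒ not conserved.  `degapped_window` re-matches the motif against
   the ortholog's degapped sequence anchored at the residue aligned to
   the human acceptor, recovering motifs shifted by within-window
   indels.
3. **Motif-level R** is the acceptor-composition-weighted mixture of
   per-residue-type background rates.
4. **Paralogs**: a genome with several members in a family is conserved
   if ANY member matches; several human members of one cluster are
   scored as separate (protein, site) records.
5. **Cluster choice**: a human protein in several ortholog clusters uses
   the cluster covering the most genomes, ties broken by lexicographic
   cluster id (logged).
6. **Arithmetic**: rates are ratios of integer counts; the only floating
   arithmetic is the final mixture and sum.  Output TSVs round to 6
   significant digits.
7. **Potential sites** use full-motif matching, symmetric with known
   sites.
8. **Kinase fractions** count kinase-substrate *edges* (site-level
   pairs), not distinct kinases — substrate totals in the thousands are
   only reachable by edge counting; a `proteins` unit is available.
9. **Enrichment** uses the hypergeometric upper tail with
   Benjamini–Hochberg adjustment (in place of resampling-based FDR);
   significance requires both p < 0.01 and FDR < 0.01.
10. **Network null** preserves the motif-set *size* only (uniform node
    resampling), since the claim under test is against randomly selected
    proteins; a degree-weighted switch exists but is off by default.
11. **Comparison** uses the Pearson correlation of raw CI pairs.

## The synthetic study generator

The generator emulates the study's inputs — ortholog clusters over the
nine genomes, one alignment per cluster, known/potential site labels —
with planted, closed-form truth:

- Human sequences are uniform over the 20 amino acids; lengths uniform
  in a configured range (defaults 200–400; calibration runs use 300–500,
  near real proteome scale).
- Motif windows are planted at a configured per-protein rate; each
  planted acceptor is labelled `known` with probability `known_rate`,
  all other S/T/Y residues are `potential`.
- Each non-human ortholog retains every position independently with the
  background probability `p_bg(q)` (else substitutes a uniformly chosen
  different residue — the pipeline only distinguishes match/mismatch
  against residue sets, so a substitution matrix would add nothing
  testable).  Each planted window is conserved as **one Bernoulli
  event** with probability `p_mot(q)` (per-class: known vs potential):
  on success the constrained window positions are copied verbatim; on
  failure the acceptor becomes a non-S/T/Y residue, which guarantees
  both a motif mismatch and an acceptor mismatch.  Wildcard positions
  always follow the background process.
- Ortholog loss removes a genome from a family with probability
  `loss_prob(q)`; insertions (when enabled) add residue blocks to single
  genomes strictly outside planted windows, exercising column mapping
  without touching truth.

Under this model C_q = (1 − loss_q)·p_mot(q) exactly.  The background is
a mixture: plain S/T/Y conserve at p_bg, planted acceptors at p_mot, and
S/T/Y at constrained non-acceptor window positions at
p_mot + (1 − p_mot)·p_bg.  `SimTruth` therefore computes the **exact**
expected CI in closed form from the realised sequence composition; at
sparse planting (one or two sites per ~400-residue protein) the mixture
correction is below 0.12 CI units and the ideal limit
Σ_q (1 − loss_q)(p_mot − p_bg) is also reported.  When p_mot = p_bg the
mixture collapses and the expected CI is exactly zero.  The reported CI
standard error sums per-genome binomial variances of C and R and ignores
their positive covariance, so 3-SE bands err conservative.

What the generator does **not** emulate: phylogenetic correlation along
a tree (genomes evolve independently), realistic amino-acid composition,
alignment errors, and detection bias in phosphosite curation.  Passing
calibration therefore shows the estimator machinery is correct and
well-calibrated under the stated sampling model, not that real
phosphoproteome inputs are free of those confounders.

## Problem sizes and numerics

Calibration analyses use 1000 planted sites (500 families × 2 sites)
for the null and planted-effect checks, 50 independent 40-family studies
for the known-vs-potential comparison, 40 single-motif studies for
CI-rank structure, 3671 multinomial edges for kinase-fraction recovery,
200 replicates for enrichment type-I calibration, and 999 permutations
for the network statistic — sizes at which binomial tolerances are a few
percent while the whole chain remains quick on one CPU.  Empty site
sets raise an error rather than yielding silent 0/0 rates; a residue
type with no background sites marks its R unavailable and any CI that
needs it fails loudly.  Permutation p-values use the add-one estimator
(1 + #{null ≥ obs}) / (1 + n_perm), so the minimum attainable p is
1/(1+n_perm) and saturated sets give exactly 1.

## Limitations

Conservation is scored through precomputed alignments and inherits their
errors; there is no tree-aware weighting, so the nine per-genome terms
are summed as exchangeable.  The strict-column call misses motifs
displaced by within-window indels unless `degapped_window` is enabled.
Kinase-group substrate CIs use acceptor-residue-only matching, as the
pooled substrates of a kinase group do not share one motif window.
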