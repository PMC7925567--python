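# Methods

## Overview

`evpair` estimates whether two proteins interact, and through which
residues, from the statistics of a species-paired (concatenated)
multiple sequence alignment. The chain is: monomer-alignment
eligibility → species pairing → concatenation quality control → Potts
model inference by pseudo-likelihood maximization (PLM) → gauge-fixed,
APC-corrected coupling scores → logistic interaction models → optional
structure comparison and docking-restraint export.

## Alignment statistics

**Pairwise identity.** Matches divided by the number of columns where
*both* sequences are non-gap. This symmetric definition is used
everywhere identity appears: sequence reweighting, query-paralog
exclusion, and ortholog pairing. (An asymmetric, query-coverage-based
definition would make the reciprocity check order-dependent.)

**Sequence weights and N_eff.** Each sequence gets weight
1/(number of alignment members at ≥ θ identity, itself included),
θ = 0.8 by default; N_eff is the sum of weights. Weights are computed
on the concatenated alignment (after the row gap filter), since the
diversity that matters for inference is that of the paired rows.

**Column statistics.** Gap fractions use unweighted counts. Column
conservation is one minus the normalized entropy of the amino-acid
frequencies, C = 1 − H/log₂20 with H = −Σₖ fₖ log₂ fₖ over the 20
canonical residues; gap and nonstandard-letter mass is excluded and the
frequencies renormalized, because the entropy scale is defined on the
amino-acid simplex. All-gap columns return NaN rather than raising, so
downstream feature rows can drop them.

**Eligibility.** A monomer alignment enters the analysis only if at
least 80% of its columns have under 50% gaps and N_eff/L ≥ 2.5 (both
boundaries inclusive). Among candidate alignments built at several
search stringencies, the coverage-passing one with the largest N_eff is
selected. Rows that are themselves more than 50% gaps are removed
before coupling inference; the query row is always kept.

## Species pairing

Species tags are parsed from UniProt-style headers (mnemonic after the
final underscore, else OX=/OS= fields). For each species present in
both monomer alignments, the member with the highest identity to each
query is the candidate ortholog (ties break to the lowest row index).
Query-genome paralogs above 90% identity to the query are removed from
consideration outright; a candidate is accepted only if it is closer to
the query than to every *remaining* query-genome paralog, in both
alignments ("reciprocal highest identity"). The two query sequences
always form row 0 of the concatenation. Comparing candidates against
the distant (<90%) paralogs, rather than the excluded near-duplicates,
is the reading that makes the guard informative: a near-duplicate of
the query would approve almost any candidate the query itself approves.

## Concatenation quality control

Five guards, all reported, none silently skipped:

- column coverage ≥ 80% (as above) on the concatenated alignment;
- N_eff/L ≥ 0.2;
- no shared domain-family identifier between the two proteins
  (externally supplied annotation lists; no live database queries);
- no overlapping structure hit (same chain of the same structure, again
  externally supplied);
- no diagonal coevolution artifact: the pair is flagged when at least
  half of the top-10 inter-protein ECs sit within |posᴬ − posᴮ| ≤ 2 in
  segment-local coordinates — the signature of homologous, rather than
  interacting, proteins (band and fraction are config-exposed; the
  default band suits protein-scale segments and will over-trigger on
  toy segments shorter than ~15 columns);
- no nonstandard amino acid (outside the canonical 20) in either query
  sequence.

## Potts inference

The alignment is modeled as a pairwise Markov random field over q
states per column (21 = 20 aa + gap for protein data; the synthetic
alphabet omits the gap). The joint likelihood is replaced by the
product of per-site conditionals (pseudo-likelihood); one symmetric
coupling matrix J_ij is shared between the site-i and site-j
conditionals, rather than fitting asymmetric halves and averaging.
The objective is the weighted negative log pseudo-likelihood plus
λ_h‖h‖² + λ_J Σ_{i<j} ‖J_ij‖²_F with λ_J = λ_base(q−1)(L−1); the
scaling keeps the per-pair penalty commensurate with the number of
coupling parameters as L and q change.

Numerical choices: λ_h = 0.01 and λ_base = 0.01 (common PLM practice;
config-exposed), L-BFGS from zero initialization (deterministic — no
RNG anywhere in the fit), stopping when the maximum gradient component
falls below 1e-4 × total sequence weight, iteration cap 500. Hitting
the cap with a large residual gradient raises a convergence error
carrying the final gradient norm.

**Scores.** Each J_ij is gauge-fixed to the zero-sum gauge over the
amino-acid states (the gap state carries alignment geometry, not
structural contact information, and is excluded); its Frobenius norm is
the raw pair score. The average product correction removes the
rank-one background: cn_ij = s_ij − s̄ᵢ s̄ⱼ / s̄, means over off-diagonal
entries. Intra-segment pairs with |i − j| ≤ 5 are dropped (local
backbone correlations, not contacts); cross-segment pairs are never
distance-excluded. Ties in CN rank by (i, j) ascending so tables are
reproducible byte for byte.

**Inter-EC transforms.** Z-scores are computed against the
distribution of all inter-protein ECs (population SD; zero spread
yields NaN). The EVcomplex raw score divides each inter EC by the
magnitude of the most negative inter EC, pinning that minimum at −1 and
making the score invariant to uniform rescaling. The diversity
normalization g(N_eff/L) multiplying the raw score is not fully
specified by its originating work; this implementation uses
g(x) = min(1, √x) — deep alignments keep their raw score, shallow ones
are shrunk toward zero — and records the factor in the table metadata.

## Interaction models

**Residue-contact model.** The top ten inter-protein ECs per pair are
featurized: EVcomplex score; conservation of the more conserved
residue; relative rank of the EC among all (intra + inter) ECs,
(strictly-better count + 1)/total; and the maximum over the two
residues of the intra-EC enrichment (per-residue sum of CN over the
top-L intra rows, normalized by the mean of that sum over the residues
those rows touch; untouched residues get 0). The structure-aware
variant adds the minimum relative solvent accessibility of the pair and
the precision of higher-ranked intra ECs with known distances. Labels
are minimum-atom distance < 8 Å; pairs unresolved in every structure
are excluded. Training uses L1-penalized logistic regression
(liblinear), regularization weight 0.05 interpreted as scikit-learn's
C, with 10-fold cross-validated precision/recall recorded. When a pair
has fewer than ten inter rows, zero-filled rows flagged `padded = 1`
complete the block.

**Protein-interaction model.** Eleven inputs: the ten residue-contact
probabilities (CN-rank order) and the relative rank of the best inter
EC. Classes are balanced by seeded sampling without replacement; a
first L1 stage (C = 0.1) drops zero-weight features, a second L2 stage
refits the survivors. Thresholds are calibrated by exhaustive scan over
observed score cuts to a precision or false-positive-rate target; the
returned threshold is the midpoint between the chosen cut and the next
score below it, and unattainable targets are flagged with the best
achievable value rather than guessed.

## Structure comparison

Distances are minimum heavy-atom distances per residue pair, minimized
across all supplied structures (an interface resolved anywhere counts);
residues unresolved everywhere stay missing and are excluded from both
numerator and denominator of EC precision. The alignment-to-structure
mapping is an explicit TSV input (alignment position, chain, residue
number, insertion code). Solvent accessibility is computed directly by
Shrake–Rupley sphere sampling: 960 points per atom on a deterministic
golden-spiral lattice (no RNG), probe 1.4 Å, standard van der Waals
radii (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å; unknown elements fall
back to carbon with a warning), hydrogens ignored. Relative
accessibility divides by theoretical per-residue maxima; profiles from
several structures are averaged per residue to dampen incomplete
models. An adapter reads precomputed DSSP tables for parity checks.

**Restraints.** The union of the top-5 inter pairs under each scoring
mode is exported as unambiguous distance restraints on Cβ (Cα for
glycine) with effective distance 5 Å and symmetric 2 Å bounds, in the
`assign (segid … and resid … and name …)` table dialect used by
restraint-driven docking.

## Synthetic data

The generators produce every input the pipeline consumes, with truth
attached and bit-reproducible under a fixed seed:

- **Planted Potts models**: Gaussian fields (σ = 0.3); each planted
  pair receives a rank-one ±strength coupling block (outer product of
  random sign vectors), so its pre-gauge Frobenius norm is exactly
  strength × q. Intra pairs respect the |i−j| > 5 exclusion band and
  inter pairs avoid the homology diagonal, so planted signal is never
  filtered out by construction. Default strength 1.0 with q = 8 gives
  strongly detectable couplings at n = 2000 sequences.
- **Gibbs sampling**: parallel chains (default 100) of single-site
  sweeps, 500-sweep burn-in, one sample per chain every 10 sweeps —
  generous settings because residual autocorrelation inflates apparent
  N_eff.
- **Species fixtures**: per species, orthologs are bounded mutations of
  the queries (divergence uniform on 5–50%, a realistic ortholog
  identity spread); decoy paralogs diverge at least a further 30% from
  the ortholog, so the true ortholog always has the highest identity to
  the query.
- **Feature tables**: two spherical Gaussian classes separated by d
  along one axis; the Bayes-optimal AUC is Φ(d/√2) in closed form.

What the synthetic data does *not* emulate: phylogenetic correlation
between sequences (every chain is independent), indels beyond the gap
states the Potts model itself emits, heterogeneous per-site
conservation of real families, and alignment errors. Passing the
planted-recovery tests therefore demonstrates the correctness of the
inference machinery, not field performance on real proteomes — the
published benchmark figures require UniProt-scale homology searches and
thousands of experimental structures that this package deliberately
does not download.

## Problem sizes

The planted-recovery check runs at L₁ = L₂ = 30, q = 8, 30 intra + 10
inter planted couplings, 2000 sampled sequences; pairing recovery at 20
species with 2 decoy paralogs each; classifier recovery at n = 5000
(weights) and 1600/3000 train/test rows (AUC); pipeline determinism at
L₁ = L₂ = 16, 300 sequences. These sizes make the whole suite run in a
few minutes while leaving all detection margins wide.

## Known limitations

- The PLM is dense (L² coupling blocks in memory); alignments beyond a
  few hundred concatenated columns need more memory and time than the
  vectorized NumPy implementation is tuned for.
- The diversity normalization g and the padding rule for sparse inter
  rows are package choices where the method family leaves the exact
  form open; both are config-exposed and recorded in outputs.
- Shipped logistic models are not included: the residue and interaction
  models must be trained on the user's own labeled benchmark before
  scoring, and the 80%-precision residue threshold must be recalibrated
  per dataset.
- Species pairing assumes one ortholog pair per species; gene fusions,
  horizontal transfer and lineage-specific duplications violate this.
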