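# Methods

## Overview

`plastmark` screens a plastid-genome multiple alignment for barcoding
markers and scores them by how well they delimit species. The pipeline is:

1. **SNP-density scan** — call variant columns, bin them into fixed-width
   windows (default 800 bp), classify windows by variability.
2. **Marker proposal** — merge runs of variable windows into candidate
   regions; named regions may also be supplied by the user.
3. **Tree building** — distance-based neighbor joining with optional
   bootstrap, or import of externally built (e.g. ML) trees via Newick.
4. **Species delimitation** — single- or multi-rate Poisson tree processes
   (PTP/mPTP) on the rooted tree: ML delimitation with a likelihood ratio
   test, plus MCMC per-node supports and the Average Support Value (ASV).
5. **Marker scoring** — percent variable sites and the fraction of species
   whose accessions are recovered exactly as one delimited entity, per
   marker and per concatenated marker combination.

A two-regime simulator generates alignments with known species structure so
every stage is testable end to end without external data.

## The PTP delimitation model

A *delimitation* of a rooted tree is a set of species roots: pairwise
non-ancestral nodes whose subtrees cover all tips. Classify every edge by
its parent node: edges whose parent lies strictly above all species roots
(including each species root's own stem) form the **speciation** class;
edges strictly inside a species root's subtree form that species'
**coalescent** class. A species sampled once contributes no coalescent
edges — only its stem, to the speciation class.

Branch lengths within a class are modelled i.i.d. Exponential. For a class
with `n` branches of total length `s` the profile log-likelihood at the MLE
rate `λ = n/s` is `n·ln(n/s) − n`; empty classes contribute zero. The
`single` model pools all coalescent classes into one rate; the `multi`
model (mPTP) gives each species its own coalescent rate. The null model
puts every branch in one class, giving `null_loglik = n·ln(n/Σb) − n`.

Branches shorter than `MIN_BRANCH_LENGTH = 1e-9` substitutions/site are
excluded from all likelihoods: they carry no rate information and would
otherwise force infinite rate estimates.

### State space and ML search

Delimitations correspond one-to-one with ancestor-closed sets `S` of
internal "speciation nodes" (`S` empty = one species; otherwise `S`
contains the root and the species roots are the nodes just below `S`).
Valid moves toggle one node: merging a species into its parent entity or
splitting an entity at a node.

The ML search is a best-improvement hill climb over these toggles, run
from the one-species state, the fully split state, and each root-to-node
path state, with an escape repair that re-climbs from every one-toggle
neighbor of a local optimum (and every two-toggle neighbor on trees with
at most 24 internal nodes, where this is cheap). Per-species coalescent
statistics are per-node constants, so each candidate move is evaluated in
O(1). An exhaustive enumeration over all antichain covers
(`brute_force_ml`, bounded at 12 tips) is the correctness oracle; the
suite verifies exact agreement of partition and log-likelihood on hundreds
of random mixed-regime trees.

Ties are always broken toward fewer entities (conservative lumping).

### Likelihood ratio test

The alternative's log-likelihood is a maximum over the whole delimitation
lattice, so a χ² reference for `2Δll` is badly anti-conservative — under
simulated one-rate nulls it rejected far more than the nominal α. The test
therefore uses an exact Monte-Carlo null: under H0 the measurable branch
lengths are i.i.d. Exponential, and log-likelihood *differences* are
invariant to rescaling, so the null distribution of the statistic depends
only on the topology (and the pattern of measurable edges). We redraw
those lengths from Exp(1) `B = 199` times, recompute the statistic with
the same cheap two-start climb used on the observed tree, and report
`p = (1 + #exceedances)/(B + 1)`, stopping early once rejection at α is
impossible. Measured on 200 simulated null trees this gives a 0.5–1%
rejection rate at α = 0.01 for both models. The classical
degrees-of-freedom count (free rate parameters minus one, over non-empty
classes) is still reported for reference.

### MCMC supports and ASV

A Metropolis sampler walks the same toggle move set under a uniform prior:
pick a uniformly random internal node, toggle it if valid, accept with
`min(1, exp(Δll))`. Two chains are run by default; 10% of each chain is
discarded as burn-in and samples are pooled. A node's support is the
fraction of samples in which it is a species root; the ASV is the mean
support of the ML delimitation's species roots. On 4-tip trees, where the
state space is enumerable, the sampler's post-burn-in frequencies match
the likelihood-weighted distribution (χ² checked in the suite). A
between-chain support correlation is reported as a light convergence
diagnostic; no formal diagnostic is applied.

## Trees

The built-in engine is classical neighbor joining on p- or JC69 distances
with pairwise deletion of gap/ambiguous sites (`d = −(3/4)ln(1 − 4p/3)`;
p ≥ 3/4 raises a saturation error). NJ is exact on additive matrices,
which the suite exploits as an oracle via path-length matrices of random
trees. Determinism: Q-matrix ties are broken by cluster representative
labels; negative branch estimates are clamped to zero with the deficit
moved to the sister branch, preserving the joined pair's path length.
Bootstrap supports are bipartition frequencies over column-resampled
replicates, seeded.

Rooting uses a declared outgroup when available (the outgroup is then
pruned before delimitation, since its long stem would otherwise dominate
the speciation class); otherwise midpoint rooting. Midpoint rooting is
implemented directly (longest leaf pair, then the edge containing the
half-way point) because it must tolerate the many zero-length branches
typical of low-divergence marker trees.

## SNP scan and window classes

A column is a SNP iff at least two distinct unambiguous bases (A/C/G/T)
occur in it; gaps, N and IUPAC ambiguity codes are never states. This is
the conservative reading; counts on gappy alignments would differ if gaps
counted as states. Windows tile `[1, L]` with a final partial window that
is counted like any other (not length-normalized — a documented caveat
affecting only the last window). Each window's count is converted to a
z-score against the mean and sample (n−1) SD of all window counts, and
classed `low` (z < 1, including negative), `moderate` (1 ≤ z < 2) or
`high` (z ≥ 2); if the SD is zero all windows are `low`. Classes are
invariant to adding a constant to all counts.

Marker proposal merges maximal runs of windows at or above a class
threshold (default `moderate`), bridging up to `merge_gap = 1` cold
window, because real intergenic markers (~2–4 kb) span several 800 bp
bins. Auto regions are named `R<start>-<end>`; gene-anchored names come
only from user tables, as annotation lift-over is out of scope.

## Marker scoring

A species counts as *identified* when one delimited entity equals its
accession set exactly (monophyletic and exclusive). A looser `not_split`
criterion (all accessions in one entity, lumping tolerated) is available
behind a flag. A marker alignment with no measurable divergence is
reported directly as a single entity (0 species identified, p = 1) rather
than an error: zero intraspecific *and* interspecific variation gives the
two-class model nothing to contrast.

## The simulator

`simulate_tree` draws a random join (Yule-type) topology over species and
a random join topology within each species, then assigns every edge an
Exponential length: `Exp(λ_sp)` for speciation-regime edges (down to and
including each species MRCA's stem), `Exp(λ_coal)` inside species. This is
exactly the generative assumption of the PTP likelihood, which makes
parameter recovery well-posed: on 10-species × 4-accession trees the
estimated coalescent/speciation rate ratio is within a factor of two of
truth (median over replicates).

Defaults (λ_sp = 50, λ_coal = 2500 per substitutions/site) put speciation
edges at 0.02 expected substitutions/site and within-species edges at
0.0004 — the shallow interspecific and very low intraspecific divergence
regime of congeneric plastomes, with the rate ratio of 50 that defines the
"easy" study condition.

`simulate_alignment` evolves sites independently under Jukes–Cantor from a
uniform root sequence; hotspot intervals multiply the per-site rate,
producing the SNP-dense windows the scanner is meant to find. Named
profiles fix the study conditions:

- **easy** — 5 species × 4 accessions, rate ratio 50, L = 20 kb, one ×20
  hotspot at columns 8001–8800.
- **hard** — 6 species × 3 accessions, rate ratio 5, two forced sister
  pairs whose stems are drawn at coalescent scale (barely diverged
  species).
- **null** — 20 accessions, one species, a single rate everywhere.

The marker-discrimination study uses 6 species × 3 accessions, L = 8 kb,
base rate 0.15 and a ×20 hotspot, so the cold comparison marker is
genuinely information-poor while the hotspot marker is strong.

What the simulator does **not** emulate: indels and alignment gaps (gap
handling is exercised by hand-built fixtures instead), among-site rate
variation beyond hotspots, base-composition bias, the inverted-repeat
structure of real plastomes, and sequencing/assembly error. Passing the
simulation studies therefore shows the statistical machinery is correct
under its own model, not that real plastome alignments satisfy that model.

## Problem sizes and numerical choices

Studies run at desk scale: 200 trees of ≤ 12 tips for the oracle check,
50 easy-profile and 100 null-profile replicates for recovery/type-I, 20
seeds for the marker study, 50,000 MCMC steps (thinned ×25 for the χ²
comparison, which mitigates autocorrelation) for sampler validation.
Likelihood tie tolerance is 1e-10 with ties resolved toward fewer
entities; all randomness flows through seeded `numpy` generators, and
every reported quantity is bit-reproducible given the seed.

## Known limitations

- The LRT's Monte-Carlo reference uses a cheap two-start climb as its
  statistic; with `B = 199` the smallest attainable p-value is 0.005.
- PTP-style delimitation needs intraspecific variation; markers with none
  are honestly reported as undelimitable (single entity), which is also
  the behavior seen on real low-variation markers.
- Midpoint rooting can misplace the root when divergence is very
  asymmetric; supplying an outgroup is preferred.
- NJ branch-length noise on short markers occasionally yields
  LRT-supported oversplitting of one species — the same artifact reported
  for over-represented species in real plastome delimitations.
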