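# Methods

This note documents the models, conventions and numerical choices behind
`degenphy`, in the spirit of the methods documentation of simulation and
statistics packages: what is computed, under which assumptions, and where
the genuinely open design choices were resolved.

## degen1 recoding

The degeneration table is built from the genetic code (NCBI translation
tables via Biopython) as the connected components of the *synonymy graph*:
vertices are the sense codons, edges join codons that differ at one
position and encode the same amino acid.  Each component's image is the
position-wise IUPAC union of its members.  This construction yields exactly
the published scheme for the standard code: one component per amino acid,
except serine, which splits into TCN (Ser1) and AGY (Ser2) because no
single-step synonymous path connects the two codon boxes.  Because the
union is taken position-wise, the Leu image YTN also resolves to Phe and
the Arg image MGN also resolves to Ser2 — the deliberate price of full
synonymous degeneracy at first positions.

Conventions:

- **Stop codons** default to `NNN` with a logged warning (`stop_policy`
  also offers `passthrough` and `error`).  Curated coding alignments
  contain no internal stops; the policy only matters for dirty data.
- **Ambiguous input codons** map to the unique common image of their sense
  resolutions when one exists (`GCM → GCN`), otherwise to `NNN` — with one
  refinement: codons that already *are* degen1 images map to themselves.
  Without this fixed-point rule re-recoding an already recoded matrix would
  degrade `YTN` to `NNN`; with it the table and the alignment operation are
  idempotent, which the test suite asserts over the full 15³-codon
  ambiguity alphabet.
- **Codons containing `-` or `?`** pass through unchanged; recoding never
  invents or destroys missingness.
- **Masked columns** are expected to be removed before codon framing (the
  usual state of distributed matrices); retained exclusion sets must align
  to whole codons, and a codon straddling the mask boundary is an error
  reported with its coordinates.

The `noLRall1nt2`/`LRall1nt3` partition assigns every third position, plus
first positions of codons translating to Leu or Arg, to `LRall1nt3`; second
positions and the remaining first positions form `noLRall1nt2`.  A
first-position column counts as Leu/Arg under the default `any_taxon` rule
if any taxon's codon there has all its resolutions in {Leu, Arg}
(`all_taxa` is available; the published definition table is external and
the per-cell variant is noted but not implemented).  Internally coordinates
are 0-based half-open; NEXUS output is 1-based inclusive.

## Composition diagnostics

Per-taxon composition vectors are A/C/G/T proportions; the default
`exclude` rule counts unambiguous bases only — degen1 matrices are rich in
Y/R/M/N codes, and counting them fractionally (the `fractional` option)
changes compositions in a rule-dependent way that we prefer to expose as a
sensitivity analysis rather than a default.  Gaps and `?` are never
counted.  The heterogeneity statistic is the total branch length of the
minimum-evolution tree built on pairwise Euclidean distances between
composition vectors (per cent/100 units; every distance ≤ √2).  The longer
the tree, the more compositional heterogeneity its taxon set carries; the
statistic deliberately contains no phylogenetic signal of the primary
sequence.

Distance trees: neighbor joining with two determinism conventions — taxa
are canonicalized to sorted-label order, and ties in the Q criterion break
at the lowest (row, column) index pair, with the minimum taken over the
upper triangle only (floating-point broadcasting makes Q asymmetric in the
last ulp).  Negative NJ branch lengths are clamped to zero with the deficit
logged.  Minimum-evolution refinement fits ordinary-least-squares branch
lengths to the fixed topology (unconstrained least squares; negative
estimates are retained internally and clamped to zero for length
reporting) and hill-climbs with nearest-neighbour interchanges, accepting
per round the single best total-length-decreasing move; on 6-taxon
problems this reaches the exhaustive-search optimum in the test suite.
The composition bootstrap resamples alignment columns with replacement,
rebuilds the NJ tree per pseudoreplicate, and reports split frequencies as
percent, mapped onto the full-data tree for display.  Outlier flagging
offers `centroid_z` (distance to the mean composition in standard
deviations; note the algebraic cap z ≤ (n−1)/√n for a single outlier among
n taxa) and `tree_tail` (the k longest midpoint-rooted root-to-tip paths).
Display rooting is midpoint by default — the alternative used in the
literature ("minimize large groups branching off a central backbone") is
subjective and not reproducible.

## Tree-set statistics

Bipartitions are canonical frozen leaf-label sets (the side away from the
smallest label), which makes all consensus operations invariant to taxon
input order and rotation.  Strict and majority-rule consensus count
canonical splits; Adams consensus recursively intersects root partitions
(the common refinement of the input trees' partitions at the root becomes
the consensus root's children).  Adams requires rooted trees: unrooted
inputs are rooted at a caller-named outgroup leaf, defaulting to the first
taxon in sorted order.

Search-effort arithmetic: if a fraction p of replicates lands within a
relative lnL threshold of the best — the threshold is relative,
(lnL\* − lnL)/|lnL\*| — then n = ln(1 − c)/ln(1 − p) searches give
confidence c of at least one hit.  n is **rounded to the nearest integer**
(minimum 1) rather than taken as a ceiling: this convention reproduces the
canonical worked values 6 and 725 from hit counts 1827/4608 and 19/4608
(a ceiling would give 726 for the latter), and the Monte-Carlo check in
the test suite confirms the attained confidence is 0.95 to within
simulation error.  p is computed as replicates-in-set over total
replicates.

Best-of-k supports subsample each pseudoreplicate's replicates to their
first k, select the highest-score tree (earliest on ties), and recompute
supports; the convergence report flags edges whose support at small k
differs from the largest-k value by ≥ δ points (default 5).

Rogue screening is two independent tools.  The annotation screen flags
(a) members of multi-exemplar groups that appear in no clade consisting
purely of ≥ 2 of their own group, and (b) single-exemplar taxa attached at
a polytomy with more children than a configurable limit (default 3).  The
RBIC pruner is a deliberately simplified single-taxon greedy variant of
rogue detection: RBIC(S) = Σ majority-consensus split frequencies /
(|S| − 3), the taxon whose removal most increases RBIC is dropped
(canonical-order tie-break), and the trace is strictly increasing by
construction.  Dropsets larger than one and exact parity with the
published RBIC optimizers are out of scope.

## The simulator, and what passing tests do and do not show

`sim_codon_alignment` is a two-layer model rather than a full codon CTMC:

1. **Amino-acid layer.**  Poisson(ν·t) substitutions per site on each
   branch of length t, uniform exchangeabilities over the 20 amino acids;
   ν is `nonsyn_rate` (default 0.3 amino-acid substitutions per site per
   unit branch length — enough signal to resolve most internal edges of a
   16-taxon Yule tree from 500 codons, without saturating).
2. **Codon-usage layer.**  Poisson(σ·t) synonymous resamplings per site;
   each resampling redraws the codon from the lineage's usage profile
   *within the codon's degen1 synonymy component*, and the codon drawn
   after an amino-acid substitution comes from the target amino acid's
   canonical (lexicographically first) component.  σ is `syn_rate`
   (default 30): third positions are then at their lineage-profile
   equilibrium on all but the very shortest branches, the saturated
   regime in which synonymous change is phylogenetically undecipherable
   and composition-driven.  Because resampling never crosses component
   boundaries, the degen1 image of every site is a function of the
   amino-acid layer alone — the synonymous/nonsynonymous separation is
   exact by construction, not approximate.

Biased lineages (stem branch plus all descendant branches whose leaf sets
lie inside the biased set) use the profile w(codon) ∝ γ^(#G/C at
degenerate image positions), γ = `gc3_weight` ≥ 1; at γ = 10 a fourfold
site sits at GC3 ≈ 20/22 ≈ 0.91 against 0.5 for unbiased lineages.  Trees
are pure-birth (Yule, default birth rate 1) with exponential waiting
times; alignments are in-frame, gapless and stop-free.  The artifact
driver picks as biased pair the *non-sister leaf pair with the shortest
internal path* — the pair for which compositional attraction competes
hardest with the true topology — and measures composition-tree lengths,
p-distance NJ recovery, and composition-bootstrap support for the pair
under raw and degen1 coding.

What the simulator does **not** emulate: indels, alignment error and
masks, among-site rate variation and heterotachy, selection on codon
usage beyond the single γ knob, and realistic amino-acid exchangeabilities.
Passing the artifact tests therefore shows that the pipeline detects and
removes a synonymous compositional artifact *of the kind modelled*; it is
not a statement about power on any particular empirical matrix.

`sim_bootstrap_run` generates the convergence analysis's generative model:
each pseudoreplicate's latent best topology is the reference with
probability `pi_true`, else a random NNI neighbour; each of k search
replicates finds the latent best with probability `q_find`, else returns a
further-degraded topology (a random NNI of the latent best) with a
strictly lower score.  Trees within a run are shared objects, so large
runs stay cheap.

## Problem sizes and reproducibility

The stochastic test-suite checks run at 100 simulations of 16 taxa × 500
codons (with 100-pseudoreplicate composition bootstraps) and 200 simulated
bootstrap runs of 50 pseudoreplicates × 15 replicates — sizes chosen so the
complete suite runs in about a minute on one CPU while leaving the
binomial margins of the asserted fractions comfortable.  Every stochastic
entry point takes an explicit seed; `numpy.random.default_rng` is used
throughout, outputs are bitwise-reproducible per seed, and the
command-line interface funnels all randomness through its global
`--seed`.

## Known limitations

- The NEXUS reader accepts the simple dialect (DATA/CHARACTERS block,
  sequential or interleaved, bracketed comments, SETS with
  CHARSET/EXSET); sequential matrices must keep each taxon's sequence on
  one logical line.  PHYLIP output is limited to distance matrices.
- `classify_columns` classifies whole columns; per-cell (taxon × site)
  masking variants exist in the literature but are not implemented.
- OLS branch lengths are unconstrained (no non-negativity constraint in
  the fit); only the reported lengths are clamped.
- The annotation rogue screen assumes a rooted consensus; on unrooted
  input root placement can change which clades count as "pure".
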