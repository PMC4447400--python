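# Methods

## The question and the two arms

Classical *"Globigerinoides"* lumps every globigeriniform planktonic
foraminifer with supplementary apertures on the spiral side. The package
implements the two independent analyses used to test whether that genus
concept covers one lineage or two: a morphometric arm that asks whether
fossil populations separate into two clusters in aperture-shape space,
and a molecular arm that asks whether the extant members form one clade
in SSU rDNA phylogenies. Both arms are fully testable on synthetic data
generated by the package itself.

## Morphometric arm

**Indices.** PADR = aperture maximum width / aperture height; SI =
larger / smaller of the two angles flanking the primary aperture. Both
are unit-free ratios of raw measurements (micrometres, degrees), so no
size normalization is applied. SI is computed as max/min regardless of
which CSV column holds the larger angle: the definition is
"larger over smaller" and column order is a data-entry convention the
code must not trust. Angles are validated to (0, 180)°, widths and
heights to be strictly positive; invalid rows are reported with reasons
and excluded rather than repaired.

**Discriminant.** Two-group LDA with the bias-corrected pooled
within-group covariance and equal priors. Equal priors are the only
reproducible reading of an "optimum discrimination score z = 0" with no
stated prior: the boundary then passes exactly through the midpoint of
the two group means, which is also an invariant the tests assert. The
features are raw (PADR, SI) — no log transform or standardization —
because the morphospace axes are the raw ratios. Training uses only
lineage-labelled specimens from one designated zone (default "M3");
other zones are scored, never trained on. An exactly zero score
classifies as "unassigned" (a measure-zero event; silently assigning a
side would bias by implementation detail). The lineage labels of the
training groups must be supplied in the data (`lineage` column); in
practice they come from morphospecies assignments, and the synthetic
generator emits them directly.

## Molecular arm

**Model.** GTR+I+G. The rate matrix is Q_ij = r_ij π_j with six
exchangeabilities (order AC, AG, AT, CG, CT, GT; GT is the reference
rate fixed at 1) and stationary frequencies π, scaled to unit expected
rate so branch lengths are expected substitutions per site under the
mixture's mean rate. Gamma heterogeneity uses k = 4 equal-probability
categories represented by their category means — the de facto standard
discretization — and the invariant class is the usual two-component
mixture: a site contributes p_inv · π_base only if it is constant up to
ambiguity. IUPAC ambiguity codes and gaps become partial-likelihood
vectors with ones over compatible bases; gaps are treated exactly like
N.

**Likelihood.** Felsenstein pruning over compressed site patterns, with
per-node rescaling accumulated in log space (1000-site alignments
underflow naive products). Transition matrices come from the spectral
decomposition of the reversible Q (symmetrized by √π similarity), which
also makes the per-edge likelihood a four-term exponential family in
the branch length: edge optimization therefore uses analytic first and
second derivatives in a safeguarded Newton iteration, falling back to
bounded golden-section search if a step fails to improve. Branch-length
optimization cycles over edges; a fast path updates all edges against
messages computed at the start of the round and falls back to fresh
messages per edge if the simultaneous update ever lowers the
likelihood, so the likelihood trace is non-decreasing by construction.
Branch lengths are searched in [1e-9, 50].

**Search.** Starting tree: neighbor joining on Jukes-Cantor distances
computed over pairwise-complete unambiguous sites, with saturated pairs
(p ≥ 3/4) capped at distance 5. NNI hill climbing then scores both
alternative topologies at every internal edge using the four directional
messages around the edge (so a candidate costs only one central-branch
re-optimization), applies the best strictly improving move, re-optimizes
branch lengths, and repeats until no edge improves. Tie-breaks are
deterministic (preorder edge enumeration, first best wins). SPR moves
are not implemented: at the 33-taxon scale of the reference analysis,
NNI from an NJ start recovers the generating topology reliably in the
package's own recovery tests, and the smaller search keeps the bootstrap
affordable.

**Model fitting.** Base frequencies are fixed at observed proportions
(+1 pseudocount) rather than ML-optimized — a standard practical choice
that removes three dimensions from the optimizer. Exchangeabilities are
fitted by cyclic bounded 1-D searches on a log scale. The gamma shape
and p_inv are deliberately fitted *jointly* (Nelder-Mead on log/logit
scales) together with a global branch-length scale factor: the two
parameters trade off along a notoriously flat ridge that is coupled to
total tree length, and 1-D coordinate steps stall on it. Sweeps
alternate with branch-length re-optimization until the log-likelihood
improves by less than 1e-5 (cap 50 sweeps, with a warning and
best-found parameters on non-convergence). Even at 50,000 sites the
ridge leaves visible joint uncertainty in (α, p_inv) on few-taxon trees;
the recovery tests use an 8-taxon tree because constancy across more,
divergent tips is what identifies p_inv.

**Bootstrap.** Nonparametric column resampling; replicate r uses RNG
seed (master + r), so runs are deterministic given the master seed and
replicates are independently reproducible. Each replicate reruns the
full NJ → branch optimization → NNI pipeline at fixed model parameters.
Supports are the fraction of replicates containing each bipartition of
the best ML tree and are mapped onto that tree (not onto a consensus),
matching how such trees are usually displayed.

**Rooting.** The root is placed at the midpoint of the edge separating
the outgroup clade from the ingroup. If the outgroup is not
monophyletic in the inferred tree, the code warns and roots on the edge
whose outgroup side contains the most outgroup taxa (fewest ingroup
taxa on ties). Rooting is display-level: ingroup bipartitions and
likelihood are unchanged (the pulley principle), and both facts are
tested. The three shipped outgroup schemes follow the published taxon
sampling: (1) *Globigerinella* + *Beella* (the sister lineage), (2)
*Globigerina* (more distant, long-branched), (3) the microperforate
*Globigerinita* + *Candeina* clade.

## Synthetic data

**Morphometrics.** Each population draws (PADR, SI) targets from a
bivariate normal truncated to PADR > 0, SI ≥ 1, then emits raw geometry
realizing them — height ~ U(40, 120) μm, width = PADR·height, smaller
flanking angle ~ U(30, 80)° redrawn while SI·angle would reach 180°,
angle column order randomized — so the downstream index computation is
exercised rather than bypassed. Preset centers (ruber: PADR 0.9,
SI 1.2, tight; trilobus: PADR 2.0, SI 2.0, wider, positively
correlated) are calibration choices consistent with the qualitative
description of the two lineages (low, tight values with SI confined
near [1, 1.5] for the ruber group; elongated, variable slit apertures
for the trilobus group); no published numeric values exist for these
presets. Default n = 200 per sample follows the picking protocol of the
fossil study. The generator does not model measurement error,
ontogenetic allometry, or preservation bias — passing tests show the
pipeline's statistics behave correctly under the configured separation,
not that real populations are that well separated.

**Sequences.** Alignments evolve site-by-site along a given tree: root
states from π; each site draws its rate class once (invariant with
probability p_inv, else one of the k gamma categories uniformly) and
keeps it on every edge, matching the +I+G likelihood's assumptions
exactly. Indels and alignment uncertainty are not simulated — the
pipeline consumes pre-aligned data by design. The 33-taxon fixture tree
carries the two focal clades (ruber + elongatus + conglobatus +
*rubescens*; sacculifer + *Orbulina* + *Sphaeroidinella*), monophyletic
versions of all three outgroup sets, and configurable branch lengths
(default 0.05 internal / 0.1 terminal — divergent enough that ~1000
simulated sites resolve every edge, shallow enough to stay realistic
for SSU rDNA).

## Numerical choices and scales

- Pattern compression before likelihood work; bootstrap replicates
  resample columns, so their patterns are subsets of the originals.
- Edge optimization tolerance: predicted log-likelihood gain < 1e-10;
  branch-length rounds stop at total improvement < 1e-6 (default).
- NNI accepts only gains > 1e-6, preventing tie-cycling.
- The acceptance script and tests run the three-outgroup protocol at
  1200 simulated sites and B = 100 bootstrap replicates, and topology
  recovery at 2000 sites over 20 seeds — sizes chosen so each check
  measures what it claims on a single CPU; supports at these sizes are
  effectively saturated for the focal clades.
- The gamma-shape recovery check asserts a ±30% band around the true
  0.5: no tighter bound is defensible given the α/p_inv ridge
  documented above.

## Known limitations

- NNI-only search can in principle be trapped by topologies needing a
  multi-edge rearrangement; the recovery tests bound how often this
  matters at the scales used, not in general.
- p_inv and α are weakly identified on trees with few taxa; estimates
  from small taxon samples should be read as a joint (α, p_inv, tree
  length) fit, not as separately meaningful numbers.
- The morphometric arm takes measurements as given; imaging, landmark
  placement and specimen orientation are upstream and unmodelled.
- The discriminant is linear with two features by design; it answers
  "which side of the published boundary", not "what is the best
  possible classifier".
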