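# Methods

## The inference model

Each network type is produced by the same tree-ensemble procedure. For a
target gene *g*, let **y** be its expression profile over the *n* tissue
samples and **X** the profiles of the *p* candidate regulators (TFs). A
random forest of regression trees is fitted to predict **y** from **X**;
every split reduces the node-weighted variance of **y**, and each
regulator's raw importance is the total reduction attributed to its splits,
averaged over trees. The importance vector is then normalized to sum to 1
across regulators (a constant target yields the zero vector instead).
Concatenating the per-target importances over all targets and sorting by
weight — ties broken by regulator id then target id, so rankings are
reproducible — gives the ranked edge list.

Defaults follow common GENIE3 practice: 1000 trees, `k = sqrt(p)` candidate
regulators per split, bootstrap resampling, expression used on the raw FPKM
scale (an opt-in log1p transform is not applied by default; with rank-based
tree splits the monotone transform mainly affects noise weighting, and raw
FPKM keeps the weight scale comparable across runs). Per-target
normalization is chosen because it makes weights comparable across targets
regardless of how predictable each target is; each target's incoming
weights then sum to 1, so a weight threshold has the interpretation "share
of explanatory power". A TF appearing among the targets is excluded from
its own candidate set, so self-edges cannot arise. Each target's forest is
seeded deterministically from the run seed and the target id, which makes
the edge list independent of target evaluation order.

The omics pairing decides the network type: mm (transcriptome →
transcriptome), TT (translatome → translatome), Tm (translatome TF →
transcriptome target). Inter-omics inference requires the two matrices to
cover the identical tissue set. Genes enter inference only after the
detectability filter (max FPKM ≥ 1 in some tissue, non-zero in ≥ 3
tissues), applied per matrix; regulators must pass in both layers of their
data source. Whether filtering should be joint across sources is
underdetermined; this implementation filters per matrix and intersects for
regulators, which keeps each source self-contained.

## Merging and topology

Edge lists are truncated (top-*k* by rank, or an inclusive minimum weight)
before merging. The union network deduplicates pairs across inputs,
aggregates weights with `max` by default (the merged resource should retain
each pair's strongest support; only pair membership is used downstream),
and records boolean provenance flags per input. The high-confidence network
intersects the three types within each data source (weight = mean of
members) and then unions the two per-source intersections.

Topology is computed on the undirected simple projection: transitivity
(3 × triangles / connected triples), average shortest-path length over
reachable ordered pairs (disconnected pairs ignored — the convention that
stays finite on fragmented graphs), and module count as connected
components with at least `min_nodes` (default 5) nodes. Components are used
for "modules" rather than a community algorithm; on sparse truncated
networks components are well defined and parameter-free, and nothing
downstream depends on finer module structure.

## Benchmarking

Given a gold standard (TF → target sets with declared TF and target
universes):

- **Overlap** counts (TF, target) pairs shared between network and gold,
  restricted to TFs present in both.
- **Null**: per iteration each shared TF's predicted target count is
  redrawn uniformly without replacement from the target universe (minus the
  TF itself); 1000 iterations by default. The per-TF null mean follows the
  hypergeometric expectation k·m/N, which the tests verify.
- **χ²**: a 2×2 table of (overlapping, non-overlapping) pairs for the
  observed network versus the null mean, df = 1, no continuity correction,
  upper-tail p. Cells with zero expectation mask the result rather than
  erroring.
- **AUROC** uses the rank-sum formulation with midrank ties; **AUPR** uses
  non-interpolated precision–recall integration. Candidates for a TF are
  the declared target universe minus the TF itself; candidates absent from
  the network score 0. TFs lacking positives or negatives are excluded from
  per-TF averages and logged.
- **Weight comparisons** restrict each network type to its top-*k* edges,
  take pairs present in all three types, and apply a two-sided paired *t*
  over the shared pairs. All-zero differences give t = 0, p = 1; non-zero
  constant differences are masked (the statistic is undefined), as are
  comparisons with fewer than 3 shared pairs.

In the pipeline, benchmarking restricts each network to edges whose target
lies in the gold target universe, since TF genes appear as inference
targets but are not regulated in the generative model and no gold standard
can contain them.

## The synthetic atlas generator

The generator encodes the premise that target transcription responds to TF
*translation*:

1. Baseline log-FPKM per gene: gene mean ~ N(log 20, 1), a tissue-category
   effect ~ N(0, 0.8) and tissue noise ~ N(0, 0.3). These give FPKM
   abundances spanning roughly three orders of magnitude with
   category-structured expression, the shape of real developmental atlases.
2. Translational efficiency per gene × tissue: TE = exp(N(0, te_sigma)),
   clipped to [0.25, 4] — the bulk range reported for real paired atlases.
   TF translatome = TF mRNA × TE.
3. Target mRNA: each target's drive is the effect-weighted sum of its
   regulators' standardized log translatome profiles, scaled by
   1/sqrt(in-degree), plus N(0, noise_sd); a softplus link keeps abundances
   positive while preserving monotone regulator effects (no generative
   model is prescribed by the benchmarked study design, which observes real
   data; this is the package's choice). Each target is then rescaled to an
   FPKM-like magnitude drawn as in step 1.
4. Target translatome = target mRNA × its own TE.
5. Measured layers: two replicates (multiplicative lognormal noise with
   log-sd `noise_sd`) and a bulked sample formed as the mean of three
   hidden noisy replicates, mirroring pooled-library designs. Detection
   dropout zeroes each measured entry independently with probability
   `detection_dropout`.

Truth networks have heavy-tailed out-degrees (Pareto-allocated, so a few
hub TFs and many small ones), signed effects with magnitude U(0.5, 1.5) and
70% activators. Gold standards degrade the truth per TF: a rounded fraction
`observed_fraction` of true targets is kept and
`round(spurious_fraction × kept)` non-targets are added (Python's built-in
round, i.e. banker's rounding, is used consistently). Every stage draws
from a named substream of the global seed (CRC32-derived, < 2^31), so any
stage can be re-seeded without perturbing the others and identical
configurations give byte-identical serialized output.

Study-condition defaults — 12 tissues in nine named categories, te_sigma
1.0, noise_sd 0.25, dropout 0.02 — are fixed once as a desk-scale analogue
of a ~30-tissue paired atlas whose per-gene cross-layer correlations
mostly fall between 0.5 and 1 and whose replicate correlations are high.

### What the generator does not emulate

Read-count noise (negative binomial), FASTQ/alignment artifacts,
ribosome-footprint periodicity, gene length effects in FPKM, correlated
dropout, indirect regulation chains (targets regulating targets), TF–TF
cooperativity, and condition-dependent network rewiring. Consequently,
passing tests show the machinery is correct and that the inter-omics
advantage follows when translation drives regulation; they do not show how
large that advantage is on real tissue atlases, where translational
buffering is structured rather than i.i.d. lognormal — no quantitative
model of buffering is established, and the lognormal TE is one defensible
choice among several.

## Numerical and degenerate-case choices

- Detection predicate: value ≥ `detect_min` and strictly positive; the
  default `detect_min = 0` makes "detected" mean FPKM > 0.
- TE uses no pseudocount; entries with the denominator below detection are
  masked, never infinite.
- Zero-variance profiles yield masked correlations (real atlases contain
  constant rows), and correlations need ≥ 3 observations.
- `min_weight` truncation is inclusive (≥).
- Edge ranks are 1..N under (weight desc, regulator asc, target asc).
- χ² with a zero expected cell, paired t with constant non-zero
  differences, and per-TF normalization with a zero denominator are all
  masked with reasons rather than raised.

## Problem sizes used by tests and the acceptance script

The recovery study runs 20 replicate atlases of 20 TFs × 200 targets over
12 tissues with 25-tree forests — sizes at which the Tm-versus-mm contrast
is already decisive (the advantage grows with trees and samples). The
pipeline demonstration uses 50 trees and truncates each network to its top
1000 edges, the desk-scale analogue of keeping the top million of ~47M
possible pairs at atlas scale (the library default truncation remains one
million). Forest-stability checks use 500 trees on a 10-TF × 30-target
subset. The random-baseline AUROC uses 50 TFs × 1000 candidates with 100
positives each.

## Known limitations

- Importance-based edges do not distinguish direct from indirect
  regulation, and edge direction is a convention of the regulator set, not
  an inference.
- The χ² overlap construction (pair counts at the chosen truncation versus
  the null mean) is one reasonable reading of an observed-versus-random
  comparison; other contingency constructions would give different
  p-values.
- Per-TF AUROC treats network-absent candidates as ties at score 0, which
  penalizes aggressive truncation.
- The "bulked" source is simulated as a mean of hidden replicates;
  real pooled libraries are pooled before sequencing, so their noise is
  not exactly the mean of replicate noise.
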