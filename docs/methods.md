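# Methods

## The problem

A meta-QTL analysis consolidates QTLs reported by many independent
linkage-mapping studies of one trait. Each study used its own mapping
population (recombinant inbred lines, doubled haploids, F2/backcross,
near-isogenic lines), its own marker map and its own statistical power, so
the reported peaks and confidence intervals are not directly comparable.
The pipeline here makes them comparable (consensus map + projection),
clusters them (mixture model), and post-processes the clusters into
regions a breeder can act on (physical anchoring, GWAS verification,
candidate genes, breeders' filter).

## Compendium completion rules

Literature tables omit fields in predictable ways. Three rules are applied
before analysis, and already-present values are never overwritten:

* missing peak ← midpoint of the two flanking-marker positions on the
  study's own map;
* missing LOD ← 3.0, the customary declaration threshold;
* missing 95% CI ← width `c/(N·R²)` centered on the peak, with `c` = 530
  (F2 and backcross), 287 (doubled haploids), 163 (RILs). These constants
  come from the simulation-derived empirical formulas in the QTL-mapping
  literature. `N` is the population size and `R²` the fraction of
  phenotypic variance explained; the compendium stores PVE as a percent
  (as printed in papers) and the conversion to a fraction happens inside
  the completion rule, never in the formula. Near-isogenic lines carry no
  published constant and use the RIL value (NILs derive from inbred
  lines). Symmetric centering is an assumption; the formula only yields a
  width. Records with neither a peak nor resolvable flanks are excluded
  and logged, mirroring the non-projectable fraction of real compendia.

## Consensus map: LP merge

Per chromosome the consensus positions `y` solve

    minimize   Σ_j (1/n_j) Σ_{(a,b) adjacent in map j} |(y_b − y_a) − d_j(a,b)|
    subject to y_b − y_a ≥ min_gap for every retained ordered pair,

a linear program solved with scipy's HiGHS backend (auxiliary variables
for the absolute values). `min_gap` defaults to 1e-6 cM — just enough to
make strict order representable without distorting distances.

Ordinal constraints are the directed adjacencies of every component map.
When maps disagree on order the union contains directed cycles; since the
minimum feedback arc set is NP-hard, a greedy pass removes, from each
remaining cycle, the edge supported by the fewest maps (ties: fewer total
markers in the supporting maps, then lexicographic). Removed constraints
are excluded from both the constraint set and the objective (their
distances contradict the retained order) and are reported.

The MAE objective frequently has a flat optimal face (two maps disagreeing
on one distance leave a whole interval of equally good positions). The
tie-break is the midpoint of that face: with the map pinned at an anchor
marker, the position-sum-minimal and -maximal optimal solutions are
computed (two more LP solves against an optimality cut) and averaged; the
optimal set is convex, so the average is optimal, deterministic and
symmetric in the inputs. Positions are finally shifted so each chromosome
starts at 0 cM. Markers touched by no distance term or constraint
(single-marker chromosomes in some component) are placed at their mean
source position, clipped into the solved range.

## Projection

For each QTL the nearest pair of markers bracketing its peak on the source
map that is shared with the consensus map (same chromosome, same order)
defines a local affine transform, `ratio = Δconsensus/Δsource`; the peak
and both CI endpoints map through it, extrapolating with the same ratio
beyond the anchors. Using the peak's single anchor pair for the endpoints
keeps the transform affine (CI midpoints map to midpoints) and
deterministic. A peak outside the shared-marker span uses the two nearest
shared markers and is flagged. Rejection codes: `CHR_ABSENT`,
`NO_COMMON_MARKERS`, `ZERO_SPAN` (degenerate source anchors),
`INVERTED_ANCHORS` (order flipped on the consensus), `EXTREME_RATIO`
(ratio outside (0.1, 10), a configurable guard against map-scale
pathologies standing in for the interval-consistency checks of GUI
projection tools).

The projected 95% CI yields the per-QTL position standard deviation used
downstream: `s_i = (CI_hi − CI_lo)/3.92`, the width of a 95% normal
interval being 2×1.96σ.

## Mixture model and model selection

Per chromosome, projected peaks are modeled as

    x_i | component k  ~  Normal(μ_k, s_i²),

with `s_i²` *known* and fixed — the variances come from the projected CIs,
not from the data being clustered. Free parameters are the K means and
K−1 mixing proportions, p = 2K−1. EM:

* E-step: `r_ik ∝ π_k · N(x_i; μ_k, s_i²)`;
* M-step: `μ_k = Σ_i r_ik x_i/s_i² / Σ_i r_ik/s_i²`, `π_k = mean_i r_ik`;
* convergence at |Δlog L| < 1e-8 or 500 iterations; best of `n_restarts`
  (default 5) deterministic-seeded initializations — quantile seeding for
  restart 0, Gaussian jitter (0.1 × data sd) for the rest; components
  sorted by mean.

K = 1..min(n, 10) are fitted and scored with five criteria:

    AIC  = −2L + 2p                AICc = AIC + 2p(p+1)/(n−p−1)   (∞ if n ≤ p+1)
    AIC3 = −2L + 3p                BIC  = −2L + p·ln n
    AWE  = −2L_c + 2p(3/2 + ln n)

where `L_c` is the classification log-likelihood under hard max-posterior
assignments. A K minimizing at least three criteria is chosen; failing
that, the K winning the most criteria, ties toward fewer components. The
exact AICc/AIC3/AWE forms are pinned here for reproducibility; the
classification-likelihood AWE follows the clustering literature's usual
approximation.

## Regions, refinement, classification

Each QTL joins its max-posterior component. A component's consensus
position is the inverse-variance weighted mean of member peaks, its
variance `1/Σ(1/s_i²)`, its 95% CI ±1.96σ. One refinement pass removes
members whose own peak lies outside that CI (they are reported as
*non-supporting*), after which position and CI are recomputed once —
a single pass keeps the accounting deterministic and transparent.
Components reduced to one member are *singletons*, not regions. Remaining
regions are **MQTLs** when their members span ≥2 studies, **QTL hotspots**
when a single study supplied all members. Ids are ordinal by position
within the chromosome (`MQTL3A.2`; `QTLhotspot_5D.1` style, the suffix
dropped when a chromosome has a single hotspot). Region flanking markers
are the nearest consensus markers outside the CI.

## Physical anchoring and candidate windows

A marker physical-position table (marker → chromosome, bp; produced
offline by sequence alignment to a reference genome) anchors each region:
start/end are the sorted bp of the two CI flanking markers, and the peak
interpolates linearly in cM↔bp between them. When a flank is missing from
the table, the nearest anchorable marker inside the CI substitutes, then
the nearest outside within 5 cM (substitutions are recorded on the
interval). Coordinates are 1-based inclusive; BED export converts to
0-based half-open at the file boundary only.

Candidate-gene windows follow the 2 Mb rule: regions spanning < 2 Mb are
scanned whole; larger regions contribute a 2 Mb window centered on the
interpolated peak, clipped to the interval. Only regions with ≥3 member
QTLs ("promising" regions) are scanned. Gene inclusion is any ≥1 bp
overlap; expression filtering keeps genes with TPM strictly > 2 in at
least one relevant tissue (default tags: grain, spike,
flag-leaf-senescence); genes absent from the expression matrix count as
not expressed. GWAS verification uses the full anchored interval, not the
window, with inclusive bounds and duplicate MTAs collapsed.

## Breeders' filter

Strict comparisons, matching how such thresholds are stated: CI < 2.5 cM,
average PVE > 10%, average LOD > 3.5, members ≥ 3, and multi-study support
(hotspots excluded). Relaxing any threshold can only grow the selection
(monotonicity is property-tested).

## Synthetic generator

`metaqtl.simulate` emulates the raw material of a meta-analysis with known
ground truth:

* **chromosomes** — three by default (genetic lengths 180–250 cM, physical
  lengths 590–800 Mb) with a piecewise-linear monotone cM↔bp mapping whose
  central 10% of genetic length covers 70% of the physical length — a
  centromeric recombination desert, the reason real regions can span
  hundreds of Mb physically while being genetically tight;
* **true loci** — 3 per chromosome, uniform with a minimum separation of
  4σ (rejection sampling), σ = 3 cM;
* **studies** — 10 by default; each draws a population (75% RIL, 23% DH,
  2% NIL; sizes 93–302, 95–414, 120 respectively), subsamples 70% of the
  master marker grid (2 cM spacing, chromosome ends always kept so flanks
  can bracket any peak) and rescales its map by exp(N(0, 0.05));
* **detections** — each study sees each locus with probability 0.8; a
  detection draws PVE ~ Uniform(4, 25)%, computes its CI width from the
  population formula, and draws its peak error with the standard deviation
  that CI implies (width/3.92) — so the compendium follows exactly the
  heteroscedastic model the meta-analysis assumes, with an average peak sd
  of about 3 cM under the default population mix; LOD = 3 + Exp(mean 3),
  covering the ≈3–30 range seen in compendia;
* **validation layers** — GWAS MTAs planted within ±1 Mb of each true
  locus (plus optional uniform decoys), tiled gene models with one gene
  planted at each locus, a LogNormal TPM matrix with a configurable
  expressed fraction (planted causal genes always expressed in relevant
  tissues), and known genes at the first locus of each chromosome.

All generators are pure functions of (config, seed).

What the generator does **not** emulate: genotype-level mapping noise
(QTLs are drawn around truth, not re-mapped from genotypes), marker-order
errors within studies (maps are subsets of one master order, so consensus
merging faces scale conflicts but few order conflicts), shared-population
correlations between studies, epistasis, and trait-specific effect-size
distributions. Passing recovery tests therefore demonstrates correctness
of the machinery under the stated noise model, not performance on any
particular real compendium.

## Numerical choices and degenerate inputs

* EM tolerance 1e-8 on the log-likelihood; 500-iteration cap; weights
  clipped at 1e-300 before normalization.
* LP optimality cut tolerance 1e-9 (relative); position box = summed
  component lengths + 10 cM.
* Zero-width projected CIs are rejected at construction (σ must be > 0);
  single-marker chromosomes pass through the merge with a warning and
  report undefined density; regions with no anchorable marker are flagged
  `UNANCHORED` and skipped downstream with a warning rather than raised.
* Matching of recovered regions to planted loci interpolates the truth
  onto the consensus map through shared markers first — comparing across
  coordinate systems would charge consensus-scale differences to the
  clustering — then greedily pairs nearest positions within 3σ + 2 cM.

## Problem sizes

Default test and acceptance scenarios use 3 chromosomes × ~110 master
markers, 10 studies, ~80 QTLs, and 3 pipeline replicates plus 50-seed
model-selection sweeps — sizes chosen so a full run takes seconds on a
laptop while every stage still exercises its real code path. All knobs
scale up through `TruthConfig`.

## Known limitations

* The greedy feedback-arc-set is approximate; a pathological cycle
  structure could drop more constraints than the true minimum.
* The five-criterion vote inherits the liberal bias of the AIC family on
  small chromosomes; the vote plus AWE/BIC tempers but does not eliminate
  it.
* One refinement pass means a region's final CI is not re-checked against
  its retained members; iterating to a fixed point would change counts on
  the margin.
* Physical anchoring trusts the marker table; no liftover between
  reference versions is attempted.
* The packaged reference region tables transcribe a published analysis
  whose own text and tables disagree in minor ways (one region row absent
  from the printed table); statistics computed from the fixtures reflect
  the printed rows.
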