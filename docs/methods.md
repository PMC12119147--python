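# Methods

This note documents the models and procedures implemented in
`phyloendemism`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic-data experiments do and do not show.

## Problem setting

The package analyses area-based endemism for a clade whose species-level
dated phylogeny is assembled by the backbone-and-graft strategy: a
time-calibrated family-level backbone provides secondary calibrations, each
family's species-level subtree is dated independently, and the dated
subtrees are spliced onto the backbone. Given the resulting tree and a
binary species × area occupancy matrix (the default area set is the ten
Indo-Australian Archipelago areas: AUS, NG, EMN, MAU, SUL, LSU, BOR, JAV,
SUM, SEA), it computes per-area diversity and endemism metrics, classifies
areas as centers of paleo-, neo-, mixed or super-endemism against a
community null model, and partitions pairwise between-area dissimilarity
into turnover and nestedness, taxonomically and phylogenetically.

## Grafting

Each family subtree must be ultrametric (root-to-tip spread ≤ 1e-6 ×
crown age, configurable). Rescaling multiplies every branch length by
k = target crown age / current crown age, which changes the time scale but
no relative branch length; the grafted-vs-ungrafted concordance check
exploits this — matching branches by the tip bipartition they subtend, the
Pearson correlation between grafted and original lengths must be exactly 1
under pure grafting, and any post-hoc distortion of a single branch drives
it below 1. Correlation is reported as undefined for families with fewer
than 3 branches or zero branch-length variance.

Two calibration conventions are exposed:

* **crown** (default): the plan's target age is the family's crown age;
  the subtree is rescaled to it and the stem branch absorbs the remainder
  (stem = attachment-parent age − target). This follows the convention of
  family-level backbones carrying one exemplar tip per family.
* **stem**: the target age is the stem age; a stem node is created at that
  age and the subtree is grafted *unrescaled*, trusting its own crown age
  (which must be younger than the stem). This is the right choice when the
  subtree dates are considered authoritative and the backbone only fixes
  the attachment time.

Dating outgroups included in a family subtree can be listed per family and
are pruned before rescaling. Families whose subtree is absent (e.g.
single-tip families) keep their backbone exemplar tip unchanged.
Calibration *ranges* are not supported; point ages only.

## Diversity and endemism metrics

All metrics operate on the rooted tree; the spanning set of a community is
the union of root-to-tip paths of its members.

* **SR**: column sum of the occupancy matrix.
* **PD** (Faith): summed branch length of the spanning set, root path
  included. A flag excludes the root-to-MRCA path for the unrooted
  convention; the rooted default keeps the PE partition identity below
  exact.
* **PE** (Rosauer): sum over the area's spanning branches of branch length
  divided by range size, where a branch's range is the number of areas
  whose spanning sets contain it. The spatial unit of the range is the
  *area* (ten units by default), not a grid cell. Every branch's length is
  thereby partitioned across the areas it occupies, so Σ_areas PE(area) =
  PD(union of occupied areas) exactly (asserted to 1e-9 in tests).
* **RPD / RPE**: the observed metric divided by the same metric on a
  comparison tree with identical topology and uniform branch lengths
  (total length preserved). High RPE concentrates unusually long
  range-restricted branches; low RPE unusually short ones. Empty areas
  have PE 0 and undefined (NaN) ratios.

The per-area computation is vectorised: a precomputed branch × species
incidence matrix turns all metrics for any occupancy matrix into one
matrix product, which is what makes the null-model replication affordable.
A cross-check test verifies rooted PD against `picante::pd` in R.

## Null model and endemism classification

The null model randomizes the occupancy matrix holding both marginals
fixed (species range sizes and area richnesses). The default sampler is
the curveball algorithm — repeated "trades" of the area sets of two random
species — with 10 × max(n_species, n_areas) trades per sample; a classic
2×2 checkerboard swap sampler is available as a cross-check. Both are
compiled (numba) and seeded; a matrix admitting no rearrangement is
returned unchanged. With few areas the randomization space can be small;
the code warns when the null samples contain few distinct values (ties
then inflate p-values, conservatively) rather than failing.

For each of n_rand randomized matrices the four metrics (PE, PE_alt =
PE on the comparison tree, RPD, RPE) are recomputed per area. One-tailed
rank p-values use (r+1)/(n_rand+1) with ties counted in both tails, so
p ∈ (0, 1] and a value above all 999 nulls gets p = 0.001.

Classification is two-step, with alpha = 0.05 and alpha_high = 0.01:

1. *Candidacy*: the area is significant if PE or PE_alt is significantly
   high one-tailed at alpha/2 (= 0.025, the two-tailed-equivalent
   convention); otherwise **not significant**.
2. Among candidates: RPE significantly high → **paleo**; significantly low
   → **neo**; neither → **mixed**, escalated to **super** when both PE and
   PE_alt are high at alpha_high.

The replicate protocol repeats the whole null run n_reps times (default
100) with seeds base_seed … base_seed + n_reps − 1 and tallies per-area
category frequencies. Only the seed varies between replicates. n_rand
defaults to 999 for one-shot analyses; the replicate experiments in the
test-suite use n_rand = 199, which keeps 100 replicates of a ~300-species,
10-area scenario around 20 s on one CPU.

## Beta diversity

Sørensen-family dissimilarities with the turnover/nestedness partition:
sor = (b+c)/(2a+b+c), sim = min(b,c)/(a+min(b,c)), sne = sor − sim, with
a/b/c as shared/unique species counts (taxonomic) or shared/unique
spanning-branch lengths (phylogenetic). Jaccard variants sit behind a
flag. Phylogenetic branch sets include the root path, consistent with PD;
shared deep branches therefore count toward overlap, which is why
phylogenetic beta tends to sit below taxonomic beta when areas share deep
lineages — the pattern the synthetic scenarios reproduce. Pairs involving
an empty area are reported as missing (NaN). On a star tree with equal
pendant lengths the phylogenetic components reduce exactly to the
taxonomic ones (each species contributes one equal independent branch).

## Synthetic data

Trees are pure-birth (Yule) trees conditioned on tip count and rescaled to
a fixed crown age; no extinction parameter, so truth constructions stay
analytic. Endemism regimes are built by surgery on a background tree:

* **paleo**: 8 relict lineages per area, pendant branches attached at stem
  ages drawn in [0.80, 0.92] × crown age, present in that area only;
* **neo**: 3 endemic radiations per area, Yule clades of 10 tips with
  crown age 0.04 × crown age, stems at twice that;
* **super**: both; **none**: background only.

Background species (default 260, giving ~300 species with one regime
active) occupy each area independently with probability 0.35 — a mean
range of 3.5 of 10 areas, a realistic mix of widespread and narrow-ranged
species; species drawn nowhere are assigned one random area so every row
has a presence. Insertions are processed deepest-first and only onto
background branches, so radiations never nest inside relicts. The default
scenario sizes (~300 species, 10 areas, n_rand 199, n_reps 100) run in
minutes on one CPU.

What passing the recovery experiments shows: the classifier detects the
constructed signals — old isolated single-area lineages are called paleo
and shallow endemic radiations neo in ≥ 95/100 replicates, and unstructured
occupancy stays not-significant in ≥ 90% of area-replicates. What it does
not show: robustness to phylogenetic uncertainty, to taxonomic error, to
spatially autocorrelated ranges, or to real richness gradients — real
occupancy data are not independent Bernoulli draws, and real relicts are
not literal pendant edges.

## Numerical choices

* Ultrametricity tolerance: relative spread 1e-6 of the root age.
* Rank-p tie tolerance 1e-12 on metric values.
* Coverage percentages are rounded half-up to 1 decimal; matrices must be
  strictly binary (abundances rejected, not thresholded).
* Newick branch lengths are written with 17 significant digits so
  round-trips preserve lengths to float precision.
* Trees are used as rooted exactly as read; no rerooting.
* CSV outputs use 6 significant digits; the run manifest contains no
  timestamps so identical configs produce byte-identical bundles.

## Known limitations

Single point calibrations only (no age ranges); areas are the only spatial
unit (no grid-cell endemism mapping); pairwise beta only (no multi-site
measures); no multiple-testing correction across areas (none is
conventional for this classification); the curveball trade count is a
mixing heuristic, not a proven mixing time.
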