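# Methods

This note documents the models and procedures implemented in `ancmosaic`,
the parameters that matter, the numerical choices behind them, and what the
synthetic-data tests do and do not establish about real data.

## Problem setting

A target ancestry (think of a proto-population whose unadmixed descendants
no longer exist) survives only as tracts inside present-day admixed genomes.
The pipeline identifies those tracts, reduces replicate tract calls to a
consensus, and reassembles the tracts into a panel of mosaic proxy genomes
for the ancestral gene pool. Downstream statistics then treat the proxy
panel as one more population.

## Synthetic data (`simdata`)

The generator controls exactly the two properties the downstream stages
consume — allele-frequency differentiation and tract structure — and nothing
else:

* **Ancestral frequencies** per site: Uniform(0.05, 0.95).
* **Population drift**: Balding–Nichols; population frequency ~
  Beta(p(1−F)/F, (1−p)(1−F)/F). F is the per-branch differentiation
  parameter; two populations drifted F each from a shared ancestor have an
  expected genome-wide Hudson F<sub>ST</sub> of ≈ F (the Monte-Carlo
  check in the acceptance suite confirms 0.0499 ± 0.0007 at F = 0.05).
* **Admixture**: a single pulse, g generations ago, target proportion m.
  Ancestry breakpoints along a haplotype are Poisson with rate
  `recomb_rate × g` per bp; the ancestry after each breakpoint is target
  with probability m. Realized switches therefore occur at a
  2·m(1−m)-thinned rate and tract lengths are exponential. Defaults
  (r = 1e-8/bp, g = 10) put mean tract length at 10 Mb per switch
  opportunity — far above the 6 kb re-chunking scale, which is the regime
  in which the chunk cap is meaningful.
* **Missingness**: i.i.d. per diploid genotype (both alleles masked
  together), matching how marginal missing-rate filters operate. No
  correlated missingness is modeled.

Coordinates are 0-based half-open everywhere in memory; VCF (1-based) and
BED (0-based) conversion happens in `vcfio` only.

What the generator does **not** emulate: coalescent LD within populations
(sites are independent given population frequencies), recombination-rate
variation, mutation-rate variation, background selection, archaic
introgression, sex chromosomes. Consequently, passing tests demonstrate the
*logic* of every stage (tract recovery, consensus arithmetic, chunk/mask
book-keeping, estimator algebra, screen set-operations) and its statistical
behaviour under frequency differentiation — not robustness to LD-driven
painting artefacts in real genomes. The painting module accepts external
tract files precisely so a production painter can be substituted.

Two auxiliary fixtures follow the same philosophy: Ne trajectories with a
known divergence time (group populations share a base trajectory; the query
is offset by `effect_sd` group-SD units in bins younger than the split; with
zero noise the offset unit falls back to 1% of the base Ne so the
constructed signal is nonzero), and Bernoulli pair-sharing indicators for
the familial-aggregation test.

## Painting (`painting`)

A deliberately collapsed model rather than full Li–Stephens copying: hidden
states are donor *populations*, emissions are add-one-smoothed donor allele
frequencies, and the transition probability of leaving the current state
over a physical gap of d bp is `min(λ·d, 0.49)`, split evenly across the
other populations. The 0.49 cap keeps the chain diagonally dominant over
long gaps. λ defaults to 1e-6/bp (about one expected switch per Mb, the
tract scale of recent admixture); with λ → 0 the painter degenerates to
global assignment. Sites where a donor population has no called alleles
contribute a flat emission and thus inherit the flanking state.

Replicates are posterior path samples (forward-filtering,
backward-sampling) with child seeds spawned from the master seed — the
replicate-to-replicate stochasticity that an external painter produces
across runs. Marginal agreement between sampled paths and the exact
forward–backward posterior is property-tested.

**Consensus** is evaluated at position level: a base belongs to a candidate
segment iff ≥ `min_support` (default 5) of the R (default 10) replicates
label it target; maximal qualifying runs become segments. The equivalent
computation is done on the union of replicate breakpoints, so it is exact,
not grid-sampled. Segment-level voting would be an alternative reading; the
position-level rule was chosen because it is deterministic under replicate
boundary jitter.

## Reconstruction (`reconstruct`)

* **Library**: `quota_per_subpop` samples (default 10) per donor subgroup,
  selected by explicit list or lexicographic order; both haplotypes of a
  chosen sample enter, so 3 subgroups give 60 candidate haplotypes.
* **Coverage mask**: `min_coverage` defaults to ⌈20% of the library size⌉
  (12 of 60). Masked regions are emitted as missing genotypes.
* **Assembly**: within each reconstructable region, start at the left edge;
  at each junction draw uniformly among candidates whose consensus segment
  covers the junction, excluding the immediately preceding source when an
  alternative exists (no immediate reuse within a chain; full reuse across
  haplotypes and genomes). Copy until `max_chunk` (6000 bp), the end of the
  source's consensus segment, or the end of the region. When local coverage
  is 1, the exclusion rule is relaxed — otherwise a single-donor library
  could not be assembled at all.
* **Junction breakpoints** come only from consensus-interval ends; interior
  disagreements between replicates are already absorbed by the consensus
  rule.
* **Randomness**: one master seed; each of the 2·n haplotypes gets an
  independent child seed via `numpy` seed-sequence spawning, so assembly is
  reproducible and order-independent.
* **Diploid pairing** of assembled haplotypes is sequential and arbitrary:
  the genomes are population-level proxies, not individuals.

QC mirrors what one would run on a real reconstruction: allele fidelity to
provenance, the chunk-length bound, mask correctness
(missing ⟺ coverage < threshold), a KING-robust-style kinship check (no
pair of proxy genomes at third degree or closer, kinship < 0.0442), and
outgroup-f3 confirmation that the proxy panel shares the most drift with the
true source population.

## Statistics (`popstats`)

* **Hudson site F<sub>ST</sub>**: numerator
  (p_A−p_B)² − p_A(1−p_A)/(n_A−1) − p_B(1−p_B)/(n_B−1), denominator
  p_A(1−p_B) + p_B(1−p_A); sites with fewer than two called alleles on
  either side are excluded. Genome-wide values are the ratio of sums;
  negative per-site numerators stay in the sums and only the reported
  genome-wide value is clamped at 0.
* **Balanced pairwise F<sub>ST</sub>**: 9 diploid samples per population,
  drawn without replacement, 100 replicates; the replicate distribution is
  reported. Draws are made against name-sorted sample lists so the result
  is invariant to column order.
* **Relative difference**: (F<sub>ST</sub>(A,X) − F<sub>ST</sub>(B,X)) /
  (F<sub>ST</sub>(A,X) + F<sub>ST</sub>(B,X)); undefined (NaN) when the
  denominator is not positive. Antisymmetric and bounded by 1 for
  nonnegative inputs.
* **Outgroup f3**: mean over sites of (p_O−p_A)(p_O−p_B); standard error by
  weighted delete-one block jackknife over physical blocks (default 5 Mb, a
  conventional scale chosen to exceed LD range). Per-site
  available-sample frequencies are used; nothing is imputed. Drift ranking
  flags references with fewer than `min_sites` jointly called sites and
  breaks ties lexicographically.

## Screens (`selscreen`, `rarevar`)

Missingness filtering drops a site as soon as any group's genotype missing
rate exceeds 10%. Top-quantile screens compute the threshold as the k-th
largest usable value, k = ⌊n·q⌋, with all ties at the threshold included;
fewer than 1/q usable sites yields a warning and an empty screen. "Extra"
variants are the set difference top-q1(ancestor track) \ top-q2(present-day
track) over a shared site universe. The gradient screen requires the
reference frequency to be exactly fixed (a tolerance knob exists, default
0), an ancestor–reference difference ≥ 0.3, and a non-strict monotone
gradient oriented toward the allele absent (or fixed) in the reference.
Non-strict inequalities were chosen because sampled frequencies tie easily
at small n.

Rare-variant polarization keeps sites with MAF ≤ 20% in the polarizing
panel and a moderate/high predicted effect (effect classes are an input
table; no annotation engine is embedded); the minor allele is called
derived, and sites at exactly MAF 0.5 are dropped with a warning. The gene
screen applies four criteria: no derived allele in the reference
population; > 10% of target individuals carrying ≥ 1 derived allele; the
highest per-site derived frequency in the target < 5%; ≥ 2 qualifying
variants. The familial-aggregation test is a two-sided Fisher exact test
under the minimum-likelihood summation convention, with a conditional-MLE
odds ratio; degenerate margins give p = 1.

## Divergence dating and language trees (`auxinfer`)

Per time bin, the reference group's Ne mean and sample SD (ddof = 1) are
computed; the query is divergent where it falls outside mean ± 3 SD (with
SD exactly zero, any difference counts). The reported divergence time is
the midpoint of the **oldest** bin of the most recent run of consecutive
divergent bins — the earliest time range of the latest divergence, which is
the bin containing the split when divergence appears in all bins younger
than the split. The alternate reading (youngest bin of that run) is
selectable with `pick="youngest"`. The rule is invariant to rescaling all
Ne by a common constant.

Linguistic distance is D = (−log10 s) × 100 on a lexical-cognate similarity
matrix (s = 0 maps to an infinite-distance sentinel); trees are built by
neighbor joining (the standard distance-matrix method; the source work does
not commit to one) with label-sorted input for deterministic tie-breaking.

## Problem sizes used in the verification suite

Simulation scales were chosen to make each check statistically decisive at
desk scale: 50 kb / 5000-site regions for chunk-and-mask checks (dense
sites exercise every breakpoint case), 2 Mb / 2000–6000-site panels for
painting and kinship checks, 20 000 sites for F<sub>ST</sub> parameter
recovery (Monte-Carlo SE ≈ 0.0007), and 20-seed batteries for the
stochastic end-to-end properties. The admixture proportion in the dense
verification run is 0.2 so that candidate coverage genuinely fluctuates
around the 12-of-60 mask threshold and both masked and reconstructable
regions occur.

## Known limitations

* The painter's collapsed population-frequency emissions ignore within-donor
  LD; on real data a Li–Stephens painter will be more accurate. The module
  boundary (tract files in, tract files out) makes the swap trivial.
* Site independence in the generator means painting accuracy figures from
  the synthetic suite are optimistic.
* Single chromosome per panel; multi-chromosome inputs are processed
  per-chromosome by the caller.
* All inputs are assumed forward-strand biallelic SNVs; no strand flipping.
* The reconstruction cannot recover ancestry absent from the candidate
  library: regions where the target ancestry did not survive in any donor
  are masked, not imputed.
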