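# Methods

This note documents the models, estimators, and numerical choices behind
`ylineage`, and what the synthetic-data generator does and does not emulate.

## The three marker layers

**Layer 1 — SNP haplotypes.** A haplotype is a distinct vector of
call-strings over a fixed marker panel. Because many Y markers sit inside
repeated fragments, a site can show a *double base call* (`G/A`): divergent
repeat copies carrying different bases on a haploid chromosome. Double
calls are modelled as atomic third states — `G`, `A`, and `G/A` are three
distinct site states, each at unit distance from the others. Haplotype
names (`SHT1`, `SHT2`, …) are assigned in descending carrier frequency with
lexicographic tie-breaks, so naming is a deterministic function of the data
(the original study's numbering follows data-entry order, which is not
recoverable). Samples with any missing panel call are excluded from
collapsing and logged; they are never imputed.

**Layer 2 — copy number.** Relative quantification against a two-copy
autosomal reference:

    CN = 2 · E_t^(−mean Ct_target) / E_r^(−mean Ct_reference)

with amplification efficiencies `E ∈ (1, 2]` defaulting to 2 (perfect
doubling), optionally fitted from a dilution-series standard curve
(`E = 10^(−1/slope)`). The 2× anchor makes equal mean Cts at equal
efficiencies read as exactly two copies. QC follows the bench rule: a
triplicate whose Ct range exceeds 0.3 cycles is flagged `retest` and its
sample-locus cell is withheld from every downstream layer (excluded, never
imputed). A `1e-9` guard keeps a range of exactly the threshold passing
despite binary rounding. Continuous estimates snap to the locus's ladder of
admissible integers by minimising `|log2(ladder) − log2(CN)|` — log scale
because Ct error is multiplicative in template copies — with exact ties
resolved to the smaller value and flagged ambiguous. Per-population
summaries use the lower-middle median so reported medians are always
observed integers; CNV polymorphism is unbiased gene diversity
`(n/(n−1))(1 − Σp_k²)` over integer CN states (the statistic behind the
published per-locus polymorphism table is unstated; gene diversity is this
package's choice and only its structural properties are asserted).

**Layer 3 — allele-specific copy number.** At a double-call locus with
integer total `N ≥ 2`, the admissible splits are `(a, N−a)` with
`1 ≤ a ≤ N−1` (a heterozygous site needs at least one copy of each allele).
The resolver picks `argmin_a |a/N − RBV|`; if the best two candidates are
within `tolerance` (default 0.02, the typical accuracy of pyrosequencing
allele quantification) of each other in this objective, the call is
ambiguous and the runner-up is reported. Exact inversion of clean ratios is
guaranteed whenever `tolerance < 1/(2N)`. Pattern censuses are keyed by
allele order, so `3:2` and `2:3` are distinct patterns (they are distinct
paternal lines). A retest copy number blocks split resolution for that
sample-locus.

## Layered refinement

Refinement is strictly nested: the allele-split partition refines the CN
partition, which refines the SNP-haplotype partition. Unknown entries (QC
retests, unresolved splits, dropouts) are agnostic — they never split a
group. Concretely, samples group by the *signature* of their known entries;
a signature whose entries are a strict subset of exactly one better-informed
signature (agreeing wherever both are known) is absorbed into it, while a
partial signature compatible with several groups stays in its own coarser
group. This absorption rule was chosen over pairwise-compatibility closure
(union-find), which let a single poorly-genotyped sample bridge two
well-resolved lines into one; under the absorption rule an unresolved
sample can remain unassigned but can never merge resolved lines. A split
whose copies do not sum to the sample's integer CN raises a validation
error naming sample and locus.

The joint distance between layered profiles is
`w_snp·Hamming + w_cnv·Σ|log2 CN_x − log2 CN_y| + w_ascnv·(#split mismatches)`
with default weights (1, 1, 1) — the published joint tree states no
weighting, so the weights are explicit parameters. Log2 copy-number
differences reflect the multiplicative ladder (1→2→5→10→20 steps count
roughly equally). Unknown entries contribute zero, making the distance a
semimetric on partially-known profiles and a metric on fully-known ones;
zeroing the CNV and AS-CNV weights reproduces the SNP-only tree exactly.

## Diversity estimators

Haplotype diversity uses Nei's (1987) unbiased estimator and variance:

    h = n/(n−1) · (1 − Σp_i²)
    V(h) = 2/(n(n−1)) · {2(n−2)[Σp_i³ − (Σp_i²)²] + Σp_i² − (Σp_i²)²}

These were validated by reproducing the printed h *and* SE of the
published per-population table from integer partitions of the printed
sample sizes; a brute-force enumeration in the test suite shows each
fixture partition is the *unique* partition matching its printed row.
Nucleotide diversity is computed from haplotype frequencies with the same
unbiased weighting, `π = n/(n−1) · Σ_{u<v} 2 p_u p_v d_uv / L`, and equals
the explicit all-sample-pairs mean to 1e-12 (property-tested). The sites
denominator `L` is an explicit parameter because per-population alignment
lengths are generally unknown; its standard error uses Nei's stochastic
variance `V(π) = (n+1)π/(3(n−1)L) + 2(n²+n+3)π²/(9n(n−1))`.

## Networks and trees

The median-joining network iterates: (i) build the ε-relaxed minimum
spanning network over the current node set (distance levels ascending; a
pair links when its endpoints were in different components before its
level; ε=0 stops at the connecting level); (ii) for each connected triplet
(two links sharing a node) compute quasi-medians — site-wise majority
consensus, expanding over all observed states where all three differ — and
add the novel medians whose connection cost is within ε of the round's
minimum; (iii) repeat to fixation; (iv) drop obsolete medians (degree ≤ 2
in the spanning network over the final node set — with a metric distance
such a median can never shorten the network). All sites carry weight 1 by
default. MP pruning keeps exactly the links and median vectors lying on at
least one minimum-length spanning tree of the observed haplotypes: exact by
median-subset enumeration up to 12 nodes (edge membership in some MST via
the cut property), heuristic above that (iterative deletion of links on no
MST and of degree-≤2 medians, in sorted order). On infinite-sites data the
pruned network is a tree whose total length equals the segregating-site
count.

UPGMA is standard average linkage on site-difference (not proportional)
distances — the choice affects branch lengths, never topology — with node
height half the merge distance and ties broken by lexicographically
smallest representative labels, so Newick output is byte-reproducible.
Every tie-break in the package (naming, snapping, medians, edge ordering)
is lexicographic for the same reason.

## Synthetic data

The generator states one fixed world (defaults are not tuning knobs):

- 302 samples across 5 populations; a 14-site panel of which 6 sites lie on
  multi-copy fragments — the scale of the study system it emulates.
- A random bifurcating genealogy (uniform coalescent-style merges) with
  Poisson(θ) mutations per branch under infinite sites; θ defaults to
  `14/(2n−2)` so the expected mutation count matches the panel size.
- Copy numbers start on the geometric ladder {1, 2, 5, 10, 20} (the values
  the published CN table reports) and take stepwise ladder moves with
  probability 0.05 per branch per locus; an existing allele split rescales
  proportionally when the total changes, and collapse to one copy fixes one
  allele.
- A mutation landing on a multi-copy locus with CN = N hits k ~ U{1, N−1}
  repeat copies, creating a double call with true split (N−k, k); splits
  drift by ±1 copy at rate 0.05 per branch.
- qPCR: reference Ct ~ Normal(20, 0.1) per replicate, target Ct shifted by
  −log2(CN/2) with the same noise. The bench retest protocol is emulated: a
  triplicate failing the 0.3-cycle rule is redrawn, at most 3 attempts
  (without this, ~25% of cells would fail QC — far more missingness than a
  real study retains); residual failures stay flagged.
- RBV = a/N + U(±1/(4N)), clipped to (0, 1) — noise small enough that exact
  recovery is expected, which the tests confirm.
- Genotype dropout 0.02 per call, applied last (the study reports
  "successfully genotyped" subsets without a rate; 2% is a realistic
  genotyping-failure rate, chosen once).

What a green end-to-end test establishes: with this noise model the
pipeline recovers ≥95% of pass-flag copy numbers and splits and the refined
partition equals the truth partition over fully-resolved samples. What it
does not establish: robustness to demographic structure (bottlenecks,
migration), to assay biases (efficiency drift, probe cross-reaction), or to
recurrent/back mutation — none of which the generator emulates. Note the
default world is only approximately infinite-sites at the *call* level:
copy-number collapse can revert a double call to a single base, so strict
perfect-phylogeny checks use a no-drift configuration
(`cn_change_rate=0, split_change_rate=0`).

## Degenerate inputs and edge rules

- Empty collapse input → empty list with a warning; n < 2 → diversity
  undefined (error), never 0.
- Empty CN summary cells are reported missing, never zero.
- `total_cn < 2` cannot host a heterozygous split (error).
- Distance-matrix validation enforces symmetry, zero diagonal,
  non-negativity; UPGMA refuses n < 2.
- All writers end files with a newline; readers skip `#` provenance lines.

## Known limitations

- The MJN implementation targets ε = 0 with unit weights (the published
  setting); large ε values can make quasi-median expansion expensive and
  are capped per triplet.
- MP pruning above 12 nodes is heuristic and may retain slightly more than
  the exact MST union (it never removes a link that is on one).
- Per-sample genotypes of the emulating study are not published, so no
  fixture reproduces its actual networks; structural properties are tested
  on synthetic data instead.
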