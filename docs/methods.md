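# Methods

This note documents the statistical models, defaults and numerical choices
behind `forgen`, what the synthetic-data generators do and do not emulate,
and the design decisions taken where the design was genuinely open.

## Cross and read-count simulation

**Recombination model.** Gametes are simulated per chromosome as a Markov
walk over map positions: the parental source of the first position is
uniform, and between adjacent positions at genetic distance Δd cM the source
switches with probability r = (1 − e^(−2Δd/100))/2, the inverse Haldane map
function. This is the standard no-interference model; real meioses show
strong positive crossover interference, so the simulator *overstates* the
rate of double crossovers within short intervals (see Limitations). Causal
loci may fall between markers; they are carried through the same walk as
extra map positions, with genetic coordinates from the constant-rate map
(cM = bp × cM/Mb ÷ 10⁶).

**Phenotype model.** Recessive: an individual is mutant iff homozygous for
the mutant allele at any causal locus. With two loci this is duplicate
recessive epistasis; the F2 mutant frequency is 1/2 − (f_ab)² where f_ab is
the double-mutant gamete frequency (r/2 in repulsion, (1 − r)/2 in
coupling), which reduces to the familiar 7/16 at r = 1/2.

**Bulk selection.** A mutant bulk of size B is drawn uniformly without
replacement from the phenotypically mutant individuals; with
misclassification rate ρ each slot is independently swapped for a random
wild-type individual. A bulk can only be collected when at least B mutants
segregate; since an F2 of 200 yields Binomial(200, 1/4) ≈ 50 mutants, the
experiment driver (`simulate_bsa_experiment`) redraws the cross with a
shifted sub-seed when a draw falls short, i.e. it samples the conditional
distribution given that the experiment is feasible — exactly the
conditioning implicit in any real pooled bulk.

**Read counts.** Equal DNA contribution per bulk member is assumed
(equal-amount pooling). Per site, depth ~ Poisson(λ) with λ the mean depth,
and alt reads ~ Binomial(depth, f(1 − e) + (1 − f)e) where f is the bulk
mutant-allele frequency and e the per-read error rate. Site quality is a
configured constant (default 150) standing in for a variant-caller QUAL;
per-read base qualities are not modelled, so the "minimum base quality 100"
filter is applied to the site record.

**Determinism.** All generators take explicit seeds; internally
`numpy.random.SeedSequence` is split per chromosome/stage so adding a
downstream draw never perturbs an upstream one. Same arguments + seed ⇒
bit-identical output.

## BSA mapping

Per-site frequency is alt/(ref + alt), with sites failing depth < 30 or
quality < 100 (defaults, configurable) flagged and excluded from smoothing.
The rolling average supports windows in bp (mean of passing sites within
±w/2 bp) and in marker count (centred rank window of w sites, clipped at
chromosome ends). The bp default of 100 follows exome-BSA convention but is
far smaller than typical exome SNP spacing — with one SNP per window the
"smoothed" track equals the raw track — so a marker-count window
(e.g. w = 5) is recommended and used throughout the examples; both units
are first-class.

Candidate regions are maximal runs of smoothed frequency ≥ 0.9 with ≥ 5
supporting sites (defaults); the peak is the leftmost maximum. Chip-style
pooled calls are classified heterozygous in [0.35, 0.65], homozygous mutant
at ≥ 0.9, intermediate otherwise; the bands are package defaults exposed in
the configuration, chosen to mirror how pooled chip intensities are read in
practice.

**Introgression detection** restricts to markers polymorphic between the
recurrent and donor parents, then reports maximal runs of ≥ 3 donor-matching
markers tolerating ≤ 1 interior non-donor call (defaults); bounds are the
outermost donor-matching markers, i.e. resolution is one flanking marker.

**Fine mapping** implements recessive exclusion mapping. Each mutant
individual restricts the causal locus to the union of its
homozygous-mutant marker runs, opened at the flanking non-homozygous
markers; the feasible region is the intersection over mutants. Wild-type
individuals are almost uninformative (a heterozygote excludes nothing), with
one exception: a wild-type line homozygous for the mutant-linked allele at
every marker of an entire remaining sub-interval rules that sub-interval
out, which is the natural disambiguator when the mutant intersection leaves
several disjoint sub-intervals. If several still remain, the widest
(leftmost on ties) is reported. Mutants with *no* homozygous-mutant marker
in the search interval (possible double recombinants or phenotyping errors)
carry no usable constraint and are skipped with a warning; an empty
intersection raises, signalling phenotyping or genotyping error. Adding
mutant individuals can only shrink the interval (intersection is monotone).

The exclusion logic assumes no double crossover between the adjacent
markers flanking the causal locus. Under the no-interference simulator this
holds only approximately: at ~2 cM marker spacing a misleading double
recombinant appears at rate ~10⁻⁴ per gamete, so the guarantee tests run at
fine-mapping density (~0.5 cM spacing), the regime the method is used in;
real meioses suppress such events further through interference.

## Two-locus segregation genetics

`estimate_r` maximises the binomial log-likelihood of the mutant class count
under p_mut(r) for the given phase, by a 501-point grid scan refined with
bounded scalar minimisation (tolerance 1e-8). The 95% CI is the
likelihood-ratio interval (drop of 1.92 log-units, found by root bracketing
to 1e-10); estimates at 0 or 0.5 are flagged as boundary cases. Phenotype
counts alone carry little information about r (dp/dr = −r/2), so estimates
are noisy at moderate n and the inversion's boundary truncation gives a
small downward bias (≈ −0.01 at r = 0.2, n = 5000); the recovery test
budgets for this. cM↔Mbp conversion is reported only when the user supplies
a local cM/Mb rate; no genome-wide constant is assumed. Both Haldane and
Kosambi map functions are provided since segregation data alone cannot
distinguish them.

## Haplotype networks and isolation by distance

Site filtering retains sites with ≥ 98% homozygous calls, then drops
accessions with any heterozygous or missing call at retained sites (both
removals logged). Haplotypes are identical allele vectors, ordered by
descending count then first appearance.

The **minimum spanning network** is the union of all minimum spanning trees
over Hamming distances, built Kruskal-style per distance class (an ε > 0
relaxes each class to admit edges up to ε longer). The **median-joining
network** starts from the observed haplotypes and repeatedly proposes the
site-wise majority (median) vector of every node triple, greedily adding the
median that most reduces the minimum-spanning-tree length of the node set
until no median helps; inferred medians with network degree ≤ 2 are then
pruned (a majority median lies on the geodesic between any two of its
parents, so pruning never lengthens the network). On small inputs
(≤ 4 haplotypes × ≤ 6 sites) the result attains the exhaustively verified
Steiner-minimal spanning length; no optimality guarantee is claimed for
large inputs, matching the heuristic character of published median-joining
implementations.

**Ritland kinship** for fully homozygous lines uses the product-moment
estimator f_l = (x_i − p_l)(x_j − p_l)/(p_l(1 − p_l)) per biallelic locus
and combines loci as a ratio of sums with per-locus weight k_l − 1 = 1,
i.e. the unweighted mean. Within-sample allele frequencies are the default
(the off-diagonal mean is then exactly −1/(n − 1), a property the tests
check); monomorphic loci are undefined under the estimator and must be
removed first — their presence raises.

**IBD regression** fits ordinary least squares of pairwise kinship on
transformed pairwise great-circle distance (haversine, Earth radius
6371.0088 km) over unordered pairs. The default transform is the natural
log, with zero distances replaced by a 1 km offset (warned); raw distance is
available. Significance comes from permuting the coordinate labels among
accessions — node-label permutation respects the pairwise dependence
structure, unlike permuting matrix cells — with
p = (1 + #{permuted slope ≤ observed})/(n_perm + 1), one-tailed for the
negative slope expected under isolation by distance (default n_perm = 9999).
Distance-class binning (as in SPAGeDi) is not implemented; the regression is
on continuous distances.

## Epidermal patterning statistics

Cell files are one-dimensional token sequences; two-dimensional effects
(subsidiary recruitment across neighbouring files) are reduced to the X
token because the quantification is per-file event counting. Events are
maximal runs of specialised tokens; runs touching a file end still count.
Stomatal event classes — single, cluster (by size), shared-subsidiary — are
kept mutually exclusive (an X-joined run is scored once as
shared-subsidiary, not additionally as a cluster); gaps of ≥ 2 pavement
cells between events are tallied separately as wide-spacing occurrences and
are not part of the event partition. A silica–cork pair token C scores as
two cells (silica + cork) in the cell index; silica-file events are banded
as normal pair / single-missing (≤ 2 cells) / 3–5 / 6–9 / ≥ 10. The
cell-file simulator alternates specialised and pavement tokens and converts
each pavement cell following a specialised cell with the violation
probability v, so the expected events per file with m specialised positions
is 1 + (m − 1)(1 − v) — the inversion used by the recovery tests.

## Problem sizes in the tests

The test suite runs the full pipeline at desk scale: F2 populations of
200–20,000, bulks of 40–600, 100 localisation replicates, 200
recombination-recovery replicates, 500 null permutation replicates at
n_perm = 199, and exhaustive Steiner verification on ≤ 4 haplotypes × ≤ 6
sites. These sizes were chosen so each statistical check has the power its
tolerance needs (3σ binomial bands, KS uniformity at p > 0.01) while the
whole suite stays fast.

## Known limitations

* No crossover interference; no mutation, no genotyping-error model for
  chip calls beyond i.i.d. missingness; no segregation distortion.
* Read counts are generated directly (no sequence-level simulation,
  alignment or variant calling), so alignment artefacts and reference bias
  are out of scope.
* The site-quality filter is a site-record threshold, not a per-read base
  quality model.
* The median-joining construction is greedy; optimality is verified only at
  small scale.
* Passing tests demonstrate correctness of the computations under the
  generators' assumptions, not robustness to the real-data artefacts listed
  above.
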