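# Methods

This note documents the models, rules and numerical choices behind
`disorderome`, in the spirit of a statistics package's methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Disorder-region calling

All region logic operates on binary per-residue states (1 = disordered).
Score tracks are binarized at a configurable cutoff, default 0.5 — the
conventional threshold for score-emitting disorder predictors; tracks
that already carry binary calls pass through unchanged.  Positions are
1-based and intervals closed in memory; the BED-like region writer is
the only place 0-based half-open coordinates appear.

*Long disorder* at threshold N means a maximal disordered run of ≥ N
consecutive residues.  %longN is computed over **all** proteins of a
proteome: proteins shorter than N can never qualify but stay in the
denominator, so %long80 ≤ %long50 ≤ %long30 holds by construction and is
enforced on the profile type.

*Completely disordered* follows a three-step rule: (1) every disordered
run shorter than 5 residues is reclassified as ordered — residues are
never deleted, so flanking ordered runs merge and the coordinate system
is conserved; (2) if any ordered run of ≥ 30 residues survives, the
protein is not completely disordered (the run could nucleate regular
structure); (3) otherwise the protein qualifies iff a disordered run of
≥ 30 residues remains.  Short disordered runs touching a protein
terminus are reclassified like any interior run; nothing in the rule's
rationale distinguishes termini, and the uniform treatment keeps the
operation a pure function of the run decomposition.

## Proteome profiles and Z-scores

Raw metrics are carried on the 0–100 percent scale throughout, matching
how such values are reported.  Standardisation is the usual
`z = (raw − mean) / sd` against a background distribution over many
proteomes.  Shipped defaults cover %long30 for three predictors (MD
14.6/4.2, NORSnet 2.5/2.0, IUPred 7.5/5.5, from a 1,613-proteome
compilation); other predictor/metric pairs load from YAML
(`predictor: {metric: [mean, sd]}`) or are recomputed from user panels
with `background_from_profiles`.  Recomputation uses the sample standard
deviation (ddof = 1) by default — the conservative choice when the panel
is a sample of available proteomes — with a `ddof=0` switch for the
population convention.

## Habitat classification

Growth metadata map to habitat classes by explicit rules: optimum
45–80 °C → thermophile; > 80 °C → hyperthermophile; optimum ≤ 20 °C
*and* maximum ≤ 20 °C *and* minimum ≤ 0 °C → psychrophile (all three
bounds required: a cold optimum alone does not make an obligate
psychrophile); otherwise minimum ≤ 5 °C → psychrotolerant ("grows at or
close to 0 °C"; the 5 °C cut is configurable since no standard number
exists); NaCl optimum ≥ 25% → halophile; pH optimum > 8 → alkaliphile;
eukaryotes are their own class; anything else is mesophile.  An organism
may match several definitions; every match is reported and the primary
label is resolved by a configurable priority, **salt > temperature > pH**
by default (salt being the strongest single correlate of disorder
content), with multi-match resolutions logged.

Grouping (by habitat, phylum, or a metadata factor such as oxygen
requirement) silently never tests groups with fewer than two organisms:
they are removed before any statistics, with a warning for records
missing the key.

## Grouped statistical decision flow

Inputs are one raw disorder value per organism; group location is
summarised by the median.  The flow is deterministic:

1. **Brown–Forsythe Levene** (median-centred) across all groups tests
   variance homogeneity at α = 0.05.
2. If homogeneous, **Kruskal–Wallis** (tie-corrected, χ² p-value) tests
   for any distributional difference.  No rejection ends the analysis.
3. On overall Levene failure, or on Kruskal–Wallis rejection, every
   unordered pair is examined: a pairwise Levene test first (per-pair
   α = 0.05), and only pairs with acceptably equal variances receive a
   two-sample **Wilcoxon rank-sum** (Mann–Whitney) test — exact null
   distribution for small tie-free samples, normal approximation with
   tie correction otherwise.  Marks: `*` for p < 0.05, `**` for
   p < 0.005.  No multiple-testing correction is applied by default;
   Holm adjustment is available as an explicit helper.

The rank comparison is two-sample rather than the paired signed-rank
variant because habitat/phylum groups are unpaired and of unequal size,
where a signed-rank test is undefined; a paired variant is available
when pairing is declared and sizes match.

Because pairwise testing is gated behind an overall rejection, the
unconditional per-pair mark rate under an exchangeable null is well
below the nominal α (the gate opens with probability ≈ 2α); the flow is
conservative by construction.  The acceptance suite therefore checks
calibration at two levels: the marking machinery itself (pairwise rank
tests applied to every pair of a null panel) must mark at ≈ α, and the
full gated flow must mark nothing in ≥ 90% of null panels while staying
below α per pair.  Degenerate inputs are defined away explicitly:
zero-spread groups make Levene undefined (error at the overall stage,
trivially-equal-variances at the pairwise stage), and all-identical
samples yield a Kruskal–Wallis of (0, p = 1).

## HVAL homology

The HSSP curve `p(L) = 480·L^(−0.32·(1+exp(−L/1000)))` for L ≤ 450 and
19.5 beyond (clamped at 100%) gives the identity threshold at which
homology becomes plausible for an alignment of L columns; HVAL is the
identity's distance from the curve.  The curve has a shallow minimum
near L ≈ 420 and re-rises by < 0.04 points before the plateau cut — a
property of the published parameterisation, preserved rather than
smoothed.  Homolog maps keep every non-self alignment with HVAL ≥ the
cutoff (ties at the cutoff are included); A–B/B–A duplicate rows
collapse to the higher HVAL.  The relation is deliberately
many-to-many: no ortholog/paralog discrimination is attempted.

Relatedness tables report, per organism, the percentage of its proteins
with ≥ 1 homolog and the percentage that are related *and* carry long
disorder in their own track, each with the binomial standard error
`100·√(p(1−p)/n)`.  The disorder-overlap counts classify each homolog
pair by which side carries long disorder; the expected number of
disordered related proteins under independence is
`(# related proteins) × (proteome-wide long-disorder fraction)` — the
natural null against which an observed deficit (disorder avoided in
shared proteins) or excess is read.

A small Smith–Waterman aligner (BLOSUM62, gap open −11 / extend −1,
sequences ≤ 2,000 residues) exists so synthetic tests can produce
alignment records end-to-end; large-scale all-vs-all searches are
expected to arrive as BLAST tabular files.

## Synthetic-data model

Disorder along a protein is a stationary two-state Markov chain with
stay-probabilities `p_stay_ordered` and `p_stay_disordered`, i.e.
geometric run lengths with means `1/(1−p_stay)`.  The probability that
a protein of length L contains a disordered run ≥ 30 residues is
computed by an exact dynamic program over (state, current run length);
the generator bisects the ordered→disordered entry probability until the
expected %long30 over the length distribution matches a requested
target (the DP is validated against full enumeration of all chains at
small L in the test suite).  Calibration uses a deterministic 64-point
quantile grid of the length distribution and is memoized per parameter
set.  An unattainable target raises with the attainable range.

Defaults: 500 proteins per proteome, lengths ~ Normal(300, 100²)
truncated at 50 (a typical prokaryotic length scale),
`p_stay_disordered = 0.97` (mean disordered run ≈ 33 residues, the
scale of "long" disorder), score noise Uniform(0, 0.3) added toward the
opposite state so that binarizing at 0.5 recovers the true states
exactly.  Sequence letters are drawn from an average proteome
composition; optional per-letter multipliers enrich disorder-promoting
residues (P/E/S/Q/K up, aromatics/aliphatics down) inside disordered
runs.

Habitat panels give every organism of a group the target
`baseline + effect × background sd` (baseline defaults to the MD
%long30 background mean 14.6, sd 4.2), attach the group label as the
habitat class with representative growth metadata, and draw per-organism
seeds from a seed sequence so the panel is reproducible from one seed.
Homolog pairs are built by copy-with-substitution at a target percent
identity (realised identity within one point by construction) with a
40-residue disordered run placed on the requested sides.

**Simulation scale.**  The grouped-statistics studies in the test suite
use 150 proteins per organism (5 groups × 6 organisms, 1,000 null and
500 shifted panels).  Real proteomes are 10–50× larger; 150 proteins
give the organism-level %long30 a binomial noise of ≈ 2.9 percentage
points, below the 4.2-point background sd, which is the regime the
grouped tests are meant for.  What these simulations do show: the flow's
branches, gating, marking and power behave as designed under the stated
effect sizes.  What they do not show: anything about predictor error,
phylogenetic correlation between organisms, or length/composition
structure of real proteins — the generator's independence assumptions
are deliberately simplistic.

## Known limitations

* Disorder predictors themselves are out of scope; predictor identity
  is track metadata, and "loopy" vs "regular" disorder is carried only
  as that label.
* Duplicate removal during FASTA reading is by identifier (keeping the
  longer sequence); identical sequences under different ids are kept.
* The habitat rules take growth optima at face value; organisms
  described only qualitatively cannot be classified.
* Backgrounds shipped as constants cover %long30 only; comparisons on
  other metrics need user-supplied or recomputed backgrounds.
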