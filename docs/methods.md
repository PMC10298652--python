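# Methods

This note documents the models, conventions and numerical choices behind
il-toolkit, and what the synthetic-data tests do and do not establish
about real data.

## Coordinate frame

All internal coordinates are 1-based inclusive base pairs; a segment
`[start, end]` has length `end − start + 1`. BED export converts to
0-based half-open by `start − 1`, so the BED length `end − start` equals
the internal length. The `GenomeMap` (chromosome name, physical length in
bp, genetic length in cM) is the single coordinate frame; marker panels,
segments and diplotypes are validated against it.

## Meiosis and pedigree model

Gametes are simulated per chromosome with a crossover count drawn from
Poisson(cM/100), crossover positions uniform on the genetic map, and no
interference (the Haldane model). Genetic position is mapped to physical
position by a single linear interpolation per chromosome; this ignores
recombination-rate heterogeneity (pericentromeric suppression, hotspots),
which is acceptable because the simulator's role is to exercise the caller
and the statistics, not to model a specific karyotype. The starting
haplotype is chosen fairly, so a 0-cM chromosome transmits one intact
parental haplotype.

Populations advance by `backcross_to_recurrent` (one gamete from a
randomly drawn plant, fused with an all-recurrent gamete) or `self` (two
independent gametes from the same plant). These give the classical
expectations used for calibration: expected diploid donor dosage
(1/2)^(t+1) after t unselected backcrosses of the F₁, and expected
heterozygous genome fraction (1/2)^s after s selfing generations. Both
are verified by Monte Carlo within 3 standard errors (2,000 replicates in
the acceptance suite).

Every stochastic operation takes an explicit `numpy.random.Generator`.
There is no module-level random state; a seed therefore fixes a run
exactly, which the pipeline manifest (SHA-256 of every output) asserts.

## Genotyping model

True ancestry dosage at a marker maps to A (0 donor alleles), H (1) or
B (2). Observational noise is per-call and independent: with probability
`error_rate` the call is replaced by one of the two wrong codes uniformly;
with probability `missing_rate` it is set to NA (a call hit by both ends
up NA). Real genotyping errors are not uniform across codes
(heterozygote dropout dominates on most platforms) and missingness is not
independent of genomic context; the simple model is enough to test the
caller's NA-bridging and robustness options.

## Introgression calling

A candidate segment is a maximal run of donor-carrying calls (B or H)
along the sorted marker panel. An A call always terminates a run (no
smoothing); NA calls bridge a run by default (`bridge_missing=True`),
because at the marker densities this tool targets a missing call is far
more often a failed assay than a recombination signal. Runs with fewer
than `min_supporting_markers` (default 1) donor calls are discarded.

Two boundary conventions are exposed:

- **dense**: segment bounds at the positions of the first and last
  donor-carrying SNP of the run. The bound always underestimates the true
  tract, by less than one marker interval per side.
- **sparse**: each bound at the integer-floor midpoint between the
  outermost donor SNP and its flanking A SNP, splitting the uncertainty
  interval; appropriate for sparse panels.

A run touching a chromosome end has no flanking A SNP on that side: sparse
mode extends to the physical end (positions 1 or chromosome length), dense
mode stays at the terminal donor marker. Dense segments are therefore
always contained in sparse segments, a property-tested invariant.
Midpoints use integer floor for determinism in bp space.

Zygosity is heterozygous if any call in the run is H, else homozygous
donor; both B and H calls seed segments, so heterozygous residual tracts
are preserved and their treatment deferred to the statistics layer.

Size filters follow the two-threshold convention of IL programs:
segments ≥ 0.1 Mbp are *reported*; the strict subset > 0.55 Mbp are
*target-sized*. Filtering happens after NA-bridging and merging. A
segment of exactly the target threshold is reported but not a target.

On simulated truth with markers every 100 kb and no noise, dense calling
recovers every true donor tract spanning at least two marker intervals,
and every called boundary lies inside a true tract within one marker
interval of its breakpoint. A recurrent gap shorter than the marker
spacing can be invisible (two true tracts merge into one called segment);
the acceptance metric is therefore defined per called boundary.

## Coverage and background statistics

Donor-genome coverage is the length of the union (sweep over sorted
endpoints) of all ILs' segments, per chromosome and overall. Heterozygous
segments count toward coverage by default (`count_het=True`) — a
heterozygous introgression still represents the donor allele in the
library — with a flag to exclude them, since published coverage figures
rarely state their convention. Per-line background recovery uses allele
dosage: 1 − (homozygous bp + ½ heterozygous bp)/genome length. The union
is verified exactly against a 1-kb brute-force grid.

## Selection

The breeder's per-generation judgement is formalised as greedy weighted
set cover: repeatedly pick the candidate maximising
(new donor bp covered)/(1 + w·introgression count) until the coverage
target is met or no candidate adds coverage, then fill remaining slots by
highest background recovery. Candidates are sorted by line id first, so
selection is deterministic and invariant to input order. An unreachable
coverage target produces a best-effort selection with a shortfall report,
mirroring real programs in which some donor regions are never recovered.
For candidate pools of single-introgression lines the denominator is
constant and the classical (1 − 1/e) guarantee of greedy set cover
applies; the acceptance suite checks it against exhaustive optima on
instances of up to 12 candidates. The final-library mode runs the same
engine chromosome by chromosome (a tiling path, preferring
single-introgression lines) and reports uncovered gaps, which partition
the genome exactly with the covered union.

In the simulated breeding program, plants that have lost all donor
segments are excluded from selection — a segment-free plant cannot
contribute to an IL library, and the background-fill phase would otherwise
favour exactly those plants.

## Field-trial model and phenotype analysis

Phenotypes are generated under the model the analysis assumes:

    y = μ_location · (1 + Σ expressed percent effects/100)
        + block + G×L + ε

with Normal block, interaction and residual terms (block and G×L SDs
specified as fractions of the location mean, residual SD per location,
optionally via a CV). An IL expresses a QTL effect iff one of its
segments overlaps the QTL interval; zygosity is not dosage-weighted (IL
panels are essentially fixed lines). Control plants carry no QTL effects.
Fruit shape FS is never drawn independently: it is recomputed per fruit as
FL/FD, so its distribution is induced by its components. Default trait
means and dispersions are typical of a large oval non-climacteric melon
cultivar evaluated in Mediterranean spring trials (fruit weight ≈ 1.8–2.6
kg, SSC ≈ 10–14 °Brix), with two traits absent in one location to exercise
per-trait location masks. The default trial design is five randomized
blocks per location, two single-plant IL replicates per block and ten
control replicates (two per block), in up to three locations.

What the simulator does *not* emulate: segregation distortion and
selection-like persistence of heterozygosity, fertility/vigour loss linked
to particular donor regions, non-Normal residuals, spatial field trends
within blocks, and missing-data mechanisms other than per-trait location
masks. Passing tests therefore establish the correctness and calibration
of the *methods* under the stated model, not the field behaviour of any
particular germplasm.

### ANOVA

`two_way_anova` fits `value ~ location * line` by least squares with
sum-to-zero factor coding and Type III sums of squares (statsmodels
OLS/anova_lm; Type II available by flag), the default behaviour of the
common GUI statistics packages on unbalanced data. Blocks are excluded
from the default model, with a flag to include them. Empty location×line
cells raise a rank-deficiency error naming the cells. With one location
the model degenerates to a one-way genotype ANOVA, where F equals the
squared two-sample t — both identities are tested, and balanced-design
Type III SS are checked against the closed-form cell-mean formulas to
1e-8 relative error.

### Dunnett contrasts

Within each location, every IL mean is compared with the control mean
using the pooled within-group variance (N − g df):
T_i = (ȳ_i − ȳ_0)/(s·√(1/n_i + 1/n_0)). Under the global null the T_i are
equicorrelated multivariate t with ρ_ij = λ_iλ_j, λ_i = √(n_i/(n_i+n_0)).
The two-sided adjusted p-value 1 − P(maxᵢ|T_i| ≤ |t|) is computed by a
deterministic two-dimensional quadrature: 96-node Gauss–Hermite over the
shared control variate and 128-node Gauss–Legendre (against the exact
chi density, ν df) over the pooled-SD scale variable, truncated at the
10⁻¹² quantiles. Agreement with an independent randomized-QMC
implementation is within 2×10⁻³; the k = 1 case reduces to the Student t
p-value to ~10⁻¹² (clamped so adjusted ≥ unadjusted always holds
exactly); familywise error under a 5,000-replicate global-null simulation
falls in [0.04, 0.06] at α = 0.05. Percent effects follow the
percent-of-control convention: 100·(ȳ_i − ȳ_0)/ȳ_0.

### QTL calling

An IL is declared to affect a trait iff its Dunnett-adjusted p < α
(default 0.05) in at least `min_locations` (default 2) locations, with the
significant locations' percent effects concordant in sign (a flag disables
the concordance requirement; an effect flipping sign between locations is
interaction, not a main effect — the direction-concordance default is this
package's choice where the rule is usually stated without it). Per-location
Dunnett runs are used rather than a pooled analysis, so a location with
phytosanitary or other problems cannot drag the others. Under the default
design with residual CV 15 %, a planted −40 % fruit-weight effect is
called in >95 % of 200 simulated trials and null ILs in <5 % (observed:
100 % and ~0 %).

### Correlations and summaries

Pearson correlations are computed per location on fruit-level records with
pairwise-complete deletion, flagged significant at p < 0.01; pairs with
fewer than 3 complete records or a constant trait are NA. Per-line
summaries report the arithmetic mean, sample SD (n − 1) and count, with
the SD of a single record as NA.

## Problem sizes

The test and acceptance workloads are deliberately compact: toy genomes of
2–5 chromosomes (10–38 Mbp each), marker panels at 100–500 kb spacing,
2,000-replicate Mendelian calibrations, 5,000-replicate Dunnett null
simulations, 200-replicate QTL power runs and exhaustive set-cover
instances of ≤ 12 candidates. These sizes give 3-SE Monte-Carlo
resolution on every calibrated expectation while keeping the full suite
around half a minute of compute.

## Known limitations

- Linear cM↔bp interpolation and no crossover interference; no
  sex-specific maps.
- The caller is rule-based; no HMM over genotype likelihoods, so isolated
  genotyping errors inside a run split segments unless
  `min_supporting_markers` is raised.
- Selection optimises coverage and background only; fertility, vigour and
  phenology constraints that shape real programs are out of scope.
- Categorical traits (rind colour, abscission layer) are carried through
  the data model but analysed only descriptively, and no
  multiple-testing correction is applied across traits.
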