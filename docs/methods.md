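# Methods

`stcpipe` implements a four-stage analysis of short ordered expression
series — the design it targets is three conditions (a control, an exposed
condition, and a later follow-up) with a small number of array replicates
each — together with a synthetic-data generator that provides ground truth
for every stage.

## Random-variance-model moderated F-test

With r ≈ 3 replicates per condition, the per-gene residual variance s²_g
(pooled within groups, d = S − m degrees of freedom) is too unstable to
support a classical one-way F-test.  The random variance model assumes the
inverse variance of each gene is drawn from a gamma prior,

    1/σ²_g ~ Gamma(a, scale = b),

under which the marginal law of the residual variance is

    s²_g · a · b ~ F(d, 2a).

The hyperparameters are estimated by maximizing the likelihood of the
observed s²_g under this marginal (L-BFGS-B on (log a, log b), box
constraints a ∈ [10⁻³, 10⁶], b ∈ [10⁻⁹, 10⁹], method-of-moments start).
The per-gene test statistic replaces s²_g by the shrunken variance

    σ̃²_g = (d·s²_g + 2/b) / (d + 2a),

and refers MS_between/σ̃²_g to F(m − 1, d + 2a): the prior contributes 2a
extra denominator degrees of freedom, which is the entire point at three
replicates.  All variance computations are on log2 signals; the inputs are
positive linear-scale values (e.g. RMA-normalized array signals), and
log2 is the scale on which such normalizations are additive.

Two limiting behaviours are worth recording.  As the prior vanishes
(a → 0 with 1/b → 0) the moderated statistic converges to the textbook
one-way F — the suite checks this against an independently coded ANOVA.
As the prior concentrates (a → ∞ with a·b fixed) the denominator tends to
the constant prior variance 1/(a·b), not to s²_g; when the observed
variances show no between-gene dispersion at all, the likelihood increases
without bound in a, so the fit returns a at its upper bound with a warning
rather than failing silently.

Genes are called differentially expressed when both the raw p-value and
the Benjamini–Hochberg adjusted value are below 0.05.  The step-up BH
procedure is the FDR adjustment because it was the standard default of the
array-era tooling; both thresholds are configurable.

## STC model-profile clustering

Candidate trajectories are enumerated independently of the data: over m
ordered conditions a profile is a vector of m − 1 per-transition changes,
each in {−c, …, +c} "units", anchored at 0 in the first condition.  The
all-constant vector is excluded, giving (2c+1)^(m−1) − 1 profiles — 8 for
m = 3, c = 1.  Profile ids follow the lexicographic order of the change
vectors with −c < … < 0 < … < +c.  This numbering is not arbitrary: for
the three-condition design it makes profile 5 the rise-then-fall
trajectory (0, 1, 0), profile 6 rise-then-sustain (0, 1, 1), profile 7 the
steady rise, profiles 0–2 the falling-first shapes and 3–4 the flat-first
shapes, which is the convention the field's short-time-series tooling
prints.

Each gene (normally the DEG set) is summarized per condition by the
geometric mean of its linear replicate signals — identical to the
arithmetic mean of the log2 replicates — and transformed to log2 ratios
against the first condition, so the first entry is always 0.  The gene is
assigned to the profile whose position vector maximizes Pearson
correlation with its ratio vector; since "one unit" is defined per gene by
correlation, the assignment is scale-free.  The anchored zero entry is
included in the correlation (excluding it would leave only m − 1 = 2
points for the canonical design, making the correlation degenerate).
Constant ratio vectors have undefined correlation and are left
unassigned; exact ties resolve to the lowest profile id (correlations are
rounded to 12 decimals first so that analytically tied values compare
equal in floating point).

Significance per profile compares the observed count with the average
count over all m! orderings of the condition columns (ratio vectors are
re-anchored to the permuted first condition and re-assigned; the identity
ordering is included in the average).  The one-sided test is Fisher's
exact on the 2×2 table [observed, n − observed; round(expected),
n − round(expected)], "observed greater", at α = 0.05, with expected
counts rounded half-up to integers because the exact test needs integer
cells; an exact binomial test against expected/n is available as an
alternative (`method="binomial"`).  No multiple-testing correction is
applied across the 8 profiles; the raw-p convention is deliberate and
documented rather than hidden.

## Gene-set over-representation

For a list of n genes from a measured universe of N, and a set with Nf
members in the universe of which nf are in the list, the enrichment ratio
is Re = (nf/n)/(Nf/N).  The Fisher p-value is the one-sided
hypergeometric upper tail P(overlap ≥ nf); a chi-square p from the same
2×2 table (no continuity correction) is reported alongside, but Fisher
drives the significance flag at α = 0.05 — one-sided because
over-representation is the question being asked.  The universe is the set
of genes on the expression matrix, not the annotation file, matching the
background logic of array data; set members absent from the universe are
dropped during harmonization, and list genes missing from the universe
are dropped with a logged count.  Degenerate tables (a zero margin) give
a NaN chi-square p rather than a fabricated value.  Raw p-values decide
significance; a BH column is provided for users who want it.

## Co-expression network

Over a selected gene list (by default the genes assigned to the
rise-then-fall profile and its mirror — ids 5 and 2 in the canonical
numbering), Pearson correlations of log2 signals are computed across all
samples of all conditions jointly, since the shared trajectory is the
signal of interest.  An edge joins two genes when |r| ≥ τ; the default
τ = 0.8 is a common operating point for array co-expression maps of this
size, but it is a genuine free parameter — published hub tables depend on
it, which is why this package asserts recovery of planted structure
rather than any particular published gene ranking.  Edges keep the signed
correlation as weight; constant genes are dropped with a warning.
Per-node metrics are degree, clustering coefficient 2e_i/(k_i(k_i−1))
(0 by convention for degree < 2), and the k-core number (largest k
surviving iterative removal of degree-< k nodes).  Hubs are ranked by
degree descending, ties broken by clustering coefficient then gene id so
the ranking is total and reproducible.

## Synthetic data

The generator emulates the three-condition, three-replicate design.
Per-gene log2 variances are inverse-gamma (reciprocal of a
Gamma(a, scale=b) draw, floored at 10⁻⁶), exactly the moderated test's
prior, so hyperparameter recovery and p-value calibration are testable on
their own model.  A configurable fraction of genes is planted on unit
profiles: group log2 means are baseline + effect·position; the rest stay
flat at baseline.  Replicates are i.i.d. normal in log2 and the matrix is
exponentiated, so the within-group geometric mean of the linear values is
an unbiased estimator of the planted log2 mean — the truth is analytically
known at every stage.  Defaults: baseline log2 mean 8 (mid-range array
signal), effect 1.0 log2 per unit step (a twofold change, the size such
experiments are designed to detect), prior (a, b) = (2, 1).  Recovery
fixtures use (a, b) = (8, 2), which puts the median per-gene sd near
0.25 — a realistic post-normalization residual noise level for arrays and
the regime in which profile assignment is expected to be ≈ 90% accurate at
effect 1.0.  The demonstration pipeline plants profiles 5 and 6 at
fractions 0.10 and 0.05 of 2000 genes, echoing the qualitative finding
the design targets: a transient response plus a sustained one.

Gene-set fixtures are uniform random sets plus "planted" sets drawing at
least 80% of members from one profile's true genes.  The hub fixture
gives one gene unit-variance log2 fluctuations, correlates module members
with it at ρ (members are then mutually correlated at ρ², which is what
makes the hub identifiable), and leaves the background independent.

What the generator does *not* emulate: probe-level effects, batch
structure, missing values, correlated null genes, heavy-tailed noise, or
real pathway topology.  Passing recovery tests therefore demonstrates
correctness of the algorithms under their own model assumptions, not
performance on any particular real dataset.

## Problem sizes and numerical choices

The test suite's simulation scales are chosen to make the statistical
assertions sharp while keeping the default run fast: calibration uses
2000 null genes (binomial sd of the p<0.05 rate ≈ 0.005, so the
[0.035, 0.065] band is ±3σ), hyperparameter recovery uses 10⁴ genes,
profile recovery uses 50 seeds × 500 genes, and the graph-metric oracles
cover every 4-node graph exhaustively, random graphs to 12 nodes against
an exponential subset-search k-core oracle, and 200 random graphs to 50
nodes against neighbor-pair clustering counts.

Numerical conventions: all result tables print floats with `%.10g` and
logs carry no timestamps, so a rerun with the same manifest is
byte-identical; residual variances are clipped at 10⁻¹² inside the prior
likelihood only (a zero residual variance is legitimate data and the gene
is never dropped — the moderated denominator is strictly positive);
the between-group mean square uses group sizes as weights so unbalanced
designs are handled; correlations are computed by centered dot products.

## Known limitations

- Headline numbers of any particular published dataset (DEG counts,
  pathway lists, hub tables) depend on the raw data, the annotation
  database version, and the unpublished correlation-threshold rule, and
  are out of scope; the package asserts analytic counts and recovery of
  planted truth instead.
- The permutation null uses all m! orderings; for large m this is
  factorial and the implementation targets small m (2–5).
- Fisher's test on [observed vs rounded-expected] treats the permutation
  mean as if it were an observed sample of the same size; this mirrors
  the field's short-series tooling but is conservative rather than exact.
- Gene identifiers are opaque strings; no symbol normalization is done.
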