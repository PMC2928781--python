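# Methods

## Scope and data model

The package analyses yeast tetrad dissection data: four spore clones per
meiosis, genotyped at two-allele markers recorded by parental origin
(`P1`/`P2`), with `BOTH` for disomic spores and `NONE` for missing calls.
Dead spores carry `NONE` at every marker, because an inviable spore cannot
be genotyped; their viability bit is the only information they contribute.
Post-meiotic segregation (half-sectored colonies) is not representable —
the data this package targets contained none — and only two parental
alleles per marker are supported.

Published studies in this area report tallies, not raw tetrads, so the
bundled fixtures carry per-interval `(PD, TT, NPD)` and parental/
recombinant spore counts.  Tally counts are reals rather than integers:
half-integer spore counts occur in published tables (an ambiguous spore
scored as one half), and every estimator downstream is agnostic to
integrality.  Observed double-crossover counts cannot be reconstructed
from marginal tallies, so the interference fixture stores them as
printed; the *expected* counts and all ratio statistics are recomputed.

## Segregation classification and exclusion

A marker in a four-spore-viable tetrad segregates 2:2 (Mendelian), 3:1 /
1:3 (gene conversion), or 4:0 / 0:4; anything else — spore death, a
disomic `BOTH`, a missing call — is unscorable.  Aberrant (non-2:2)
segregation rates use four-spore-viable tetrads as the denominator.

For interval classification, a tetrad aberrant at **any** marker of a
chromosome is excluded from **all** intervals of that chromosome, not just
the interval containing the converted marker.  This per-chromosome rule is
a reconstruction: in the published tables every interval of a chromosome
has exactly the same tetrad total (e.g. 556 = 572 − 16 chromosome-III
aberrants for all three chromosome-III intervals), which per-interval
exclusion would not produce.  It also keeps adjacent-interval COC
denominators well-defined.

## Estimators

**Perkins map distance.**  `cM = 100 (TT/2 + 3 NPD) / n`.  Reported raw,
with no mapping-function correction — verified to reproduce all 128
published interval distances to one decimal.  The standard error is the
delta method on the multinomial frequencies `t = TT/n`, `v = NPD/n`:

    Var(cM)/100^2 = [ t(1−t)/4 + 9 v(1−v) − 3 t v ] / n

This reconstruction reproduces the published SE column to the printed
digit in 120 of 128 rows and within one final-digit ulp (0.1 cM) in the
rest; the original values came from an online calculator whose rounding
is not documented.

**Spore route.**  Map distance = 100 × recombinant/total over all viable
spores with clean parental calls at both markers, regardless of tetrad
completeness.  Confidence intervals are Wilson score intervals without
continuity correction (delegated to `statsmodels`); Wilson — not Wald,
not Clopper–Pearson — reproduces the published 95% CIs at one-decimal
rounding.  Note the spore route estimates the recombinant *fraction*,
which saturates as `(1 − e^{−2d})/2` under Poisson crossovers: at 20 cM
the expected recombinant fraction is 16.5%, so only the tetrad route
recovers the map length for longer intervals.

**Coefficient of coincidence.**  Expected DCOs across adjacent intervals
are `R1·R2/n` with `Ri = TTi + NPDi`, i.e. a tetrad "contains a
crossover" in an interval when it is TT or NPD there, and a tetrad NPD in
one interval and TT in the other counts as one DCO tetrad.  This
convention (rather than weighting NPD as two exchanges) reproduces every
published expected-DCO value.  Significance: the observed count is
referred to `Binomial(n, exp/n)` through the continuity-corrected normal
approximation, two-tailed; interference is called when `p < 0.05` *and*
COC < 1 (an excess of DCOs is never called interference).

**NPD ratio.**  The no-interference null assumes `Poisson(x)` exchanges
per meiosis and no chromatid interference (each exchange picks one of the
four nonsister chromatid pairs uniformly), giving

    pTT(x)  = (2/3)(1 − e^{−3x/2})
    pNPD(x) = 1/6 + e^{−3x/2}/3 − e^{−x}/2,   pPD = pNPD + e^{−x}

(verified against a brute-force Monte-Carlo oracle).  Two expectation
routes are provided: Papazian's moment formula, which solves the null
model at the observed tetratype frequency alone (algebraically identical
to `n·pNPD(x)` at the `x` matching `pTT`, and infeasible for `T ≥ 2/3`),
and a maximum-likelihood fit of `x` to the full `(PD, TT, NPD)` tally by
bounded scalar search on `x ∈ [10⁻⁶, 20]` (`xatol = 10⁻⁸`,
deterministic), followed by a 1-df chi-square goodness-of-fit test
(3 classes − 1 − 1 fitted parameter).  The original study used an online
calculator whose algorithm is undocumented; our MLE expectations land
near but not exactly on its printed values (e.g. 34.8 vs 33.4 expected
NPDs for the wild-type TRP5–CYH2 interval) while producing identical
interference calls, so printed expected-NPD values are treated as
non-binding and the implementation is validated by simulation
calibration instead.

**Fisher's exact test** is delegated to `scipy.stats.fisher_exact`
(two-sided) and cross-checked in the test suite against an exact
rational-arithmetic enumeration over all 2×2 tables with total ≤ 30.
Degenerate tables (a zero margin) return p = 1 by convention.

**Sister-spore inference.**  Among two-spore-viable tetrads, the
survivors are classified as sisters when they agree at every
centromere-linked marker — the standard dissection-genetics inference;
the original study does not state its method.  Non-mater calls require
`BOTH` at the mating-type marker in both survivors, an abstraction of the
mating-test phenotype.

## The meiosis simulator

The generator emulates an SK1 dissection experiment: a few hundred
four-spore tetrads, 4–9 two-allele markers on three chromosomes, 2:2
segregation with a low conversion rate, interfering crossovers, and
aneuploidy-driven spore death.

**Crossover placement.**  Per bivalent, a two-pathway mixture.  The
interfering pathway is a stationary counting (chi-square) renewal
process: precursors fall as Poisson with intensity `2(m+1)(1−f)` per
Morgan and every `(m+1)`-th matures into a crossover, with the phase
drawn uniformly so the process is stationary.  The non-interfering
pathway adds independent Poisson crossovers at `2f` per Morgan.  Total
intensity is 2 crossovers per Morgan regardless of `m` and `f` (each
crossover involves two of the four chromatids, so map length in Morgans
is half the expected crossover count), which lets map length be
parameterized directly in cM.  `m = 0, f = 0` reduces exactly to the
Poisson null of the NPD-ratio test, giving a closed-form cross-check.
The counting model was chosen over a gamma-renewal model for its single
integer parameter and this exact null reduction.

**Chromatid resolution.**  Each crossover joins one chromatid of each
homolog, chosen uniformly and independently (no chromatid interference).
Spore genotypes are resolved by walking outward from the centromere along
each arm and switching strands at every crossover involving the strand
currently followed.  (An earlier draft applied crossovers as sequential
segment swaps keyed on original chromatid labels; that breaks
adjacent-interval independence and was replaced — the walk resolution is
the standard construction and restores COC = 1 under `m = 0`.)

**Gene conversion** is single-chromatid and single-marker: with
probability `g` per marker per meiosis, one uniformly chosen chromatid's
allele is overwritten with the opposite allele, yielding 3:1/1:3.  No
co-conversion tracts and no post-meiotic segregation, matching what the
analysis side can score.

**Nondisjunction and death.**  A bivalent with zero crossovers
nondisjoins at Meiosis I with probability `ndj_prob_e0`, sending both
homologs to one pole: two spores disomic, two nullisomic for that
chromosome.  Nullisomy is always lethal; disomy is lethal unless the
chromosome is flagged viable (default: chromosome III only, whose disomes
survive as non-maters carrying both mating types).  Precocious sister
separation and Meiosis II errors are not modelled.

**Defaults** (wild-type-like): `m = 3` and `f = 0.2` (roughly the
interference-independent crossover share reported for large
chromosomes), `g = 0.01` per marker (published wild-type per-marker
aberrant rates run 0.2–2.1%), `ndj_prob_e0 = 0.5` (random segregation of
an achiasmate pair; no quantitative rate is published, so this is an
order-of-magnitude choice).  Marker spacing follows the wild-type map;
chromosome lengths (1.15/4.0/2.0 Morgans for III/VII/VIII) and centromere
placements are order-of-magnitude choices.  All randomness flows from a
single seeded `numpy` generator; identical seeds give byte-identical
output tables.

**What the generator does and does not emulate.**  Because aneuploidy is
the only death mechanism, simulated viability profiles contain no 3- or
1-viable-spore tetrads; real dissections show them through sporadic,
recombination-independent spore death.  Tests that pass on synthetic data
therefore validate the estimators and the aneuploidy logic, not the full
death-process realism.  Simulated wild-type viability (~99.5%) likewise
exceeds the ~97% of real strains.  Conversion events are independent
across markers, whereas real conversion tracts can span adjacent markers.

## Calibration and numerical choices

* The COC test's type-I error is measured against the model-true expected
  DCO count (`n·P(R1)·P(R2)` from the closed-form null): exact error
  0.039 at n = 500 with ~15.7 expected DCOs, empirical 0.038 over 2000
  simulated null replicates.  When the expectation is instead *estimated
  from the same tetrads* (as in routine data analysis) the test becomes
  conservative (~0.01), because the observed count and the estimated
  expectation are positively correlated — a deficit of double crossovers
  lowers both.  Reported COC values always use the data-estimated
  expectation; only the calibration study substitutes the true one.
* Test problem sizes: parameter recovery at n = 2000 tetrads; SE
  validation over 500 replicates of n = 500; interference calibration
  over 2000 null and 200 interfering replicates (n = 500–700).  These
  sizes put Monte-Carlo noise well inside the asserted tolerances.
* Report tables round half away from zero at one decimal, matching the
  published tables; internal values keep full precision.
* Degenerate inputs: empty tallies, zero expected DCOs with observed
  DCOs, and tetratype frequencies ≥ 2/3 raise typed errors rather than
  returning NaNs; a tetrad set with no scorable tetrads for an interval
  is an error, not an empty tally.

## Known limitations

* The per-chromosome aberrant-exclusion rule and the sister-spore
  inference are reconstructions of undocumented conventions (both stated
  above with their evidence).
* The NPD-ratio MLE is a reconstruction of an undocumented calculator;
  expected-NPD values differ from the published ones by ~4% in the one
  comparable case, with identical calls.
* Interference strength `m` cannot be *estimated* from data by this
  package (no gamma/counting-model fitting); `m` is a simulation input
  only.  Chromatid-interference tests and centromere-spanning
  interference special cases are likewise out of scope.
* The simulator draws crossovers per bivalent independently across
  chromosomes; crossover homeostasis (redistribution under DSB
  shortfall) is represented only implicitly through the obligate-
  crossover protection that interference provides.
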