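# tetrakit

Tetrad-genetics analysis of meiotic crossing over in budding yeast, built
around the question of how far crossover numbers can fall before Meiosis I
chromosome segregation — and hence spore viability — collapses.  The
package implements the complete dissection-data analysis chain used to
characterize *msh4*/*msh5* hypomorphs ("threshold" alleles that halve
crossing over yet keep spores alive), together with a meiosis simulator
that generates synthetic dissection tables with controllable interference,
crossover number, gene conversion, and nondisjunction.

## What it computes

For a pair of linked markers, each four-spore-viable tetrad is a parental
ditype (PD), tetratype (TT), or nonparental ditype (NPD).  From the tally
`(PD, TT, NPD)`, `n = PD + TT + NPD`:

* **Map distance (tetrad route)** — the Perkins estimator
  `cM = 100 (TT/2 + 3 NPD) / n`, with a multinomial delta-method standard
  error `SE = 100 sqrt[(t(1−t)/4 + 9v(1−v) − 3tv)/n]`, `t = TT/n`,
  `v = NPD/n`.
* **Map distance (spore route)** — percent recombinant spores with a
  Wilson score confidence interval.
* **Coefficient of coincidence (COC)** — observed double-crossover tetrads
  across adjacent intervals over `R1·R2/n` expected (`Ri = TTi + NPDi`),
  with a continuity-corrected binomial test; COC < 1 means crossover
  interference.
* **NPD ratio** — observed NPDs over those expected under Poisson (random)
  crossing over, by Papazian's closed form
  `E[NPD] = n/2 [(1−T) − (1−3T/2)^{2/3}]` or by a one-parameter maximum-
  likelihood fit of the no-interference model `pTT(x) = (2/3)(1−e^{−3x/2})`,
  `pNPD(x) = 1/6 + e^{−3x/2}/3 − e^{−x}/2`, with a 1-df chi-square test.
* **Strain statistics** — segregation classes (2:2 vs 3:1/1:3/4:0 gene
  conversion), spore-viability profiles, Fisher-exact strain comparisons,
  the viability-versus-crossover threshold surface, and the
  chromosome-III nondisjunction signature (two-spore-viable tetrads whose
  survivors are sister-spore non-maters carrying both mating types).
* **Simulation** — a stationary counting-model (chi-square) crossover
  process of order `m` mixed with a Poisson pathway, no chromatid
  interference, per-marker gene conversion, and Meiosis I nondisjunction
  of achiasmate bivalents with aneuploid spore death.

The published count tables of the *msh4/msh5* structure–function study
(57 alleles; wild-type, null, and threshold strains over eight intervals
on chromosomes III, VII, VIII) ship as TSV fixtures and every printed
statistic regenerates from them.

## Worked example

```python
>>> import tetrakit as tk
>>> from tetrakit.fixtures import interval_tally, load_fixture
>>> t2 = load_fixture("table2_nhy")
>>> tally = interval_tally(t2, "wild-type", "HIS4", "LEU2")
>>> (tally.pd, tally.tt, tally.npd)
(413.0, 141.0, 2.0)
>>> est = tk.perkins_distance(tally)
>>> round(est.cM, 1), round(est.se_cM, 1)
(13.8, 1.2)
>>> t1 = interval_tally(t2, "wild-type", "CEN8", "THR1")
>>> t3 = interval_tally(t2, "wild-type", "THR1", "CUP1")
>>> exp = tk.expected_dco(t1, t3)
>>> res = tk.coc_test(67, exp, t1.n)
>>> round(exp, 1), round(res.coc, 3), res.interference_called
(107.2, 0.625, True)
```

The `HIS4-LEU2` interval maps at 13.8 ± 1.2 cM, and on chromosome VIII
only 67 double-crossover tetrads are seen where 107.2 are expected by
chance (COC 0.625, p < 0.0001) — strong crossover interference.

The numbered drivers under `analysis/` run the full study: `01` map
distances and per-strain chromosome sums (wild-type 147 cM; threshold
alleles 99–109 cM; nulls 68/56 cM), `02` COC and NPD-ratio interference
tables, `03` the 57-allele threshold surface and subunit Fisher tests,
`04` simulator calibration, `05` nondisjunction phenotypes.  Each writes
TSVs under `results/`.

A command-line interface wraps the same library:

```sh
tetrakit simulate --params analysis/sim_params_wildtype.yaml \
    --out wt.tsv --truth wt_truth.tsv --seed 4
tetrakit fixtures table2_nhy
```

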