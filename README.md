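# primdiv

Macroevolutionary analyses on time-calibrated phylogenies and fossil
records, built around the questions raised by large primate
supermatrices: how complete is a concatenated alignment, where did
clades live ancestrally, when did diversification rates shift, and do
molecular timetrees agree with the fossil record and with their own
calibrations?

The package is aimed at systematists and comparative biologists who
have a chronogram (a rooted ultrametric tree with branch lengths in
Myr), tip-to-area codings, fossil occurrence tables, and calibration
bounds — and want the standard analyses over them as tested, scriptable
functions rather than a pile of one-off scripts.

## What it computes

* **Supermatrix occupancy audit** (`primdiv.matrix_audit`) — per-(taxon,
  locus) counts of non-missing characters from a FASTA/NEXUS alignment
  plus a RAxML-style partition table; percent filled, mean nucleotides
  per taxon, taxa per locus, single-locus taxa.
* **Ancestral-area reconstruction** (`primdiv.areas`) — two routes over
  area *sets* (bitmasks over up to 16 named areas, ancestral ranges
  capped at `max_range_size`, 2 by default):
  * MAC (minimum-area-change) parsimony: Sankoff dynamic programming
    with cost |S △ T| (gains + losses), exact per-node MPR state sets,
    and exact (min, max) gain/loss decompositions over all MPRs via an
    augmented DP;
  * DEC (dispersal–extinction–cladogenesis) likelihood: along a branch
    a range S gains area a at rate d·|S| and loses each occupied area
    at rate e (single areas can be extirpated to an absorbing null
    range); at speciation a one-area range is inherited by both
    daughters while a two-area range {a,b} resolves into one of six
    equally weighted scenarios ({a},{b}), ({b},{a}), ({a},{a,b}),
    ({a,b},{a}), ({b},{a,b}), ({a,b},{b}). Maximum-likelihood (d̂, ê),
    per-node candidate ranges within a log-likelihood window, and
    dispersal-event counting on branches.
* **Diversification-shift detection** (`primdiv.shifts`) — the
  piecewise-constant birth–death likelihood of the n−1 branching ages
  of a reconstructed tree, with sampling fraction ρ at the present and
  conditioning on survival of both root lineages. With
  E(t) = P(no sampled descendant), u = 1 − E:

      1/u(t) = λ/r + (1/u(t₀) − λ/r) e^{−r(t−t₀)},   r = λ − μ
      log q(t) = log q(t₀) + 2[log u(t) − log u(t₀)] − r(t−t₀)
      log L = 2 log q(x₁) − 2 log u(x₁) + Σ_{i≥2}[log λ(x_i) + log q(x_i)] + n log ρ

  Shift ages are scanned on a grid, epoch rates optimized in log space,
  and k shifts accepted over k−1 by a likelihood-ratio test whose
  critical value can be calibrated by constant-rate simulation
  (`calibrate_type1`). A window-constrained variant tests a forced
  shift near a fixed boundary (e.g. the Eocene–Oligocene transition).
* **Fossil diversity** (`primdiv.fossil`) — range-through standing
  diversity (a species counts at every instant between its first and
  last occurrence, boundaries inclusive), occurrence-table pruning to
  species level, per-interval net diversification rates
  ln(N_end/N_start)/Δt from fossil counts or from a chronogram's LTT
  curve, and Pearson comparison of rate series.
* **Calibration bounds** (`primdiv.calib`) — minimum ages from the
  oldest crown fossil; maximum ages as the max of stratigraphic
  bounding (walk rootward until two successive fossil-free chronologic
  units), phylogenetic bracketing (oldest stem fossil within two nodes
  rootward), and a user-supplied uncertainty age; plus auditing of
  estimated node ages against the bounds.
* **Simulators** (`primdiv.simulate`) — seeded generators for every
  input: (piecewise) birth–death chronograms with ρ-sampling, DEC tip
  ranges with full truth logs, fossil species ranges around known
  durations, and sparse supermatrix occupancy patterns.

## Worked example

```python
import primdiv as pv

# a 300-tip chronogram with a planted net-rate increase at 8 Ma
tree, _ = pv.sim_bd_tree([0.3, 0.1], [0.0, 0.0], rho=1.0,
                         age=34.0, shift_times=[8.0], seed=11)
table = pv.fit_shifts(tree, max_shifts=1, grid_step=0.5, rho=1.0)
for row in table.rows:
    print(row.n_shifts, round(row.loglik, 3), row.model.shift_times,
          row.directions, row.accepted)
```

prints

```
0 -962.68 () () True
1 -950.579 (7.5,) ('increase',) True
```

i.e. the one-shift model improves the log-likelihood by 12.1 units
(LRT statistic 24.2, far beyond the calibrated critical value), places
the shift at 7.5 Ma on the 0.5-Myr grid — within one grid step of the
true 8.0 — and labels it an increase because the net rate λ−μ rises
toward the present across the shift.

A ready-made deterministic example: the shipped per-interval rate table
(`primdiv.datasets.interval_rate_table()`) gives

```python
tab = pv.datasets.interval_rate_table()
pv.compare_rate_series(tab["fossil"], tab["AUTOhard"])   # 0.248
pv.compare_rate_series(tab["fossil"], tab["AUTOsoft"])   # 0.273
```

— the fossil-derived net rates are uncorrelated (statistically) with
the timetree-derived ones in all four comparisons, the quantitative
face of the mismatch between fossil and molecular views of Cenozoic
primate diversification.

There is also a thin CLI: `primdiv audit|areas|shifts|fossil|calib|tree ...`
(see `primdiv --help`).

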