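# cartsim

Population-level modelling of ERK activation in CAR T cells under
biological variability.

## The problem

Chimeric antigen receptor (CAR) T cells recognise a tumour antigen and
fire an intracellular signalling cascade that culminates in doubly
phosphorylated ERK (ppERK) — a switch-like, all-or-nothing readout of
T-cell activation. Second-generation CARs add the CD28 costimulatory
domain. In a therapeutic setting, no two cells see the same world: the
target antigen density varies across tumour cells, and effective kinetic
rates vary across T cells. `cartsim` asks how CD28 shapes the
*population* response under those two sources of variability, which
kinetic parameters control the activation time, and which of them an
engineer should target to make CAR T cells respond faster and more
uniformly.

The package provides, as importable library + example scripts + a thin
CLI:

* a reduced mechanistic ODE model of CAR-triggered ERK activation
  (CAR–antigen binding, the LCK/CSK/CD45 activity cycle, dual-site ITAM
  phosphorylation, ZAP70→LAT, SOS/Ras exchange, and a Raf→MEK→ERK
  cascade with distributive dual phosphorylation), with three togglable
  CD28 mechanisms (Grb2 route, GADS route, LCK catalytic boost);
* a Monte Carlo variability engine: per-cell antigen ~ lognormal
  (µ = 1.0, σ = 0.5, matching the observed CD19 surface-density range),
  or per-cell kinetic rates ~ Normal(mean, mean/3), at "low"
  (4.5 molecules µm⁻²) and "high" (45) antigen;
* a gradient-boosted-tree surrogate of the map (kinetic parameters →
  activation time), validated by fivefold CV of R² and explained
  variance, with permutation-importance scores and a one-tailed t-test;
* a LASSO-penalized activation-time minimisation by particle swarm:

  minimise  T_ERK(p) + λ · Σᵢ |ln(pᵢ / pᵢ₀)|

  swept over λ ∈ {10, 3, 1, 0.3, 0.1} to trace which catalytic rates are
  recruited as the constraint relaxes.

A cell counts as **active** when more than half of its ERK pool is doubly
phosphorylated within the 30-minute horizon; the first-crossing time is
its activation time T_ERK.

## Worked example

```bash
python examples/antigen_variability.py
```

prints (1000 cells per construct, seed 42):

```
gen1:  82.0% active, mean 13.9 min (SD 4.0) over 820 active cells
gen2:  99.9% active, mean 8.7 min (SD 1.7) over 999 active cells
```

Read: under the same lognormal antigen exposure, the CD28-bearing
construct activates essentially every cell, ~5 minutes sooner on
average, and with less than half the cell-to-cell spread — CD28 makes
the population response faster *and* more consistent. Other example
scripts cover the dose–response shift (`dose_response.py`), the
mechanism ablation showing the LCK boost is the mechanism that matters
(`mechanism_ablation.py`), surrogate training and parameter importance
(`surrogate_importance.py`), and the λ-sweep that selects the LCK and
ZAP70 catalytic rates as engineering targets
(`optimize_selection.py`).

The same experiments are available as CLI scenarios:

```bash
cartsim population --n 1000 --seed 42 --out results/
cartsim ablation   --n 500  --seed 7  --out results/
cartsim reproduce-all --n 300 --out results/
```

Every scenario writes table-shaped CSV/JSON outputs plus a manifest
(config hash, seeds, runtimes, output checksums) sufficient to re-run it
bit-identically.

## Layout

```
src/cartsim/
  parameters.py   kinetic parameter registry + committed default table
  constructs.py   CAR generations and CD28 mechanism toggles
  network.py      stoichiometry, rate laws, conserved moieties, resting state
  simulate.py     LSODA trajectories, activation readout, batched populations
  variability.py  antigen/kinetic samplers, population driver, ablation
  surrogate.py    GBT surrogate, R²/EV cross-validation, permutation importance
  optimize.py     penalized objective, particle swarm, λ sweep, re-simulation
  pipeline.py     scenario driver with manifests
  cli.py          thin command-line interface (`cartsim`)
docs/methods.md   model, assumptions, numerics, design choices
examples/         narrative scripts, one per capability
```
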