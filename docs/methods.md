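# Methods

## The model

`cartsim` simulates ERK activation in CAR T cells with a reduced
mechanistic ODE network of 25 species and 30 reactions, organised in six
stages:

1. **CAR–antigen binding.** Reversible binding of surface CAR (total 30
   au) to target antigen at density `A` (molecules µm⁻²), with mass-action
   on/off rates (`kon_CAR`, `koff_CAR`; effective Kd = 20 molecules µm⁻²,
   so the printed "high" condition of 45 molecules µm⁻² is near
   saturating and the "low" condition of 4.5 is on the rising flank).
2. **LCK activity cycle.** CSK binds active LCK (`CSKon`/`CSKoff`) and
   phosphorylates its inhibitory site (`kcat_CSK`); CD45 reverses the
   inhibition (`Kcat_CD45_LCK505`). At rest roughly 40% of LCK is active;
   this interior steady state is solved per parameter draw by bisection
   and used as the committed resting state (basal ppERK is exactly zero).
3. **ITAM phosphorylation.** Active LCK phosphorylates the ITAMs of
   antigen-bound CAR distributively at two sites (`Kcat_LCKPU_CD3z`,
   Michaelis–Menten); only the doubly phosphorylated ITAM docks ZAP70
   (tandem-SH2 recognition). CD45 (`Kcat_CD45_A1`) and SHP1 (`Kcat_SHP1`,
   recruited in proportion to phospho-ITAM — negative feedback) reverse
   both sites. The tier is balanced in a light-loading, near-linear
   regime: the dephosphorylation capacity exceeds the phosphorylation
   flux even at saturating antigen, so the steady phospho-ITAM level
   scales roughly with the *square* of LCK activity × occupancy, and the
   antigen dose ratio propagates undamped into the cascade.
4. **ZAP70 → LAT.** ZAP70 binds doubly phosphorylated ITAM
   (`kon_ZAP`/`koff_ZAP`); docked ZAP70 phosphorylates LAT (`Kcat_ZAP`)
   against a constitutive LAT phosphatase (`k_LATase`).
5. **Ras exchange.** Phospho-LAT recruits SOS activity that converts
   Ras-GDP to Ras-GTP (`k_SOS`, saturable in LATp) against a constitutive
   GAP (`k_GAP`). In second-generation constructs each engaged adaptor
   route (Grb2, GADS — identical kinetics) docks a fraction
   `cd28_dock_frac` of SOS onto engaged CD28, where it drives Ras with
   reduced efficiency `cd28_route_eff` < 1. The diversion is mildly
   *detrimental* on its own, which reproduces the observed pattern that
   adaptor-only constructs underperform first-generation cells.
6. **Raf → MEK → ERK.** Ras-GTP activates Raf; active Raf doubly
   phosphorylates MEK and ppMEK doubly phosphorylates ERK, distributively,
   against saturable phosphatases operating near zero order
   (Km ≈ 5% of the pool). The two dual-phosphorylation tiers are the
   source of the all-or-nothing ppERK switch.

A cell is **active** when more than half of its total ERK pool is doubly
phosphorylated; the first crossing time (linear interpolation on a
0.01-min readout grid) is the activation time T_ERK, censored at the
30-min horizon.

CD28 appears through three independently togglable mechanisms: the two
adaptor routes above and a multiplicative boost (`cd28_lck_boost`, default
3) of LCK's catalytic rate toward CD3ζ. The boost is the dominant
mechanism: because ITAM phosphorylation is distributive over two sites,
a 3-fold boost yields roughly a 9-fold gain in ZAP70-docking sites,
shifting the dose-response curve left and cutting activation times.

### Units and calibration

Time is in minutes, antigen in molecules µm⁻², intracellular species in
arbitrary concentration units with committed totals (e.g. LCK 100, ERK
200 au). The committed parameter table (`src/cartsim/data/
default_parameters.csv`) was calibrated once, then frozen, against the
package's own calibration goals: under the lognormal antigen distribution
generation 1 activates 70–90% of cells and generation 2 > 95%; the five
named catalytic parameters are among the top permutation-importance
scorers; and the λ = 1 optimization selects only the LCK and ZAP70
catalytic rates. These are structural goals for the committed table, not
claims of numerical equivalence with any experimentally calibrated model.

## Variability engine

Two stochastic input structures define the populations:

* **Antigen variability**: per-cell antigen density ~ lognormal with
  scale µ = 1.0 and scatter σ = 0.5 (median e¹ ≈ 2.7 molecules µm⁻²,
  chosen to span the experimentally observed CD19 surface-density range
  0.16–5.2 molecules µm⁻²).
* **Kinetic variability**: each of the 23 varied rate constants ~
  independent Normal(default, default/3), redrawn per entry until
  positive. Rejection truncation at CV = 1/3 shifts the mean by < 0.3%,
  well inside the moment tolerances asserted in the tests. Fixed antigen
  conditions: "low" = 4.5 and "high" = 45 molecules µm⁻².

Per-cell randomness derives from `SeedSequence(master).spawn(n)`, so
results are independent of batching or scheduling; identical
(configuration, seed) pairs reproduce summaries bitwise. Population
statistics (mean, SD of T_ERK) are computed over *active cells only*;
censored cells count toward the denominator of % active.

What the generator deliberately does not emulate: correlated parameter
variation across cells, intrinsic (molecular-number) noise, temporal
fluctuation of rates within one cell, antigen depletion by engagement,
and receptor-number variability. Passing tests therefore demonstrate the
population consequences of *independent static heterogeneity* in inputs
and rates, not of intrinsic stochasticity.

## Numerics

* Single trajectories: stiff-capable LSODA (via `scipy.integrate.odeint`)
  at rtol 10⁻⁶ / atol 10⁻⁹ on a dense 0.01-min readout grid; threshold
  crossing by linear interpolation (verified against a 0.001-min
  brute-force scan to < 0.01 min).
* Populations: cells are stacked into one vectorized system and advanced
  together by adaptive RK45 with per-cell parameter columns and a
  0.05-min readout grid (chunks of 1000 cells). The calibrated network is
  non-stiff at population-typical rates, and the batch path agrees with
  the single-cell path to < 0.02 min; a dedicated test enforces this.
  This is what makes 10⁴-cell conditions tractable (~2 ms/cell).
* Conservation: the network is stored as an explicit stoichiometry
  matrix, so the eleven conserved moieties (CAR, LCK, CSK, CD45, ZAP70,
  SHP1, LAT, Ras, Raf, MEK, ERK) are structural; trajectories drift by
  < 10⁻⁴ relative at default tolerances.
* Degenerate inputs: zero antigen yields exactly zero ppERK; solver
  failures are flagged per cell and reported as separate counts, never
  silently dropped; states are clipped at zero only within solver noise.

## Surrogate sensitivity analysis

The surrogate maps a cell's sampled kinetic parameter vector to its
activation time (censored cells carry the 30-min horizon as label,
preserving the information that slow regimes exist; drop-mode is a
documented switch). The regressor is a gradient-boosted tree ensemble
(500 trees, depth 3, learning rate 0.05, subsample 0.8 — a standard
weak-learner regime; all exposed), validated by seeded fivefold
cross-validation of R² and explained variance. EV ≥ R² holds identically,
with equality iff the residual mean is zero, so R² = EV certifies an
unbiased predictor.

Permutation importance is the drop in R² when a single feature column is
shuffled, repeated k = 5 times; significance is a one-tailed t-test
(H₁: mean ΔR² > 0, df = k − 1), with no multiple-testing correction.
Scores are reported raw: on evaluation data, sampling noise can make
them slightly negative, and the significance test — not clipping —
handles that. With the committed table, the five catalytic parameters of
the proximal module (`Kcat_LCKPU_CD3z`, `CSKon`, `Kcat_ZAP`,
`Kcat_CD45_LCK505`, `Kcat_CD45_A1`) all score within the top ten of 23,
with `Kcat_LCKPU_CD3z` first.

## Constrained optimization

The objective T_ERK(p) + λ Σᵢ |ln(pᵢ/pᵢ₀)| (natural log; censored
candidates score 2 × horizon = 60 min to keep the landscape finite) is
minimized over the candidate panel by a particle swarm (30 particles,
100 iterations, inertia 0.7, cognitive/social 1.5, best of 3 restarts;
a reduced 16 × 40 × 1 budget is used for sweeps and smoke runs) in
log-fold-change coordinates bounded to ±2 decades. After the swarm, a
coordinate-wise snap-to-zero polish resets each coordinate to zero
whenever that does not worsen the objective, so non-selected parameters
sit exactly at their defaults instead of at swarm-noise residuals.
λ is swept over {10, 3, 1, 0.3, 0.1}, warm-starting each λ with the
previous (sparser) optimum — the usual homotopy continuation for
penalized paths. A parameter counts as "changed" when |log fc| > 0.05.

**Candidate panel.** The default panel is the five proximal catalytic
parameters named above, not the raw top-5 of the importance ranking
(which, for the committed calibration, also admits downstream cascade
rates such as `kcat_Raf_MEK`). The panel deliberately focuses on the
catalytic activities of the receptor-proximal module — the biologically
actionable targets — and excludes the CAR–antigen affinity; any other
candidate list, including a data-driven top-k, can be passed explicitly.

With the committed table the path behaves like a LASSO path: at λ = 10
nothing moves; at λ = 3 only `Kcat_LCKPU_CD3z` is recruited (~e⁰·⁷); at
λ = 1 the selection is {`Kcat_LCKPU_CD3z` ≈ +1.8, `Kcat_ZAP` ≈ +0.2} in
log fold change; smaller λ grows both. Re-simulating with the *same*
optimized LCK rate applied to both constructs (an engineered kinase has
the same catalytic properties whichever CAR it signals under) drives
both populations to 100% activation and makes generation 1 at least as
fast as generation 2: the shared rate saturates ITAM loading in both
constructs, while generation 2 retains the small CD28 adaptor drag.

## Design choices that were genuinely open

* **Dual-site ITAM phosphorylation** (rather than a single lumped
  phospho-state): chosen both for biological realism (tandem-SH2 docking)
  and because it decorrelates the LCK and ZAP70 levers, giving the
  penalized optimization a well-defined recruitment order.
* **Negative kinetic draws**: redrawn until positive (rejection
  truncation) rather than clipped or folded.
* **Censored cells in the surrogate label**: kept at the horizon rather
  than dropped.
* **Non-activating optimizer candidates**: finite penalty (60 min)
  rather than +∞, so the swarm can traverse slow regions.
* **Log base**: natural; the λ grid is therefore base-dependent and
  documented as such.
* **CD28 boost magnitude**: a single multiplicative factor 3 on
  `Kcat_LCKPU_CD3z`; the true magnitude is not identifiable from the
  population patterns alone, so it is a named, documented constant.

## Problem sizes

Monte Carlo conditions in the test suite run at 10⁴ cells (10⁵ is the
generator's nominal regime; n is a configuration knob and the binomial
tolerances in the tests are set for the sizes actually run). The
surrogate trains on 10⁴-cell datasets in the tests and 4 × 10³ in the
acceptance script; selection paths use the reduced swarm budget. The
`scripts/acceptance.py` report recomputes every headline quantity at
these sizes from scratch.

## Known limitations

* The network is a reduced abstraction: rate constants are effective,
  concentrations are in arbitrary units, and absolute activation times
  should be read as qualitative (minutes-scale) predictions.
* The activation-time spread between low- and high-antigen conditions is
  narrower than in experimentally calibrated full-scale models, because
  the reduced cascade has fewer sequential slow tiers.
* Grb2 and GADS routes are implemented identically; the model cannot
  distinguish them by construction.
* The surrogate's CV R² (~0.75–0.8 at 10⁴ training cells) reflects the
  strong censoring nonlinearity at the activation threshold; it is
  sufficient for stable importance rankings (top-3 sets reproduce across
  dataset seeds) but not a precise emulator of T_ERK.
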