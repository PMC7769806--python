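# Methods

## Data model

The unit of analysis is a decision-making unit (DMU) — a province-level
division — observed yearly with three inputs of the health system
(institutions, beds, health staff), two service outputs (outpatient
visits, discharged patients), the population and land area used as equity
bases, and one of three region-group labels (eastern/middle/western,
11/8/12 DMUs by default). Panels are long-format CSV, one row per
(dmu, year); record order is normalised on construction so file order
never affects results. Missing (dmu, year) combinations are tolerated by
the per-year equity analyses but are a hard error for the Malmquist index,
which needs both periods balanced over the same DMUs.

Densities are reported per 1,000 persons and per 1,000 km². Published
tables of this literature sometimes label the areal density "per 1,000 m²",
but the printed magnitudes are only consistent with km²; the label is
treated as a misprint and the package stores area in km² throughout.

## Equity measures

Let X_i be unit i's share of a resource and Y_i its share of the base
(population or area), ΣX = ΣY = 1.

* **Hoover index** (`gini_hoover`, method label `paper_eq1`):
  G = ½ Σ|X_i − Y_i|. In parts of the health-equity literature this
  formula is printed under the name "Gini"; it is in fact the Robin Hood
  index and equals the maximum vertical deviation of the Lorenz curve
  from the diagonal, so it never exceeds the Lorenz-area Gini. Both are
  exposed; the Lorenz-area form is the headline default because the
  area-ratio definition is the one the band cutoffs refer to.
* **Lorenz-area Gini** (`gini_lorenz`): units sorted ascending by
  X_i/Y_i (ties broken by unit identifier for determinism), then
  G = 1 − Σ Y_i (cumX_{i−1} + cumX_i) (trapezoid rule). Equality bands
  are half-open: G < 0.2 absolute equality, [0.2, 0.3) relative equality,
  [0.3, 0.4) proper equality, [0.4, 0.5) relative inequality, ≥ 0.5
  serious inequality.
* **Theil index** (`theil`): T = Σ P_i ln(P_i/Y_i) with P_i the base
  share and Y_i the resource share — the population-weighted mean log
  deviation. The natural log is used throughout (the group decomposition
  requires a single base for additivity). A unit with zero resource share
  makes T undefined and raises; no epsilon substitution is performed.
  Gini tolerates zero resource shares.
* **Decomposition** (`theil_decompose`): for group g with base share p_g
  and resource share y_g, the within-group index t_g is computed on
  shares renormalised inside g; T_intra = Σ p_g t_g and
  T_inter = Σ p_g ln(p_g/y_g) add up to the pooled T exactly (asserted to
  1e-10 in tests). Contribution rates are T_intra/T and T_inter/T.
* **Multi-year contribution rates** (`contribution_rates`): the default
  is the arithmetic mean of yearly T_intra/T ratios, which is the
  convention that reproduces the published multi-year figures from the
  yearly reference components; a pooled mode (ΣT_intra / ΣT) is available
  via a flag. Years with T = 0 are excluded with a warning.

## DEA

Output-oriented radial envelopment with technology
{(x_j, y_j): all entries > 0}:

max φ s.t. Σλ_j x_j ≤ x_o, Σλ_j y_j ≥ φ y_o, λ ≥ 0, plus Σλ = 1 under
VRS (the BCC model). Scores are stored as φ ≥ 1 with technical efficiency
te = 1/φ, matching the ≤ 1 score convention of the classic DEAP tool.
Solved with `scipy.optimize.linprog` (HiGHS) at 1e-7 feasibility/optimality
tolerance.

* **Slacks** come from a second LP maximizing Σs⁻ + Σs⁺ at fixed φ
  (two-stage method, free of non-Archimedean ε, chosen for numerical
  robustness over one-stage ε-formulations). Internally slacks are
  nonnegative; report tables serialize input slacks as negative numbers
  (reduction needed) and output slacks as positive (shortfall), the sign
  dialect of the published slack tables.
* **Returns to scale** use the Banker Σλ criterion on the CRS solution,
  with an alternate-optima guard: Σλ is minimized and maximized at the
  optimal φ, and the class is CRS if 1 lies in the interval (±1e-6),
  IRS below, DRS above.
* Nonpositive data are rejected rather than ε-shifted. Rounding to 3
  decimals happens only in report tables.

## Malmquist productivity index

Adjacent-period, CRS-based, in the Färe–Grosskopf–Norris–Zhang form. With
output distance functions D^a(b) = 1/φ^a(b) (observation of period b
against the frontier of period a):

* effch = D^{t+1}(t+1)/D^t(t)
* techch = [(D^t(t+1)/D^{t+1}(t+1)) · (D^t(t)/D^{t+1}(t))]^{1/2}
* pech = D_VRS^{t+1}(t+1)/D_VRS^t(t), sech = effch/pech
* tfpch = effch · techch

effch/techch/tfpch are measured against the CRS frontier with only the
pure-efficiency term under VRS: this keeps the decomposition identities
exact (asserted to 1e-9 at construction) and avoids the cross-period
infeasibility that plagues VRS cross distances. Cross-period LPs cannot
be infeasible under CRS with positive data, but a failure would exclude
that (dmu, pair) from summaries with a logged warning rather than abort.

Summaries use geometric means everywhere (per DMU across pairs — the
DEAP convention for per-DMU tables — and per pair across DMUs); frequency
tables count components >1 / =1 / <1 per pair with class membership
decided after rounding to 3 decimals.

## Synthetic data

`gen_panel` emulates the study design: 31 DMUs in three unequal groups,
five yearly waves, log-normal heterogeneity with group-level log offsets
(eastern resource-rich and dense, western sparse with large areas) and
deterministic secular growth. Default growth factors per quantity are the
geometric annualizations of the 2013–2017 national resource totals
(institutions 1.066, beds 1.094, staff 1.074, outputs 1.059/1.097);
dispersions and offsets were chosen once to give province-like
right-skewed magnitudes and Gini/Theil values in the observed range.
A single integer seed drives one named pseudo-random stream per quantity
(fixed stream ids), so adding a quantity never perturbs existing draws.

`gen_frontier_panel` constructs DEA ground truth: all DMUs share the
input/output mix of one reference ray at random scales, and a DMU with
inefficiency factor c_j ≤ 1 has its outputs multiplied by c_j, so its true
CRS radial score is exactly 1/c_j. Outputs grow by a Hicks-neutral factor
g per year, making true techch = g and effch = 1 for every DMU. Frontier
points are placed without noise so the truth is exact (a noise knob exists,
default 0).

What the generator does **not** emulate: spatial correlation, real
yearbook marginals, input-mix heterogeneity on the constructed frontier,
measurement error, or missing data. Passing tests therefore demonstrate
correctness of the estimators under the assumed generating laws, not
agreement with any particular real panel — which is why the published
summary tables are additionally used for internal-consistency checks
(component additivity, decomposition identities, frequency counts,
contribution rates).

## Numerical choices and limitations

* LP tolerance 1e-7; if a fixed-φ stage-2 problem is at the numerical
  boundary it is retried with φ(1 − 1e-9). RTS interval tolerance 1e-6.
* Equity tables round to 4 decimals and DEA/MPI tables to 3, only at the
  report layer.
* The "=1" frequency class uses |x − 1| ≤ 5e-4 after 3-dp rounding.
* Theil contribution rates are undefined in years with T = 0 (excluded).
* Reported problem sizes: the default analyses run 31 DMUs × 5 years;
  property suites use 1,000 random share vectors and 25 random grouped
  panels, and DEA oracle checks use toy technologies with n ≤ 4.
* Not implemented (out of scope): input orientation, super-efficiency,
  bootstrap confidence intervals for DEA/Gini, Atkinson or
  concentration-index measures, the health-resource density index, and
  base-period-fixed or global-frontier Malmquist variants.
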