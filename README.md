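# equidea

Equity and efficiency analysis of regional health-resource panels:
Lorenz/Gini and decomposable Theil inequality measurement, output-oriented
data envelopment analysis (DEA) with slack and returns-to-scale analysis,
and the DEA-based Malmquist productivity index with its four-way
decomposition.

The package is aimed at health-services researchers who study how
resources such as hospitals, beds and health staff are distributed across
provinces (relative to population and land area) and how productively they
are used — the setting of the 2013–2017 traditional-Chinese-medicine (TCM)
health-resource system over mainland China's 31 province-level divisions,
whose published summary tables ship with the package as reference values.
Because the province-level raw data behind those tables are not public in
machine-readable form, a synthetic-data module generates panels with the
same statistical structure and *known* ground truth, so every stage of the
pipeline is verifiable end to end.

## Methods at a glance

**Equity.** For units i = 1..k with resource shares X_i and base
(population or area) shares Y_i:

* Hoover (Robin Hood) index: G = ½ Σᵢ |X_i − Y_i| — the maximum vertical
  gap between the Lorenz curve and the diagonal;
* Lorenz-area Gini (headline measure): after sorting units by X_i/Y_i,
  G = 1 − Σᵢ Y_i (cumX_{i−1} + cumX_i);
* Theil index (population-weighted mean log deviation):
  T = Σᵢ P_i ln(P_i/Y_i), which splits exactly into a within-group part
  T_intra = Σ_g p_g t_g and a between-group part
  T_inter = Σ_g p_g ln(p_g/y_g).

**Efficiency.** Output-oriented envelopment LP per DMU o:
max φ s.t. Σλⱼxⱼ ≤ x_o, Σλⱼyⱼ ≥ φy_o, λ ≥ 0 (plus Σλ = 1 under VRS / BCC);
technical efficiency is 1/φ. A second LP maximizes total slack at fixed φ;
returns to scale are classified from the Σλ interval of the CRS solution.

**Productivity.** Adjacent-period Malmquist index in the
Färe–Grosskopf–Norris–Zhang form: tfpch = effch × techch with
effch = pech × sech, from four CRS and two VRS distance-function LPs per
DMU and year pair.

## Worked example

```python
from equidea import *
from equidea.synthetic import PanelSpec

panel = gen_panel(PanelSpec(seed=7))          # 31 DMUs x 5 years, 3 regions

sv = make_shares(panel, 2017, "beds", "population")
g = gini_lorenz(sv)
print(f"Gini (Lorenz area): {g.value:.4f}  band: {g.band}")
print(f"Hoover index:       {gini_hoover(sv).value:.4f}")

dec = theil_decompose(panel, 2017, "beds", "population")
print(f"Theil T = {dec.T:.4f} = within {dec.T_intra:.4f} + between {dec.T_inter:.4f}")

res = efficiency_table(panel, 2017, rts="VRS")
print(f"VRS-efficient DMUs in 2017: {sum(r.strongly_efficient for r in res)} of {len(res)}")

summ = summarize(malmquist_panel(panel))
print(f"overall tfpch geomean: {summ.overall['tfpch']:.3f}")
```

prints

```
Gini (Lorenz area): 0.4803  band: relative inequality
Hoover index:       0.3477
Theil T = 0.3970 = within 0.3004 + between 0.0966
VRS-efficient DMUs in 2017: 13 of 31
overall tfpch geomean: 1.006
```

Bed allocation in this synthetic panel is relatively unequal (G ≈ 0.48),
three quarters of the inequality originates *within* the three regions,
13 of 31 DMUs sit on the 2017 best-practice frontier, and total factor
productivity grows about 0.6 % per year (the deterministic growth built
into the generator's defaults).

A command-line interface wraps the same pipeline:

```sh
equidea simulate --seed 7 --out panel.csv
equidea all --input panel.csv --outdir report/
```

which writes density, Gini, Theil, DEA-slack and Malmquist tables as CSV
plus a JSON run manifest (and Lorenz plots with `--plots`).

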