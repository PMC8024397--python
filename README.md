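# sccosol

Density-based correlation of solid solubility in supercritical CO₂, with and
without a cosolvent.

Measuring how much of a drug dissolves in supercritical carbon dioxide
(SC-CO₂) is the first step in designing supercritical particle-formation
processes, but the measurements are costly, so a small family of
semi-empirical *density-based correlations* is routinely fitted to sparse
isothermal data and used to interpolate. `sccosol` implements that whole
workflow for people who work with such data: curated experimental tables for
ketoconazole (KTZ) in SC-CO₂ and in SC-CO₂ + menthol, twelve registered
correlations, seeded global fitting with an AARD objective, the derived
physical analysis (dissolution/vaporization/solvation enthalpies, cosolvent
enhancement factors, crossover-pressure windows), and a synthetic-data
generator for validating the estimation machinery.

## The models

Each correlation relates the solute mole fraction $y_2$ (or the mass
concentration $c$ in g/L) to the CO₂ density $\rho$ (kg/m³), temperature
$T$ (K) and pressure $P$, with 3–6 adjustable coefficients $a_0 \dots a_5$.
Representative forms:

| model | form |
|---|---|
| Chrastil | $c = \rho^{a_0}\exp(a_1/T + a_2)$ |
| Bartle | $\ln(y_2 P/P_\text{ref}) = a_0 + a_1/T + a_2(\rho-\rho_\text{ref})$ |
| Méndez-Santiago–Teja (MST) | $T\ln(y_2 P) = a_0 + a_1\rho + a_2 T$ |
| Sodeifian | $\ln y_2 = a_0 + a_1 P^2/T + a_2\ln(\rho T) + a_3\rho\ln\rho + a_4 P\ln T + a_5\ln\rho/T$ |
| Sodeifian–Sajadian (ternary) | $\ln y_2' = (a_0 + a_1\rho_1/T)\ln\rho_1 + a_2\rho_1 + a_3\ln(y_3 P)$ |

The full registry (`sccosol.list_models()`) holds eight binary models
(Chrastil, Kumar–Johnston, Bartle, MST, Sparks, Bian, Jouyban, Sodeifian)
and four ternary ones (MST-ternary, Sodeifian–Sajadian, González,
Soltani–Mazloumi), which add the cosolvent mole fraction $y_3$.

Models are ranked by the average absolute relative deviation

$$\mathrm{AARD}\,\% = \frac{100}{N-Z}\sum_{i=1}^{N}
\frac{|y_2^\mathrm{calc} - y_2^\mathrm{exp}|}{y_2^\mathrm{exp}},$$

with $Z$ the number of adjustable coefficients (the plain $100/N$ mean is
also computed on every fit), alongside $R^2$ and the adjusted correlation
coefficient $R_\mathrm{adj} = \sqrt{|R^2 - Q(1-R^2)/(N-Q-1)|}$ with $Q$ the
number of independent state variables.

Fitting minimizes the AARD directly with a seeded multi-start scheme
(Nelder–Mead polish of a transformed-space least-squares start, plus
differential-evolution starts), so identical seeds give identical results.

## Worked example

```python
>>> import sccosol as sc
>>> data = sc.builtin_dataset("ktz_binary")   # 28 records, 308-338 K, 12-30 MPa
>>> res = sc.fit("chrastil", data, seed=0)
>>> [round(a, 1) for a in res.params]
[11.0, -11851.6, -38.9]
>>> round(res.aard_percent_plain, 2), round(res.r_adj, 3)
(12.06, 0.996)
```

The fitted Chrastil association number (~11 CO₂ molecules per solute
molecule) and the temperature coefficient $a_1 = -11852$ K give the total
dissolution enthalpy; the Bartle temperature coefficient gives the
vaporization enthalpy, and their difference the (exothermic) solvation
enthalpy:

```python
>>> dh_total = sc.enthalpy_from_temperature_coefficient("chrastil", res.params[1])
>>> bartle = sc.fit("bartle", data, seed=0)
>>> dh_vap = sc.enthalpy_from_temperature_coefficient("bartle", bartle.params[1])
>>> round(dh_total, 2), round(dh_vap, 2), round(sc.solvation_enthalpy(dh_total, dh_vap), 2)
(98.53, 121.09, -22.55)
```

(kJ/mol: dissolving the solute is strongly endothermic, dominated by the
solute's vaporization; the solvation step releases ~23 kJ/mol.)

Cosolvent and crossover analysis:

```python
>>> ternary = sc.builtin_dataset("ktz_ternary")
>>> effects = sc.cosolvent_effect(data, ternary)   # e = y2'/y2 per condition
>>> max(r.e for r in effects)                      # at 338 K, 12 MPa
60.0
>>> sc.crossover_window(data).window               # binary crossover area, MPa
(15.0, 21.0)
>>> sc.crossover_window(ternary).window
(12.0, 15.0)
```

Menthol raises KTZ solubility up to 60-fold, most strongly where the bare
solubility is worst (hot, low pressure), and shifts the crossover-pressure
region (where solubility isotherms intersect) to lower pressures.

The same runs are available from a shell:

```
sccosol fit --data builtin:ktz_binary --all --seed 0 --out report.json
sccosol report --report report.json
sccosol analyze --out analysis.json
sccosol simulate --model chrastil --params 11.0,-11850,-38.9 --noise-cv 0.05 --out synth.csv
```

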