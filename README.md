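# cafebudget

County-scale nitrogen and phosphorus budget accounting across a nested
hierarchy of nutrient-management systems (the *CAFE* framework: **C**ropping,
**A**nimal-crop, **F**ood, **E**cosystem), written for watershed nutrient
studies such as the Chesapeake Bay county cohort (197 counties, 1985–2019).

Nutrient pollution analyses usually stop at the farm gate. Here every
system in the food production–consumption chain gets a mass balance, so the
trade-offs between on-farm management, animal production, food processing
and urban waste become visible: for each accounting unit (county or whole
watershed), year, nutrient and system,

```
nutrient use efficiency (NUE, PUE) = productive outputs / inputs
nutrient surplus (N_sur, P_sur)    = inputs − productive outputs
```

A positive surplus is potential loss to the environment; an efficiency above
100% means the system is drawing down stored nutrients (for P, soil mining
of legacy phosphorus). On top of the budgets the package computes:

* adjacent-system surplus changes (e.g. `dN_sur,A,C = N_sur,A − N_sur,C`)
  and attribution of the largest positive change,
* surplus rates per hectare of cropland or land, compared against
  planetary-boundary reference points (24 / 15 kg N ha⁻¹ yr⁻¹,
  3.5–6.9 kg P ha⁻¹ yr⁻¹),
* theoretically recyclable waste (unrecycled manure excluding pasture
  deposition + food processing/retail waste + human waste loads) and the
  percent of mineral-fertilizer demand it could offset, with source/sink
  county classification,
* N:P ratios of system surpluses (positive surpluses only) and county-level
  trend counts,
* fertilizer-share binning with Kruskal–Wallis group comparison and OLS.

Because real county budget databases are assembled from state inventories
and are not redistributable, the package ships a synthetic county generator
(log-normal livestock/population densities, secular trends, food-system
mass-balance closure through trade) plus a deterministic watershed fixture
whose budgets reproduce the published watershed summary table for 1985 and
2019.

## Worked example

```python
from cafebudget import (CafeSystem, system_budget, efficiency_percent,
                        np_ratio, table1_fixture)

table = table1_fixture()
b = system_budget(table, "WATERSHED", 2019, "N", CafeSystem.Cropping)
print(b.inputs / 1e6, b.productive_outputs / 1e6, b.surplus / 1e6)
# 378.0 286.0 92.0   <- Gg N/yr: inputs, productive outputs, surplus
print(efficiency_percent(b))
# 76.0               <- cropland NUE in 2019, percent
```

The cropping system received 378 Gg N/yr in the 2019 period, exported
286 Gg N/yr in harvested crops, and left a 92 Gg N/yr surplus — a 76% use
efficiency. The same table through the CLI:

```
$ cafe fixture table1 --out fix.csv
$ cafe budget --flows fix.csv --covariates fix.covariates.csv --out budgets.csv
$ head -4 budgets.csv
year,nutrient,system,inputs_gg,outputs_gg,surplus_gg,efficiency_pct
1985,N,Cropping,327.0,224.0,103.0,69.0
1985,N,Animal-crop,526.0,294.0,232.0,56.0
1985,N,Food,593.0,315.0,278.0,53.0
```

and a synthetic cohort run end to end:

```
$ cafe simulate --seed 3 --n-counties 197 --calibrate --out sim.csv
$ cafe report --flows sim.csv --covariates sim.covariates.csv --out-dir results/
```

which writes the budget summary, county-share metrics, recyclable
inventories, N:P ratios, largest-change counts and a JSON run manifest.

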