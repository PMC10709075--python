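# pancreg

Cohort decision model of pancreatic cancer surgery regionalization.

Pancreatic resection has markedly better 30-day outcomes at high-volume
centers (HVCs, ≥20 resections/year) than at low-volume centers (LVCs),
which has driven policy proposals to concentrate ("regionalize") these
operations at HVCs.  `pancreg` quantifies what complete or partial
regionalization would buy at a population level: 30-day deaths, 30-day
complications, and the cost of managing those complications, for an
annual statewide cohort, under the observed center allocation versus a
regionalized one.  It is written for health-services researchers and
policy analysts who want the model, its sensitivity analyses, and its
parameter-uncertainty propagation as tested, scriptable code.

## The model

A single 30-day decision cycle evaluated in closed form.  With annual
incidence *I*, resectable fraction *p*<sub>res</sub>, resection fraction
*p*<sub>op</sub>, and HVC allocation *f*:

```
N      = I · p_res · p_op                      operated cohort
N_hvc  = N · f          N_lvc = N − N_hvc      allocation
deaths = N_lvc · y + N_hvc · d                 y, d = LVC/HVC 30-day mortality
compl  = N_lvc · x + N_hvc · c                 x, c = LVC/HVC 30-day complication rates
cost   = compl_lvc · u_lvc + compl_hvc · u_hvc u = cost per complication (USD)
```

The headline output is the **differential** — current-state totals
(*f* = 0.466) minus future-state totals (*f* = 1 for complete
regionalization) — in deaths, complications and dollars.  Expected
counts are rounded half-away-from-zero to whole patients at each step
(the convention that reproduces the published cohort tables exactly);
a `rounding="off"` mode carries fractional counts for sweeps, threshold
solving and probabilistic sensitivity analysis.  See
[docs/methods.md](docs/methods.md) for assumptions, parameter ranges,
and known inconsistencies in previously reported sensitivity figures.

## Worked example

```python
>>> import pancreg as pr
>>> params = pr.default_parameters()
>>> current = pr.run_state(params, params.p_hvc, "current")
>>> future = pr.run_state(params, 1.0, "future")
>>> current.total_deaths, current.total_complications, current.total_cost
(35, 364, 6120660)
>>> pr.compare_states(current, future)
Differential(delta_deaths=17, delta_complications=29, delta_cost=487635)
```

Of 5,958 projected annual cases, 2,443 (41 %) are resectable and 977
(40 %) are operated.  Under the current 46.6 % HVC allocation the model
predicts 35 deaths, 364 complications and $6,120,660 of complication
costs within 30 days; complete regionalization averts 17 deaths and 29
complications and saves $487,635 per year.

The same comparison from the shell:

```sh
$ pancreg run --out report.csv
INFO current: 977 surgeries, 35 deaths, 364 complications, $6120660
INFO future: 977 surgeries, 18 deaths, 335 complications, $5633025
$ cat report.csv
state,center_class,surgeries,deaths,complications,complication_costs_usd
current,LVC,522,27,208,3497520
current,HVC,455,8,156,2623140
current,TOTAL,977,35,364,6120660
future,LVC,0,0,0,0
future,HVC,977,18,335,5633025
future,TOTAL,977,18,335,5633025
differential,TOTAL,0,17,29,487635
```

Other subcommands: `pancreg scenario` (the packaged sensitivity
scenarios: partial regionalization at 75 %, class-differential
complication costs, a widened complication-rate gap — each reported
with rounded and unrounded differentials side by side), `pancreg sweep`
(one-way sweep of any parameter across its literature range),
`pancreg psa` (seeded Monte-Carlo propagation of parameter uncertainty)
and `pancreg fixture` (reproducible sampled parameter sets).
Parameters load from a flat `key: value` config file
(`--config`; fractions, not percent strings).

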