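# psadapt

Simulation of PSA-guided adaptive therapy in metastatic castrate-resistant
prostate cancer (mCRPC), for researchers in mathematical oncology and
evolutionary therapy design.

In the abiraterone adaptive-therapy protocol, treatment is withdrawn when a
patient's PSA falls to half of its baseline value and resumed when it
recovers to baseline. But PSA is an imperfect window on the tumor: different
cancer cell types secrete different amounts of it. `psadapt` asks how the
protocol's benefit depends on *which cells produce the PSA*.

The tumor is modelled as three competing cell types — testosterone-dependent
(T+), testosterone-producing (TP) and testosterone-independent, drug-resistant
(T−) — with Lotka-Volterra dynamics

$$\frac{dx_i}{dt} = r_i x_i \Big(1 - \frac{\sum_j a_{ij} x_j}{K_i}\Big),$$

where abiraterone acts by collapsing the TP carrying capacity
(10 000 → 100 cells) and weakening the T+ capacity coupling
$K_{T^+} = \mu\, x_{TP}$ (μ: 1.5 → 0.5). Serum PSA is a convex weighting of
the composition,

$$\mathrm{PSA}(t) = \alpha\, x_{T^+}(t) + \beta\, x_{TP}(t) + (1-\alpha-\beta)\, x_{T^-}(t),$$

and treatment success is measured by the **time to competitive release
(TCR)** — the first time the resistant type outweighs the sensitive ones,
$x_{T^-} \ge x_{T^+} + x_{TP}$. The package compares continuous maximum
tolerable dose (MTD) with the adaptive protocol (AT) across the whole
feasible (α, β) simplex, for three representative patient categories (best
responder / responder / non-responder, defined by the equilibrium frequency
of T−), and can generate classified virtual-patient cohorts. See
`docs/methods.md` for the full model description.

## Worked example

Reproduce the responder comparison table from the command line:

```
$ psadapt compare --category responder --outdir out
compare responder:
 category    alpha     beta    tcr_mtd     tcr_at  at_applicable  abs_improvement  pct_improvement
responder 1.000000 0.000000 201.645209 496.582572           True       294.937363       146.265494
responder 0.000000 1.000000 201.645209 499.436018           True       297.790809       147.680577
responder 0.333333 0.333333 201.645209 381.899343           True       180.254133        89.391726
responder 0.000000 0.000000 201.645209        NaN          False              NaN              NaN
```

Under continuous dosing this patient's resistant clone takes over after
~202 days regardless of the PSA weights (the MTD controller never consults
PSA). Adaptive therapy roughly doubles that — to ~497/499/382 days when PSA
comes from T+ cells only, TP cells only, or all types equally. When T− cells
are the sole producers (α = β = 0) the drug never halves the PSA, the
treatment is never withdrawn, and adaptive therapy is not applicable (NaN).

The same from Python, for a single best-responder course:

```python
>>> from psadapt import PSAWeights, representative_patient, run
>>> from psadapt.experiments import preset_params
>>> p = representative_patient("best_responder")
>>> res = run(preset_params(p), p.init, "at", PSAWeights(alpha=1, beta=0))
>>> round(res.tcr), res.at_applicable, len(res.therapy.switch_times)
(5375, True, 11)
```

Eleven on/off switches delay competitive release to day ~5375, versus
~4076 under continuous dosing — a 32% improvement. Other entry points:
`psadapt simulate` (one course → trajectory CSV + JSON summary),
`psadapt scan` (TCR over the (α, β) simplex, optional heatmap PNG),
`psadapt cohort` (seeded virtual-patient generation). All accept a YAML
config (`--config`) with CLI flags taking precedence, and write a
`run_config.yaml` echo for reproducibility.

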