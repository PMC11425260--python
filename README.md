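# caflux

Calcium dynamics and recording analysis for substrate-conductivity studies:
a two-pool (cytosol–ER) calcium ODE model with Hill-type calcium-induced
calcium release, a ground-truthed generator of synthetic 3-minute Fluo-4
recordings, per-cell oscillation featurization (amplitude, basal threshold,
frequency, rise & decay time), and the normality-gated ANOVA/Tukey group
comparison used to contrast substrate conditions — plus the 2^−ΔΔCt qPCR
fold-change helper.

The scientific question the package addresses: does extracellular
electroconductivity, acting through faster membrane charging (larger
calcium influx γ, smaller efflux β), raise cytoplasmic calcium?  The model

    d[Ca²⁺]ᵢ/dt  = k·[Ca²⁺]_ER − k₁·[Ca²⁺]ᵢ + α·H([Ca²⁺]ᵢ)·[Ca²⁺]_ER + γ − β·[Ca²⁺]ᵢ
    d[Ca²⁺]_ER/dt = −(k·[Ca²⁺]_ER − k₁·[Ca²⁺]ᵢ + α·H([Ca²⁺]ᵢ)·[Ca²⁺]_ER),
    H(c) = cⁿ/(δⁿ + cⁿ)

answers it in closed form: the total-calcium balance integrates to
mean [Ca²⁺]ᵢ = γ/β over any limit cycle or steady state, so the three
conductivity conditions (low/control/high ↔ γ/β = 1.9/2.1, 2.0/2.0,
2.1/1.9) are strictly ordered.  Simulation, featurization and statistics
verify the same ordering end to end on synthetic recordings.

Audience: modelers and experimentalists analyzing single-cell calcium
imaging across substrate conditions who want a tested, deterministic
pipeline with known ground truth at every stage.

## Worked example

```python
from caflux.model import CaState, condition_params, cycle_average, simulate, stability
from caflux.features import featurize_cohort
from caflux.stats import compare_conditions
from caflux.synth import GeneratorConfig, generate_cohort

# 1. the model: control condition oscillates around an unstable fixed point
rep = stability(condition_params("control").params)
print(rep.classification, round(rep.jacobian_trace, 3))   # unstable 1.408

for label in ("low", "control", "high"):
    traj = simulate(condition_params(label).params, CaState(0.1, 5.0), 300.0, 1e-3)
    print(label, round(cycle_average(traj), 4))
# low 0.9048, control 1.0, high 1.1053  (= γ/β each)

# 2. synthetic cohort -> features -> gated comparison
cohort = generate_cohort(GeneratorConfig(n_cells_per_condition=30, seed=20260922))
table = featurize_cohort(cohort.traces)
for res in compare_conditions(table):
    print(res.feature, res.omnibus["test"], f"p={res.omnibus['p']:.3g}")
# amplitude         kruskal p=5.38e-13   (flagged fallback: a group failed normality)
# threshold         kruskal p=2.95e-09
# frequency_per_min kruskal p=0.443      (programmed null survives)
# rise_time_s       anova   p=1.44e-06
# decay_time_s      anova   p=0.00212
```

Mean cytosolic calcium rises with conductivity exactly as γ/β predicts;
the featurized cohort separates the conditions on amplitude, threshold and
kinetics while frequency — generated with no condition effect — stays null.

The same stages are scripted as a narrative under `analysis/`
(01_simulate_conditions → 02_parameter_sweep → 03_synthetic_cohort →
04_group_comparison), each writing its tables under `results/`, and are
available as CLI subcommands:

```bash
caflux simulate --condition high --out traj.csv
caflux sweep --out sweep.csv
caflux cohort --out cohort_dir --seed 7
caflux featurize cohort_dir/cohort.csv --out features.csv
caflux compare features.csv --out comparison.json
caflux run --seed 7 --out runs/          # full pipeline, fresh run directory
```

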