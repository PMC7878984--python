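# restamp

Estimation of microbial division and death rates from neutral sequence-tag
(barcode) frequency data and CFU counts, with analytical correction for
technical sampling bottlenecks.

## The problem

A population of bacteria carrying *k* fitness-neutral genomic barcodes drifts
in tag composition as cells randomly divide (rate β, min⁻¹) and die (rate δ,
min⁻¹). The magnitude of that drift is summarized by the **founder population
size** N_B(t) — the size of a hypothetical population whose multinomial
sampling noise would produce the observed frequency change:

    N_B(t) = 1 / [ (1/k) Σᵢ (fᵢ(t) − ⟨fᵢ(0)⟩)² / (⟨fᵢ(0)⟩(1 − ⟨fᵢ(0)⟩)) ]

For a neutral birth–death process its expectation is independent of the tag
distribution:

    ⟨N_B(t)⟩ = (β − δ) N(0) / [(β + δ)(1 − e^{−(β−δ)t})]

Combined with the census trajectory N(t) = N(0)e^{rt} (r = β − δ, the slope of
ln CFU vs time), this inverts to closed-form rate estimates:

    δ = (r/2) [ N(0) / (N_B (1 − N(0)/N(t))) − 1 ],   β = r + δ

Experimental sampling steps (pipetting a small volume, limited sequencing
depth) add drift of their own. On the inverse scale these contributions are
additive, so they are subtracted with a ledger of mean inverse sample sizes:

    ⟨N_B(t)⟩ = 1 / [ drift − Σⱼ⟨Sⱼ⁻¹⟩ − Σⱼ⟨Iⱼ⁻¹⟩ ]

A **bottleneck sensitivity** s_B(t) = r·N(0) / [(β+δ)(1−e^{−rt})·N_B] flags
designs where sampling noise rivals the biological signal (threshold 0.17).

The package also provides: a vectorized tau-leaping birth–death simulator
with multinomial bottleneck sampling (for validation and experiment design),
a FASTQ barcode-counting pipeline with a binomial sequencing-error model and
abundance-ranked spurious-read removal, a plasmid-segregation comparator
(β = ln(F(0)/F(t))/t), death-process emulation utilities, and tag-extinction
forecasting for choosing *k*.

## Worked example

Simulate a dying population (β = 0.01, δ = 0.03 min⁻¹, 1000 geometric tags,
census ≈ 10⁶, 120 min) with two-stage bottlenecks on each side, then recover
the rates:

```python
import math
from restamp import (BirthDeathParams, SimulationPlan,
                     run_insilico_experiment, estimate_rates)

plan = SimulationPlan(params=BirthDeathParams(beta=0.01, delta=0.03,
                                              t=120, n0=1e6),
                      dt=0.01, n_iterations=100, seed=42)
res = run_insilico_experiment(plan, inoculum_sizes=[1e6, 1e6],
                              sample_sizes=[1e5, 1e6])
s = res.summary()
print(f"ideal       N_B: {s['nb_ideal']['mean']:.3g}")
print(f"uncorrected N_B: {s['nb_uncorrected']['mean']:.3g}")
print(f"corrected   N_B: {s['nb_corrected']['mean']:.3g}")

n0, nt = s['census_start']['mean'], s['census_end']['mean']
r = math.log(nt / n0) / 120
est = estimate_rates(r, n0, nt, s['nb_ideal']['mean'])
print(f"beta = {est.beta_hat:.4f}, delta = {est.delta_hat:.4f}")
```

Output:

```
ideal       N_B: 5.07e+04
uncorrected N_B: 3.02e+04
corrected   N_B: 4.99e+04
beta = 0.0100, delta = 0.0300
```

The uncorrected estimate is biased low by the technical bottlenecks
(1/3.02×10⁴ ≈ 1/4.99×10⁴ + 10⁻⁵ + 3×10⁻⁶); the ledger correction recovers
the biological value, and the rate inversion returns the simulation's true
rates.

The same workflow is available from the shell:

```sh
restamp simulate --preset fig-dying --out sim.json
restamp count reads.fastq --strain-barcode ACGT... --k 1000 --out counts.tsv
restamp estimate --sample counts.tsv --time 120 --reference ref1.tsv \
    --reference ref2.tsv --reference ref3.tsv --cfu cfu.tsv --config ledger.yaml
restamp emulate --v0 100 --delta 0.015 --times 20,25,30,35,40
restamp sensitivity --t 60 --n0 1e5 --nb 1e6
restamp ps --f0 0.4 --ft 0.2 --n0 1e5 --nt 2e5 --t 28
```

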