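# unbindkit

Desk-scale toolkit for studying ligand-unbinding kinetics: how long a
drug stays bound to its target (the residence time, 1/k_off), which
protein-ligand contacts carry the unbinding event, and which of them
decide a trajectory's fate at the transition state.  It is aimed at
method developers and computational chemists who want the full
methodology — iterative collective-variable (CV) discovery, string-method
free energies, and machine-learning transition-state analysis (MLTSA) —
runnable end-to-end on analytic model potentials with a single CPU,
instead of on weeks of all-atom molecular dynamics.

## What it computes

**Unbinding protocol** (`unbindkit.cvselect`).  Starting from an
unbiased exploration, every ligand-protein distance persistently below
d_in = 3.5 Å becomes a contact; the sum of the M active contact
distances is biased harmonically (k = 20 kcal mol⁻¹ Å⁻²) toward
D = D0 + M·d_tar, ramped over each iteration.  Contacts whose recent
mean exceeds d_out = 6 Å or whose recent variance exceeds d_var are
dropped, newly persistent ones are added, and the protocol ends when no
stable contact remains — the ligand has left the pocket.

**Free energies** (`unbindkit.string_fes`).  The unbinding path seeds a
string of restraint windows in CV space, refined by restrained sampling
plus order-8 polynomial refits with equal-arc reparametrisation until
node motion falls below 7% of the CV range (or 0.3 Å).  Window samples
are unbiased with binless WHAM,

    f_i = -kT ln Σ_n exp(-u_i(x_n)/kT) / Σ_j N_j exp((f_j - u_j(x_n))/kT),

yielding the potential of mean force (PMF) along the string coordinate,
its barrier ΔG‡, a 4-way-split standard error, and the
transition-state windows (the five highest-energy windows).

**MLTSA** (`unbindkit.mltsa`).  Unbiased "downhill" trajectories
started at the TS either rebind (IN) or dissociate (OUT).  A classifier
(single-hidden-layer perceptron or gradient-boosted trees) trained on an
early-time window of per-frame features predicts that fate; replacing
one feature at a time with its training-set global mean measures each
feature's accuracy drop, ranking the interactions that decide the
outcome.

**Kinetics** (`unbindkit.kinetics`).  Eyring-Polanyi conversion
k = (k_B T/h)·exp(-ΔG‡/k_B T) between dissociation rates and
activation free energies.

The analytical benchmark (`unbindkit.benchmarks`) exercises all of the
ML machinery on known ground truth: 25 latent 1D Langevin coordinates —
one decisive double well started at its crest — observed through 180
L1-normalised linear features, 11 of which carry the decisive
coordinate with known mixing share α.

## Worked example

```python
import numpy as np
from unbindkit import barrier_from_rate, benchmarks, mltsa

# experimental k_off -> activation free energy (298 K)
print(round(barrier_from_rate(0.0823, 298.0), 2))   # 18.92 kcal/mol
print(round(barrier_from_rate(0.00261, 298.0), 2))  # 20.97 kcal/mol

# one replica of the analytical benchmark
bench = benchmarks.make_benchmark(seed=7)
ds = benchmarks.simulate_benchmark(bench, seed=42)
model, report = mltsa.train_and_score(ds, mltsa.MLPConfig(seed=42))
print(f"test acc {report.test_accuracy:.3f}  "
      f"validation acc {report.validation_accuracy:.3f}")
# test acc 0.999  validation acc 0.980

drops = mltsa.global_mean_drop(model, ds, on="validation")
top = np.argsort(drops)[::-1][:3]
print(top.tolist(), np.round(bench.mixing.alphas[top], 2).tolist())
# [140, 30, 104] [0.65, 0.5, 0.59]
```

The two barriers are the activation free energies implied by measured
dissociation rates of 0.0823 and 0.00261 s⁻¹.  On the benchmark, the
perceptron predicts trajectory fate from frames 30–60 (of 500) with
99.9% frame-level test accuracy and 98% accuracy on 50 trajectories it
never saw; the three features with the largest global-mean accuracy
drops (indices 140, 30, 104) are all genuinely correlated features,
with decisive shares of 65%, 50% and 59%.

The same machinery runs end-to-end on a 2D toy pocket from the shell:

```
unbindkit mltsa --mode pocket --seed 1 --out rundir/
unbindkit eyring --koff 0.0823 --temp 298
```

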