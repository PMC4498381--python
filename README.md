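# snm3f — task-discriminative space-by-time decomposition of muscle activity

`snm3f` factorizes single-trial electromyographic (EMG) recordings into a
small set of shared *temporal modules* (activation waveforms over
normalized movement time), shared *spatial modules* (weightings across
muscles), and per-trial *activation coefficients* that couple them. It is
aimed at motor-control researchers who study muscle synergies: people who
record multiple muscles over many repetitions of several motor tasks and
want a compact, task-relevant description of that activity.

## The model

Each trial `s` is a non-negative matrix `M^s` (T time steps × M muscles),
approximated by the tri-factorization

```
M^s ≈ W̃ A^s W        for all s = 1..S
```

where the columns of `W̃` (T×P) are temporal modules, the rows of `W`
(N×M) are spatial modules — both shared across all trials — and `A^s`
(P×N) holds the non-negative coefficients `a_ij^s` that recruit temporal
module *i* together with spatial module *j* in trial *s*. Modules are
normalized to unit sum, so all amplitude information lives in the
coefficients.

The unsupervised solver (**sNM3F**) minimizes the reconstruction error

```
E²_NMF = Σ_s ‖M^s − W̃ A^s W‖²_F
```

The task-discriminative extension (**DsNM3F**) assumes each trial carries
a task label and augments the cost with a Fisher-style scatter penalty on
the vectorized coefficients,

```
E² = E²_NMF + γ·tr(S_w) − δ·tr(S_b)
```

where `S_w`/`S_b` are the within-task and between-task scatter matrices
of `vec(A^s)`. Minimizing `E²` pulls the coefficients of same-task trials
together (γ) and pushes task means apart (δ), so the decomposition is
discriminative *by construction* rather than only evaluated for
discriminability afterwards. Three interchangeable optimizers are
provided — multiplicative updates (`mult`), alternating constrained least
squares (`als`, `als_qp`) and a joint constrained nonlinear program
(`nlp`) — plus projection of new data onto fixed modules.

Decompositions are scored by VAF (variance accounted for), DEC
(leave-one-out linear-discriminant decoding of the task from the
coefficients), their product VDM = VAF × DEC (used to tune γ, δ), the
discrimination ratio J = tr(S_w)/tr(S_b), an SVM generalization score CLS
on held-out trials, and module-similarity indices. A synthetic-data
generator with known ground truth makes the whole pipeline testable
without recordings.

## Worked example

```python
import snm3f as sf

# four tasks × ten trials, two temporal and two spatial modules,
# 40% additive+multiplicative noise, known ground truth
synth = sf.generate(sf.toy_spec(seed=1))
data = synth.dataset

opts = sf.FitOptions(n_restarts=100, seed=0)
base = sf.fit_snm3f(data, P=2, N=2, options=opts)
disc = sf.fit_dsnm3f_mult(data, data.labels, P=2, N=2,
                          params=sf.toy_tuned_params(), options=opts)

for name, res in [("sNM3F", base), ("DsNM3F", disc)]:
    v = sf.vaf(data, res.model)
    dec = sf.lda_decode_loo(res.model.coefficients, data.labels)
    summ = sf.scatter(res.model.coefficients, data.labels)
    print(f"{name}:  VAF={v:.3f}  DEC={dec:.3f}  VDM={sf.vdm(v, dec):.3f}  "
          f"tr(Sw)={summ.tr_sw:.1f}  tr(Sb)={summ.tr_sb:.1f}  "
          f"J={sf.j_ratio(summ):.2f}")

rec = sf.recovery_score(disc.model, synth)
print(f"module recovery (min R): {rec.min_module_correlation:.3f}, "
      f"coefficient R: {rec.coefficient_correlation:.3f}")
```

prints

```
sNM3F:  VAF=1.000  DEC=0.675  VDM=0.675  tr(Sw)=361.3  tr(Sb)=19.9  J=18.14
DsNM3F:  VAF=0.493  DEC=1.000  VDM=0.493  tr(Sw)=4.2  tr(Sb)=19.3  J=0.22
module recovery (min R): 1.000, coefficient R: 0.929
```

Read this as the central trade-off of the method. The toy dimensions
allow a full-rank factorization, so the unsupervised fit reconstructs the
noisy data essentially perfectly (VAF ≈ 1) — but it does so by letting the
coefficients absorb measurement noise, which caps task decoding at 67.5%
and inflates the within-task scatter (J ≈ 18). The discriminative fit
gives up reconstruction of the noise (VAF ≈ 0.49, close to the share of
variance the true signal actually explains), collapses the within-task
scatter ~85-fold, decodes the task perfectly, and still recovers the
generative modules exactly (R = 1.0).

## Command line

```bash
snm3f simulate --spec toy --seed 7 --out data.h5
snm3f fit --input data.h5 --P 2 --N 2 --solver mult \
          --gamma 8.0 --delta 0.1 --restarts 100 --seed 7 --out model.h5
snm3f decode --model model.h5 --input data.h5 --report report.json
snm3f select --input data.h5 --P 2 --N 2 --out grid.json   # tune γ, δ by VDM
```

`preprocess` converts raw signed EMG to model input (rectification,
zero-phase 3 Hz Butterworth envelope, 50-step time normalization,
per-muscle amplitude normalization) and `compare` reports two fitted
models side by side.

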