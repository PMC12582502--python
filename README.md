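# bmdd — bimodal-Dirichlet imputation of zero-inflated microbiome counts

Microbiome sequencing yields a samples-by-taxa table of read counts that is
both compositional (only relative abundances are identified) and extremely
sparse: a zero can mean a taxon is absent or merely undersampled at the
achieved depth. Log-scale analyses — and most differential abundance tools —
need those zeros replaced by something defensible, and the usual pseudocount
is ad hoc. `bmdd` is for microbiome statisticians and bioinformaticians who
want a principled, uncertainty-aware alternative: an empirical-Bayes model
of the *true* composition whose posterior mean imputes the table and whose
posterior draws feed multiple-imputation inference.

## The model

For sample *i* with depth *N<sub>i</sub>* over *m* taxa:

- δ<sub>ij</sub> ~ Bernoulli(π<sub>j</sub>) — latent mode indicator per taxon,
- θ<sub>ij</sub> = α<sub>j,δ<sub>ij</sub></sub> with modes α<sub>j,0</sub> ≤ α<sub>j,1</sub>,
- X<sub>i</sub> ~ Dirichlet(θ<sub>i1</sub>, …, θ<sub>im</sub>) — true composition,
- W<sub>i</sub> ~ Multinomial(N<sub>i</sub>, X<sub>i</sub>) — observed counts.

Each taxon's concentration is a two-point mixture, so its marginal abundance
distribution can be bimodal — a spike near zero (α<sub>j,0</sub> ≈ 0.01–0.1)
plus a "present" mode — which is exactly the shape excess zeros produce.
The 2<sup>m</sup>-term posterior is intractable; a mean-field variational
family Dirichlet(β<sub>i</sub>) × ∏ Bernoulli(γ<sub>ij</sub>) is fitted by a
variational EM algorithm: closed-form updates
β<sub>ij</sub> = W<sub>ij</sub> + γ<sub>ij</sub>α<sub>j,1</sub> + (1−γ<sub>ij</sub>)α<sub>j,0</sub>
and logistic responsibility updates in the E-step; closed-form π and
quasi-Newton α in the M-step, all monitored by a Jensen-bounded evidence
lower bound that is non-decreasing by construction. The posterior mean
β<sub>ij</sub>/Σ<sub>k</sub>β<sub>ik</sub> is strictly positive, so logs are
always safe; Dirichlet(β<sub>i</sub>) draws give multiple imputations.

Also included: an exact 2<sup>m</sup> enumeration oracle for validation,
simulators (the model itself, plus Gaussian-copula-correlated gamma /
log-normal / Poisson / negative-binomial alternatives and two-group
designs), a 15-metric battery for composition-recovery benchmarking, naive
baselines, standard preprocessing filters, and a bias-corrected log-linear
differential abundance engine that combines imputations either as repeated
measurements (random-intercept model) or by Rubin's rules.

## Worked example

`examples/03_multiple_imputation_daa.py` simulates a two-group study
(n = 50 samples, m = 50 taxa, 10% of taxa shifted 5-fold in group 1), fits
the model, draws 20 posterior compositions and tests every taxon:

```
50 samples, 50 taxa; truly differential: [18, 25, 33, 36, 38]
discoveries at FDR 0.05: [18, 33, 38]
true positives: 3/5   false positives: 0
```

Three of the five planted taxa are recovered with no false discovery at the
5% target — the method trades a little power for reliable error control.
The other examples fit and impute a table (`01`), run a posterior
predictive check of the sparsity pattern (`02`), and score imputations with
the 15 metrics (`04`). A thin CLI mirrors the library
(`bmdd simulate|preprocess|fit|impute|sample|ppc|evaluate|daa|daa-null`);
every run writes a manifest with its seed and parameters.

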