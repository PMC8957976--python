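# cmcdcm

Resting-state effective-connectivity analysis of a five-region **Common
Model of Cognition (CMC)** network, built around dynamic causal modeling
(DCM): a generative neural + hemodynamic simulator, variational-Laplace
model inversion, fixed-effects Bayesian model selection, Bayesian parameter
averaging with directional group tests, and a GLM regressor-quality check.

The scientific question the toolchain addresses: do the **basal ganglia
(BG)** influence the prefrontal cortex (PFC) through a *direct* first-order
connection, or by *gating* — multiplicatively modulating — the cortical
pathways that feed the PFC?  The question matters for Parkinson's disease
(PD), where basal-ganglia dysfunction should propagate very differently
under the two architectures.  Because raw patient fMRI for this design is
not publicly deposited, the package ships a first-class synthetic-cohort
generator whose ground truth follows the published PD and control group
parameter summaries, so the full analysis can be exercised, calibrated and
stress-tested end to end.

## The model

Five regions (MC motor cortex, PFC prefrontal, BG basal ganglia, MTL medial
temporal, SENS sensory cortices) follow the bilinear neural state equation

    dy/dt = A·y + C·x(t) + Σᵢ yᵢ · D(i)·y

where `A` (Hz) holds fixed directed connections with negative self-decay,
`C` couples K = 8 deterministic low-frequency boxcar drivers `x(t)`
(sine/cosine pairs at 0.01–0.08 Hz, the standard deterministic stand-in for
resting-state fluctuations) into every node, and `D(i)` holds second-order
gains with which region *i* modulates connections between other regions.
Neural activity enters a balloon–Windkessel hemodynamic cascade per region
and is read out as percent-signal-change BOLD at TR = 2.5 s.

Two model variants are compared:

* **Direct** — BG→PFC is a fixed entry of `A`; `D = 0`.
* **Modulatory** — the BG→PFC entry is removed and the BG instead gate
  MTL→PFC ("Connection 1") and SENS→PFC ("Connection 2") through `D`.

The variants differ by exactly **one** free parameter (two gains replace
one fixed entry).  Per subject, each variant is fitted by variational
Laplace (Gaussian posterior, free energy F as the log-evidence
approximation); across n subjects the variants are compared by the log
group Bayes factor

    log B = Σᵢ log L(m_mod | yᵢ) − Σᵢ log L(m_dir | yᵢ),

with log B > 3 moderate and > 10 strong evidence for the modulatory
architecture.  Group parameter summaries come from fixed-effects Bayesian
parameter averaging, and PD-vs-control differences are tested directionally
with z = (μ_PD − μ_HC)/√(σ²_PD + σ²_HC).

## Worked example

```python
import cmcdcm as cc

spec = cc.build_cmc_spec("modulatory")
print(cc.count_free_parameters(spec))
# {'fixed': 13, 'input': 40, 'modulatory': 2, 'total': 55}   (direct: total 54)

# plant the PD group means as ground truth and simulate one subject
profile = cc.default_group_profile("PD", spec).with_jitter(0.0)
params = cc.draw_subject_parameters(profile, spec, seed=0)
rec = cc.generate_subject(params, spec, tr=2.5, n_scans=240, seed=1001, group="PD")
print(rec.values.shape, round(rec.noise_sd, 3))
# (240, 5) 0.467        <- 240 scans x 5 regions at SNR 3

# invert the modulatory variant and inspect the recovered gating gains
post = cc.invert_subject(rec, spec)
for lab in ("d:BG|MTL→PFC", "d:BG|SENS→PFC"):
    i = post.labels.index(lab)
    print(f"{lab}: {post.mean[i]:+.2f} ± {post.sd()[i]:.2f}")
# d:BG|MTL→PFC: +0.28 ± 0.29     (planted truth 0.24)
# d:BG|SENS→PFC: -1.59 ± 0.31    (planted truth -1.59)

# compare architectures on the same recording
post_dir = cc.invert_subject(rec, cc.build_cmc_spec("direct"))
bms = cc.log_group_bayes_factor([post.free_energy], [post_dir.free_energy])
print(round(bms.log_group_bayes_factor, 1), bms.verdict.value)
# 93.4 favor_modulatory_strong
```

The recovered posterior means sit on top of the planted gains, and even a
single subject's evidence difference (93 nats) overwhelmingly favors the
architecture that generated the data.

A command-line interface mirrors the library:

```bash
cmcdcm simulate --variant modulatory --n-pd 2 --n-hc 2 --seed 1 --out-dir cohort/
cmcdcm invert --variant modulatory --in cohort/ --out posteriors_mod/
cmcdcm invert --variant direct     --in cohort/ --out posteriors_dir/
cmcdcm compare --mod-dir posteriors_mod/ --dir-dir posteriors_dir/ --out bms.tsv
cmcdcm run-all --seed 1 --n-pd 2 --n-hc 2 --n-scans 120 --out report/
```

`run-all` writes the full diffable report bundle: cohort manifest,
per-subject posteriors for both variants, the Bayes-factor summary, group
comparison tables for the gating and direct connections, the cross-model
contrast, and the GLM check.

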