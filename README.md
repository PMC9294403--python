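# fscc — few-shot subtomogram classification

`fscc` classifies macromolecules in cryo-electron tomography (cryo-ET)
subtomograms when a class of interest has only **1–5 labeled examples**. It
is aimed at structural/cell biologists and methods developers who have a
pool of well-annotated "base" macromolecule classes and need to recognize
novel classes without labeling thousands of new particles.

## Method

Two stages:

1. **Contrastive pre-training.** A six-block 3D CNN feature extractor f_θ
   and a linear softmax head are trained on the base classes with

   L = L_CE + λ·L_SCL (λ = 0.05),

   where L_SCL is the supervised contrastive loss (temperature τ = 0.07)
   that pulls same-class embeddings together and pushes different classes
   apart, over class-balanced mini-batches.

2. **Distribution calibration.** The extractor is frozen. Each novel
   support feature v is Gaussianized with the Tukey ladder of powers
   ṽ = v^0.5; the k = 2 nearest base classes (by Euclidean distance of
   their transformed-space means to ṽ) donate their statistics:

   μ′ = (Σ_{i∈S} μ_i + ṽ)/(k+1),  Σ′ = (Σ_{i∈S} Σ_i)/k.

   150 synthetic features per support example are sampled from N(μ′, Σ′)
   and a multinomial logistic classifier is retrained on support + samples.
   Queries are classified in the same transformed space.

Because the real reference datasets are external downloads, the package
ships a **synthetic subtomogram simulator** (size-graded geometric density
classes, random 3D orientations, missing-wedge filtering, exact
variance-ratio SNR control) and a **feature-space Gaussian benchmark**
(novel class means constructed as averages of two base means, with ground
truth recorded) so the entire method is testable end to end. See
`docs/methods.md` for the model details, defaults and limitations.

The CNN (convolution, batch norm, pooling, Adam, full backprop) is
implemented in NumPy and gradient-checked against finite differences;
volumes are read and written as MRC maps via gemmi.

## Worked example

Calibrated few-shot classification on the feature benchmark (8 base / 5
novel Gaussian classes, d = 16), 5-way-1-shot over 100 episodes:

```python
from fscc import (FeatureBenchmarkConfig, generate_feature_benchmark,
                  compute_base_statistics, run_evaluation, CalibrationConfig)

bench = generate_feature_benchmark(FeatureBenchmarkConfig(seed=0))
stats = compute_base_statistics(bench.base_features, bench.base_labels,
                                tukey_lambda=0.5)

calibrated = run_evaluation("fscc", bench.novel_features, bench.novel_labels,
                            n_way=5, k_shot=1, q_queries=15, n_tasks=100,
                            master_seed=0, stats=stats)
ablation = run_evaluation("fscc", bench.novel_features, bench.novel_labels,
                          n_way=5, k_shot=1, q_queries=15, n_tasks=100,
                          master_seed=0, stats=stats,
                          calibration_config=CalibrationConfig(n_sampled_per_support=0))
baseline = run_evaluation("baseline", bench.novel_features, bench.novel_labels,
                          n_way=5, k_shot=1, q_queries=15, n_tasks=100,
                          master_seed=0)
```

Output:

```
        calibrated: 74.56% ± 1.78 (95% CI over 100 tasks)
    no-calibration: 65.32% ± 1.60 (95% CI over 100 tasks)
fine-tune baseline: 53.72% ± 1.66 (95% CI over 100 tasks)
```

With a single labeled example per class, sampling from the calibrated
distribution lifts mean episode accuracy by ~9 points over retraining on
the support alone, and by ~21 points over fine-tuning a plain softmax head
on raw features — the regime the method was designed for, where each novel
class genuinely resembles a mixture of base classes. On data whose novel
classes have no statistically similar base class, calibration can instead
cost accuracy (see the limitations section of `docs/methods.md`).

## Command line

```sh
fscc simulate       --config sim.yaml --out data/          # MRC volumes + manifest.csv
fscc pretrain       --manifest data/manifest.csv --config pretrain.yaml --out ckpt/
fscc calibrate-eval --ckpt ckpt/ckpt.npz --manifest data/manifest.csv \
                    --nway 5 --kshot 1 --tasks 100 --seed 7 --out report.json
fscc benchmark      --out bench.h5                          # feature benchmark (HDF5)
```

All commands are deterministic under their seed: rerunning reproduces every
written report byte for byte.

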