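# histofuse

Feature-fusion transfer learning for classifying grayscale histopathology
patches, together with the patch-to-scan / whole-scan accuracy protocol
used by the Kimia Path24 benchmark and a seeded synthetic texture
benchmark so the whole pipeline is testable without any dataset download.

## Who this is for

Researchers evaluating patch classifiers on Kimia-style benchmarks
(directory-per-class patch datasets, heavily imbalanced test supports)
who want (a) the fusion representation below, (b) the exact accuracy
protocol with per-class and comparison reports, and (c) a reproducible
synthetic stand-in dataset for development and CI.

## The method

A frozen pre-trained convolutional backbone maps each patch to its
penultimate-layer feature vector f (length 4096 for the 16-layer
backbone).  The patch itself is flattened to a pixel vector x.  Both are
L2-normalized so they live on the same unit sphere, concatenated, and the
concatenation is normalized again:

    v = normalize( [ normalize(f), normalize(x) ] )

Each half of v then carries L2 norm 1/√2, so features and pixels enter
training with equal weight regardless of their native scales.  The fused
vector is zero-padded to the next perfect square and reshaped to a
single-channel square map, and the same convolutional architecture is
retrained from scratch on these maps (Adamax, categorical cross-entropy,
dropout before the K-way softmax output, best-validation-epoch restore).

Evaluation follows the Kimia protocol over the confusion matrix C
(C[s,t] = test patches of class s assigned to class t):

    η_p     = trace(C) / n_tot                      (micro accuracy)
    η_w     = (1/K) Σ_s C[s,s] / n_Γs               (macro recall)
    η_total = η_p · η_w

η_total is always the product of the unrounded factors; only rendered
tables round (percentages to 2 decimals).

## Worked example

Run the synthetic-benchmark experiment: 4 texture classes (oriented
gratings + blob noise), 200 training / 50 test patches per class, a
frozen seeded tiny backbone as feature extractor, and the tiny
architecture trained for 30 epochs on fused maps and on pixels alone with
identical seeds:

```python
import histofuse as hf
from histofuse.metrics import render_comparison_table

result = hf.run_benchmark_experiment(
    num_classes=4, train_per_class=200, test_per_class=50,
    epochs=30, seeds=(1, 2, 3))
rows = [(f"fused seed {i+1}", r) for i, r in enumerate(result.fused)]
rows += [(f"pixels seed {i+1}", r) for i, r in enumerate(result.pixels)]
print(render_comparison_table(hf.comparison_table(rows)))
print(f"mean fused eta_p  = {result.mean_fused_eta_p:.3f}")
print(f"mean pixels eta_p = {result.mean_pixels_eta_p:.3f}")
```

prints

```
        model eta_p_pct eta_w_pct eta_total_pct
 fused seed 1    100.00    100.00        100.00
 fused seed 2    100.00    100.00        100.00
 fused seed 3    100.00    100.00        100.00
pixels seed 1    100.00    100.00        100.00
pixels seed 2     75.00     75.00         56.25
pixels seed 3    100.00    100.00        100.00
mean fused eta_p  = 1.000
mean pixels eta_p = 0.917
```

Each row is one trained model scored on the held-out test patches: the
patch-to-scan accuracy η_p, whole-scan accuracy η_w and their product
η_total, as percentages.  The fused representation solves the benchmark
at every seed, while the pixels-only baseline drops to 75 % on one seed —
the desk-scale analogue of the fusion improvement (here η_p = η_w because
the test supports are balanced; on skewed supports they differ).

The same pipeline is available from the shell:

```sh
histofuse simulate --classes 4 --seed 7 --out bench/
histofuse train    --data bench/train --out run/ --epochs 30 \
                   --learning-rate 0.005
histofuse evaluate --checkpoint run/checkpoint.npz --data bench/test \
                   --out eval/ --name fused-tiny
histofuse report   eval/ --out comparison.csv
```

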