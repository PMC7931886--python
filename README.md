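# mmfusion

Multimodal image+text fusion models and annotation-burden experiments for
radiology-style paired data.

Medical image classifiers are expensive to train because every label costs
expert time. When each image comes with a free-text report, the two
modalities can be fused — and a fused model may need *fewer labelled
examples* to reach a given performance than either modality alone.
`mmfusion` implements this study end to end: three fusion architectures
(Early, Late, Model), two unimodal baselines, and the *n-split* protocol
that measures how classification performance degrades as the labelled
training set shrinks. A synthetic paired-data generator with controllable
per-modality signal makes the whole pipeline runnable and testable on one
CPU, with no downloads.

## The models

With image X_img ∈ R^(224×224×C) and a report encoded by skip-gram
embeddings as X_text ∈ R^(200×224):

* **Early fusion** stacks the blocks row-wise into X_input ∈ R^(424×224×C)
  and feeds one CNN.
* **Late fusion** trains an image CNN and a wide-kernel text CNN
  independently and averages their class distributions:
  p = ½ (p_img + p_text).
* **Model fusion** concatenates the flattened terminal feature maps of both
  branches into a shared dense head, trained end to end; "Pretrained"
  variants initialise the branches from trained unimodal weights.

Text CNNs use kernels spanning the full embedding dimension (2×d, 3×d) with
max-over-time pooling. Heads are softmax + categorical cross-entropy
(single-label) or sigmoid + binary cross-entropy with inverse-frequency
class weights (multi-label). The protocol partitions patients into n
disjoint chunks (n ∈ {1, 2, 4}), splits each chunk 80/10/10 patient-
exclusively, trains every variant per chunk, and averages chunk metrics,
then repeat means. Reported per model and n: AUC, precision, recall and
F1 = 2PR/(P+R); data efficiency is summarised by the relative AUC drop
100·(AUC_n1 − AUC_n4)/AUC_n1.

Because no deep-learning framework is among the dependencies, the networks
run on a compact NumPy layer engine (im2col convolutions over BLAS, batch
norm, Adam, backprop verified against finite differences) with numba-JIT
gather/scatter kernels; skip-gram word2vec is likewise implemented in NumPy.

## Worked example

```python
import mmfusion as mf

cfg = mf.GeneratorConfig(n_patients=600, image_size=32, seed=7,
                         signal_overlap=0.0,       # complementary modalities
                         image_signal=0.6, text_signal=0.8)
samples = mf.generate_dataset(cfg)

specs = [mf.FusionModelSpec("image_only", "none", "square"),
         mf.FusionModelSpec("text_only", "wide", "none"),
         mf.FusionModelSpec("early_fusion", "square", "square")]
tc = mf.TrainConfig.desk_scale(epochs=10)
result = mf.run_experiment(samples, specs, ns=(1, 2), repeats=1,
                           config=tc, base_seed=0)
print(mf.metrics.render_results_table(result.aggregate()))
```

Output (one desk-scale run; numbers vary with seed):

```
model,f1_n1,precision_n1,recall_n1,auc_n1,f1_n2,precision_n2,recall_n2,auc_n2
Early Fusion (Square),0.93,0.98,0.88,0.97,0.67,0.82,0.6,0.74
Image Only (Square),0.8,0.86,0.74,0.82,0.68,0.8,0.62,0.73
Text Only (Wide),0.85,0.83,0.86,0.86,0.6,0.64,0.56,0.53
```

Each row is one model; column blocks give F1/precision/recall/AUC at n=1
(all 600 patients) and n=2 (half the data, averaged over both halves). The
fused model is clearly best with the full cohort (AUC 0.97 vs 0.86 for the
best unimodal baseline) because it reads the planted evidence from both
modalities; at half the data every model suffers — 300 patients is deep in
the data-starved regime — and `mf.metrics.degradation_report` quantifies the
drops. The packaged headline study (`mmfusion.experiments`, 2,000 patients,
n ∈ {1, 4}) runs the same comparison at a cohort size where the fusion
model's degradation is reliably the smallest.

A CLI mirrors the library: `mmfusion generate --config cfg.yaml --out data/`,
`mmfusion run --data data/ --ns 1,2,4 --repeats 5 --out results/`,
`mmfusion report --results results/`.

## Layout

| Path | Contents |
| --- | --- |
| `src/mmfusion/synthetic.py` | paired image/text generator, PNG+CSV writer |
| `src/mmfusion/text.py` | vocabulary, skip-gram embeddings, report encoding |
| `src/mmfusion/models.py` | model specs, fusion primitives, builders |
| `src/mmfusion/nn/` | NumPy layer engine (conv, BN, Adam, DenseNet-121) |
| `src/mmfusion/protocol.py` | partitions, splits, training, experiment loop |
| `src/mmfusion/metrics.py` | AUC/P/R/F1, degradation, results tables |
| `src/mmfusion/experiments.py` | the prepackaged annotation-burden study |
| `docs/methods.md` | model, generator and protocol details |
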