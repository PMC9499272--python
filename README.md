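# prmftp

Multi-label prediction of **multi-functional therapeutic peptides** (MFTP):
short peptides (5–50 residues) that carry one or more therapeutic function
annotations — anti-bacterial (ABP), anti-cancer (ACP), anti-viral (AVP),
anti-endotoxin (AEP) and so on, out of a 21-class vocabulary.

The package provides:

* a deep multi-label sequence classifier: token embedding → multi-scale 1-D
  CNN (kernel sizes 2, 3, 8) with max pooling → bidirectional LSTM →
  multi-head self-attention (MHSA) → per-class sigmoid scores, thresholded
  at 0.5;
* **class-weight optimization (CW)** for imbalanced multi-label training:
  the class-weighted binary cross-entropy with

  $$W_i = \varphi\,\left[\log\frac{N}{n_i}\right]^{\theta},\qquad
    1 \le \theta \le \frac{\ln X - \ln Y}{\ln(\log_Y X)},\quad
    X = \frac{N}{\min_i n_i},\; Y = \frac{N}{\max_i n_i},$$

  where $N$ is the number of training peptides and $n_i$ the number carrying
  label $i$, so rare functions get larger loss weights;
* the five set-theoretic multi-label metrics (Precision, Coverage, Accuracy,
  Absolute true, Absolute false), a repeated-random-subsample evaluation
  protocol, and paired t-tests between methods;
* benchmark curation (standard amino acids only, length 5–50, classes with
  ≥ 40 members) for a multi-label FASTA dialect (`>id|CODE1,CODE2`);
* training orchestration: Adam / batch 64 / 60 epochs, ensembling over
  random initializations with score averaging, grid search with 5-fold CV,
  and an ablation runner (`no_cnn`, `no_bilstm`, `no_mhsa`, `no_cw`);
* a **synthetic data generator** that plants class-specific sequence motifs
  into random peptides with controllable class imbalance and label
  co-occurrence, so every pipeline stage is testable without any download.

The network and its training loop are implemented on a small, fully tested
reverse-mode autodiff engine over numpy (`prmftp.autodiff`) — the package has
no deep-learning-framework dependency.

## Worked example

Train on an imbalanced synthetic benchmark (three classes, ~16:1 realized
imbalance) and evaluate on the held-out split:

```python
import numpy as np
from prmftp import (SyntheticSpec, generate_dataset, LabelVocabulary,
                    encode_batch, split_train_test, ModelConfig, RunConfig,
                    train, predict_labels, evaluate_multilabel,
                    compute_cw_weights)
from prmftp.weights import label_counts, theta_upper_bound, default_theta

spec = SyntheticSpec(counts={"ABP": 300, "ACP": 150, "AEP": 15},
                     co_occurrence=0.05, seed=7)
records = generate_dataset(spec)
vocab = LabelVocabulary(("ABP", "ACP", "AEP"))
train_r, test_r = split_train_test(records, ratio=0.8, seed=7)
tb, eb = encode_batch(train_r, vocab), encode_batch(test_r, vocab)

counts, n = label_counts(tb.labels)
print("training label counts:", dict(zip(vocab.codes, counts.tolist())), "N =", n)
print("theta upper bound: %.4f -> default theta %.4f"
      % (theta_upper_bound(counts, n), default_theta(counts, n)))
print("CW weights:", np.round(compute_cw_weights(counts, n, phi=1.0,
      theta=default_theta(counts, n)), 4))

cfg = RunConfig(model=ModelConfig.small(n_labels=3), epochs=15,
                learning_rate=3e-3)
model = train(tb, cfg, seed=0)
rep = evaluate_multilabel(eb.labels,
                          predict_labels(model.predict_proba(eb.tokens)))
print("held-out metrics:", {k: round(v, 3) for k, v in rep.as_dict().items()})
```

Output:

```
training label counts: {'ABP': 244, 'ACP': 127, 'AEP': 19} N = 372
theta upper bound: 1.3068 -> default theta 1.1534
CW weights: [0.1412 0.4153 1.3435]
held-out metrics: {'precision': 0.978, 'coverage': 0.978, 'accuracy': 0.968,
                   'absolute_true': 0.946, 'absolute_false': 0.022}
```

Reading the numbers: the rare AEP class (19 training peptides vs 244 ABP)
receives a ~10× larger loss weight than the majority class (1.34 vs 0.14);
`absolute_true = 0.946` means 94.6 % of held-out peptides got *exactly* the
right label set; `absolute_false = 0.022` is the mean per-peptide symmetric
difference between predicted and true label sets, normalized by the number
of classes.

## Command line

```sh
prmftp synth    --spec spec.yaml --out synthetic.fa
prmftp curate   input1.fa input2.fa --min-len 5 --max-len 50 --min-class 40
prmftp train    --fasta curated.fa --vocab curated.fa.vocab.json --seed 1 --repeats 10
prmftp predict  --models runs/ --fasta peptides.fa --out preds.tsv
prmftp evaluate --preds preds.tsv --truth truth.fa --subsample 0.8 --reps 5
prmftp ablate   --train-fasta train.fa --test-fasta test.fa --variants no_cnn,no_bilstm,no_mhsa,no_cw
```

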