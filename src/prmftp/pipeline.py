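"""Training orchestration: Adam mini-batch training with class-weighted BCE,
ensembling over random initializations, grid search with k-fold CV, and the
ablation runner.

The protocol mirrors the published setup: Adam, batch size 64, 60 epochs, no
early stopping; an ensemble of repeats differing only in initialization seed
whose predicted scores are averaged before thresholding; class weights always
computed from the *training* split only.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.model_selection import KFold

from .data import EncodedBatch, LabelVocabulary, PeptideRecord, encode_batch
from .metrics import (
    MetricReport,
    compare_methods_ttest,
    evaluate_multilabel,
    significance_stars,
    subsample_evaluate,
)
from .network import Adam, ModelConfig, PeptideNetwork, predict_labels
from .weights import (
    BCE_EPS,
    baseline_weights,
    compute_cw_weights,
    default_theta,
    label_counts,
)

__all__ = [
    "RunConfig",
    "TrainedModel",
    "train",
    "train_ensemble",
    "ensemble_predict",
    "grid_search_cv",
    "run_ablation",
]

ABLATION_VARIANTS = ("no_cnn", "no_bilstm", "no_mhsa", "no_cw")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one training run."""

    model: ModelConfig
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 60
    weight_scheme: str = "cw"  # cw | uniform | inverse_frequency
    phi: float = 1.0
    theta: float | None = None  # None -> midpoint of [1, theta_upper_bound]
    log_base: float = 10.0
    threshold: float = 0.5

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"]["kernel_sizes"] = list(d["model"]["kernel_sizes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        m = dict(d.pop("model"))
        m["kernel_sizes"] = tuple(m["kernel_sizes"])
        return cls(model=ModelConfig(**m), **d)


@dataclass
class TrainedModel:
    """A fitted network with its vocabulary, weights, and training log."""

    network: PeptideNetwork
    vocab: LabelVocabulary
    run_config: RunConfig
    class_weights: np.ndarray
    loss_history: list[float]
    seed: int

    def predict_proba(self, tokens: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(tokens)

    def save(self, path) -> None:
        meta = {
            "run_config": self.run_config.to_dict(),
            "vocab": list(self.vocab.codes),
            "class_weights": [float(w) for w in self.class_weights],
            "loss_history": self.loss_history,
            "seed": self.seed,
        }
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **self.network.state_dict(),
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            state = {k: archive[k] for k in archive.files if k != "__meta__"}
        run_config = RunConfig.from_dict(meta["run_config"])
        net = PeptideNetwork(run_config.model, seed=meta["seed"])
        net.load_state_dict(state)
        return cls(
            network=net,
            vocab=LabelVocabulary(tuple(meta["vocab"])),
            run_config=run_config,
            class_weights=np.array(meta["class_weights"]),
            loss_history=list(meta["loss_history"]),
            seed=meta["seed"],
        )


def resolve_class_weights(labels: np.ndarray, cfg: RunConfig) -> np.ndarray:
    """Class weights for a training label matrix under the config's scheme.

    A class absent from the (sub)set — possible inside a CV fold — is clamped
    to count 1 with a warning so the fold stays usable.
    """
    counts, n_total = label_counts(labels)
    if np.any(counts == 0):
        warnings.warn(
            "class(es) absent from this training subset; clamping their count "
            "to 1 for weight computation",
            stacklevel=2,
        )
        counts = np.maximum(counts, 1)
    if cfg.weight_scheme == "cw":
        theta = cfg.theta if cfg.theta is not None else default_theta(counts, n_total)
        return compute_cw_weights(
            counts, n_total, phi=cfg.phi, theta=theta, log_base=cfg.log_base
        )
    return baseline_weights(counts, n_total, scheme=cfg.weight_scheme)


def _batch_loss(net: PeptideNetwork, tokens, targets, weights, training, rng):
    probs = net.forward(tokens, training=training, dropout_rng=rng)
    p = probs.clip(BCE_EPS, 1 - BCE_EPS)
    term = -(p.log() * targets + (1.0 - p).log() * (1.0 - targets))
    return (term * weights).mean()


def train(batch: EncodedBatch, run_config: RunConfig, seed: int = 0) -> TrainedModel:
    """Fit one network on an encoded training batch.

    Deterministic for a fixed seed: initialization, batch shuffling and
    dropout all derive from it.  Raises on a NaN loss with a diagnostic.
    """
    cfg = run_config
    if cfg.model.n_labels != batch.labels.shape[1]:
        raise ValueError("model n_labels disagrees with the label matrix width")
    weights = resolve_class_weights(batch.labels, cfg)
    net = PeptideNetwork(cfg.model, seed=seed)
    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11]))
    n = batch.tokens.shape[0]
    history: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            net.zero_grads()
            loss = _batch_loss(
                net, batch.tokens[idx], batch.labels[idx], weights,
                training=True, rng=rng,
            )
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: lower the learning rate "
                    "or check for zero/degenerate class weights"
                )
            loss.backward()
            net.mask_frozen_grads()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)) if losses else float("nan"))
    return TrainedModel(
        network=net, vocab=batch.vocab, run_config=cfg,
        class_weights=weights, loss_history=history, seed=seed,
    )


def train_ensemble(
    batch: EncodedBatch, run_config: RunConfig, seeds: list[int]
) -> list[TrainedModel]:
    """Train one model per seed; seeds differ only in initialization/shuffle."""
    if not seeds:
        raise ValueError("seeds list must be non-empty")
    return [train(batch, run_config, seed=s) for s in seeds]


def ensemble_predict(models: list[TrainedModel], tokens: np.ndarray) -> np.ndarray:
    """Average the member models' probability matrices (score averaging;
    thresholding is applied downstream, after the average)."""
    if not models:
        raise ValueError("empty model list")
    vocabs = {m.vocab.codes for m in models}
    if len(vocabs) != 1:
        raise ValueError("ensemble members disagree on the label vocabulary")
    return np.mean([m.predict_proba(tokens) for m in models], axis=0)


def grid_search_cv(
    batch: EncodedBatch,
    grid: list[RunConfig],
    folds: int = 5,
    selection: str = "accuracy",
    seed: int = 0,
) -> tuple[RunConfig, list[dict]]:
    """Grid search by k-fold cross-validation on the training set.

    Scores each candidate by mean CV Accuracy and Absolute true; the best
    candidate is chosen by `selection` (accuracy by default) with the other
    metric as tie-breaker.  Returns the winner and the full CV table.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if selection not in ("accuracy", "absolute_true"):
        raise ValueError("selection must be 'accuracy' or 'absolute_true'")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    table: list[dict] = []
    for gi, cfg in enumerate(grid):
        fold_reports: list[MetricReport] = []
        for fi, (tr, va) in enumerate(kf.split(batch.tokens)):
            sub = EncodedBatch(
                batch.tokens[tr], batch.labels[tr], batch.vocab, batch.length
            )
            model = train(sub, cfg, seed=seed + fi)
            probs = model.predict_proba(batch.tokens[va])
            pred = predict_labels(probs, cfg.threshold)
            fold_reports.append(evaluate_multilabel(batch.labels[va], pred))
        table.append(
            {
                "grid_index": gi,
                "config": cfg,
                "accuracy": float(np.mean([r.accuracy for r in fold_reports])),
                "absolute_true": float(np.mean([r.absolute_true for r in fold_reports])),
                "folds": fold_reports,
            }
        )
    tiebreak = "absolute_true" if selection == "accuracy" else "accuracy"
    best = max(table, key=lambda row: (row[selection], row[tiebreak]))
    return best["config"], table


def run_ablation(
    train_batch: EncodedBatch,
    test_batch: EncodedBatch,
    run_config: RunConfig,
    variants: list[str] = list(ABLATION_VARIANTS),
    seed: int = 0,
    subsample_fraction: float = 0.8,
    subsample_reps: int = 5,
) -> dict[str, dict]:
    """Train the full model and each single-module ablation under identical
    seeds, evaluate all on shared repeated test subsets, and attach paired
    t-tests (accuracy, vs the full model) with star annotations."""
    for v in variants:
        if v not in ABLATION_VARIANTS:
            raise ValueError(f"unknown variant {v!r}; options: {ABLATION_VARIANTS}")

    def evaluate(cfg: RunConfig) -> dict:
        model = train(train_batch, cfg, seed=seed)
        probs = model.predict_proba(test_batch.tokens)
        mean, reps = subsample_evaluate(
            probs, test_batch.labels, fraction=subsample_fraction,
            reps=subsample_reps, seed=seed, threshold=cfg.threshold,
        )
        return {"report": mean, "reps": reps, "model": model}

    results = {"full": evaluate(run_config)}
    for v in variants:
        if v == "no_cw":
            cfg = dataclasses.replace(run_config, weight_scheme="uniform")
        else:
            cfg = dataclasses.replace(run_config, model=run_config.model.variant(v))
        results[v] = evaluate(cfg)

    full_acc = [r.accuracy for r in results["full"]["reps"]]
    for name, res in results.items():
        if name == "full":
            res["p_value"], res["stars"] = None, ""
            continue
        acc = [r.accuracy for r in res["reps"]]
        try:
            _, p = compare_methods_ttest(full_acc, acc, paired=True)
            res["p_value"], res["stars"] = p, significance_stars(p)
        except ValueError:
            res["p_value"], res["stars"] = None, "degenerate"
    return results
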