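"""Training with contig-grouped cross-validation and early stopping.

Contigs are partitioned into folds; for fold *f* the test group is *f*,
the validation group is the next one, and the remainder trains, so no
window's contig ever crosses sets. The total loss is the multinomial
profile NLL plus ``counts_loss_weight`` times the counts MSE. After
training, a fold is marked usable only when its held-out profile NLL
beats the analytic uniform-profile baseline.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import ProfileModelConfig, TrainingConfig
from .data import TrainingExample, TrainingWindow, epoch_examples
from .losses import (counts_mse, counts_mse_grad, multinomial_profile_nll,
                     multinomial_profile_nll_grad, uniform_profile_nll)
from .network import ProfileModel

logger = logging.getLogger(__name__)


@dataclass
class FoldResult:
    fold: int
    model: ProfileModel
    train_contigs: list[str]
    val_contigs: list[str]
    test_contigs: list[str]
    history: list[dict] = field(default_factory=list)
    val_nll: float = float("nan")
    uniform_nll: float = float("nan")

    @property
    def usable(self) -> bool:
        """Quality verdict: held-out NLL must beat the uniform baseline."""
        return np.isfinite(self.val_nll) and self.val_nll < self.uniform_nll


def partition_contigs(contigs: list[str], n_folds: int) -> list[list[str]]:
    """Deterministic round-robin grouping of sorted contig names."""
    contigs = sorted(set(contigs))
    if n_folds > len(contigs):
        raise ValueError(
            f"n_folds={n_folds} exceeds the {len(contigs)} available contigs; "
            "simulate a multi-contig genome set or override n_folds=1"
        )
    groups: list[list[str]] = [[] for _ in range(n_folds)]
    for i, contig in enumerate(contigs):
        groups[i % n_folds].append(contig)
    return groups


def _batches(examples: list[TrainingExample], batch_size: int,
             rng: np.random.Generator | None):
    order = np.arange(len(examples))
    if rng is not None:
        rng.shuffle(order)
    for lo in range(0, len(order), batch_size):
        yield [examples[i] for i in order[lo : lo + batch_size]]


def _stack(batch: list[TrainingExample]):
    seq = np.stack([ex.sequence for ex in batch])
    target = np.stack([ex.target_profile for ex in batch])
    log_total = np.array([ex.target_log_total for ex in batch])
    control = np.stack([ex.control_profile for ex in batch])
    ctrl_log = np.array([ex.control_log_total for ex in batch])[:, None]
    return seq, target, log_total, control, ctrl_log


def evaluate(model: ProfileModel, examples: list[TrainingExample],
             batch_size: int = 64) -> dict:
    """Mean profile NLL, counts MSE and total loss without augmentation."""
    if not examples:
        return {"nll": float("nan"), "mse": float("nan"), "loss": float("nan")}
    w = model.config.counts_loss_weight
    nlls, mses, sizes = [], [], []
    for batch in _batches(examples, batch_size, rng=None):
        seq, target, log_total, control, ctrl_log = _stack(batch)
        logits, pred_log = model.forward(seq, control, ctrl_log)
        nlls.append(multinomial_profile_nll(logits, target) * len(batch))
        mses.append(counts_mse(pred_log, log_total) * len(batch))
        sizes.append(len(batch))
    n = sum(sizes)
    nll = sum(nlls) / n
    mse = sum(mses) / n
    return {"nll": nll, "mse": mse, "loss": nll + w * mse}


def train(model: ProfileModel, train_windows: list[TrainingWindow],
          val_windows: list[TrainingWindow],
          genomes: dict, tracks: dict, tcfg: TrainingConfig,
          control_tracks: dict | None = None) -> list[dict]:
    """Optimize in place; returns the per-epoch loss history."""
    if not train_windows:
        raise ValueError("empty training set")
    mcfg = model.config
    rng = np.random.default_rng(tcfg.seed)
    optimizer = model.make_optimizer(lr=tcfg.learning_rate)
    val_examples = epoch_examples(val_windows, genomes, tracks, mcfg, tcfg,
                                  rng=np.random.default_rng(0),
                                  control_tracks=control_tracks, augment=False)
    best_loss = np.inf
    best_weights = model.get_weights()
    bad_epochs = 0
    history: list[dict] = []
    for epoch in range(tcfg.max_epochs):
        examples = epoch_examples(train_windows, genomes, tracks, mcfg, tcfg,
                                  rng=rng, control_tracks=control_tracks)
        train_loss = 0.0
        n_seen = 0
        for batch in _batches(examples, tcfg.batch_size, rng=rng):
            seq, target, log_total, control, ctrl_log = _stack(batch)
            logits, pred_log = model.forward(seq, control, ctrl_log)
            nll = multinomial_profile_nll(logits, target)
            mse = counts_mse(pred_log, log_total)
            loss = nll + mcfg.counts_loss_weight * mse
            optimizer.zero_grad()
            dlogits = multinomial_profile_nll_grad(logits, target)
            dlog = mcfg.counts_loss_weight * counts_mse_grad(pred_log, log_total)
            model.backward(dlogits, dlog)
            optimizer.step()
            train_loss += loss * len(batch)
            n_seen += len(batch)
        val = evaluate(model, val_examples, tcfg.batch_size)
        record = {"epoch": epoch, "train_loss": train_loss / max(n_seen, 1),
                  "val_nll": val["nll"], "val_mse": val["mse"],
                  "val_loss": val["loss"]}
        history.append(record)
        logger.info("epoch %d: train %.3f val %.3f", epoch,
                    record["train_loss"], record["val_loss"])
        if val["loss"] < best_loss - 1e-9:
            best_loss = val["loss"]
            best_weights = model.get_weights()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= tcfg.patience:
                break
    model.set_weights(best_weights)
    return history


def train_folds(windows: list[TrainingWindow], genomes: dict, tracks: dict,
                mcfg: ProfileModelConfig, tcfg: TrainingConfig,
                control_tracks: dict | None = None,
                model_seed: int = 0) -> list[FoldResult]:
    """Contig-grouped cross-validation; one trained model per fold."""
    fold_keys = sorted({w.fold_key for w in windows})
    if len(fold_keys) < 2 and tcfg.n_folds > 1:
        raise ValueError(
            "cross-validation needs >= 2 distinct contigs; simulate a "
            "multi-contig genome set or set n_folds=1"
        )
    groups = partition_contigs(fold_keys, tcfg.n_folds)
    results = []
    for f in range(tcfg.n_folds):
        test_contigs = groups[f]
        if tcfg.n_folds == 1:
            val_contigs = test_contigs
            train_contigs = fold_keys
        else:
            val_contigs = groups[(f + 1) % tcfg.n_folds]
            train_contigs = [c for g in groups for c in g
                             if c not in test_contigs and c not in val_contigs]
            if not train_contigs:
                # two-group degenerate case: train and validate on the same
                # non-test group (the test group stays untouched)
                train_contigs = list(val_contigs)
        train_w = [w for w in windows if w.fold_key in train_contigs]
        val_w = [w for w in windows if w.fold_key in val_contigs]
        test_w = [w for w in windows if w.fold_key in test_contigs]
        model = ProfileModel(mcfg, seed=model_seed + f)
        history = train(model, train_w, val_w, genomes, tracks, tcfg,
                        control_tracks)
        held_out = test_w or val_w
        examples = epoch_examples(held_out, genomes, tracks, mcfg, tcfg,
                                  rng=np.random.default_rng(0),
                                  control_tracks=control_tracks, augment=False)
        metrics = evaluate(model, examples, tcfg.batch_size)
        baseline = uniform_profile_nll(np.stack([e.target_profile for e in examples]))
        results.append(FoldResult(
            fold=f, model=model, train_contigs=list(train_contigs),
            val_contigs=list(val_contigs), test_contigs=list(test_contigs),
            history=history, val_nll=metrics["nll"], uniform_nll=baseline,
        ))
        logger.info("fold %d: held-out NLL %.2f (uniform %.2f) usable=%s",
                    f, metrics["nll"], baseline, results[-1].usable)
    return results
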