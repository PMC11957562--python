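"""Profile and counts losses.

The profile loss is the multinomial negative log-likelihood of the
observed per-base 5'-end counts under probabilities obtained by a single
softmax over the concatenated two-strand logits of the output window;
the counts loss is the squared error of the predicted log of total
counts across both strands, averaged over the batch.
"""
from __future__ import annotations

import numpy as np
from scipy.special import logsumexp


def _flatten(a: np.ndarray) -> np.ndarray:
    """(B, 2, L) or (2, L) -> (B, 2*L)."""
    a = np.asarray(a, dtype=np.float64)
    if a.ndim == 2:
        a = a[None]
    return a.reshape(a.shape[0], -1)


def multinomial_profile_nll(profile_logits: np.ndarray,
                            target_profile: np.ndarray) -> float:
    """Mean over batch of ``-sum_i c_i log softmax(logits)_i``."""
    logits = _flatten(profile_logits)
    counts = _flatten(target_profile)
    if logits.shape != counts.shape:
        raise ValueError(f"shape mismatch: {logits.shape} vs {counts.shape}")
    if (counts < 0).any():
        raise ValueError("target counts must be non-negative")
    log_p = logits - logsumexp(logits, axis=1, keepdims=True)
    return float(-(counts * log_p).sum(axis=1).mean())


def multinomial_profile_nll_grad(profile_logits: np.ndarray,
                                 target_profile: np.ndarray) -> np.ndarray:
    """d(mean NLL)/d(logits), same shape as ``profile_logits``."""
    shape = np.asarray(profile_logits).shape
    logits = _flatten(profile_logits)
    counts = _flatten(target_profile)
    p = np.exp(logits - logsumexp(logits, axis=1, keepdims=True))
    totals = counts.sum(axis=1, keepdims=True)
    grad = (totals * p - counts) / logits.shape[0]
    return grad.reshape(shape)


def counts_mse(predicted_log_total: np.ndarray, target_log_total: np.ndarray) -> float:
    pred = np.atleast_1d(np.asarray(predicted_log_total, dtype=np.float64)).ravel()
    target = np.atleast_1d(np.asarray(target_log_total, dtype=np.float64)).ravel()
    if pred.shape != target.shape:
        raise ValueError("batch shapes differ")
    return float(np.mean((pred - target) ** 2))


def counts_mse_grad(predicted_log_total: np.ndarray,
                    target_log_total: np.ndarray) -> np.ndarray:
    pred = np.atleast_1d(np.asarray(predicted_log_total, dtype=np.float64))
    target = np.atleast_1d(np.asarray(target_log_total, dtype=np.float64))
    return 2.0 * (pred - target) / pred.size


def uniform_profile_nll(target_profile: np.ndarray) -> float:
    """Analytic baseline: NLL of a flat profile, ``total * ln(2 L_out)``
    per window, averaged over the batch."""
    counts = _flatten(target_profile)
    n_bins = counts.shape[1]
    return float((counts.sum(axis=1) * np.log(n_bins)).mean())
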