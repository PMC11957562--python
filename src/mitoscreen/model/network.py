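"""The sequence-to-profile network.

Trunk: a wide first convolution, then dilated 3-bp convolutions with
dilation doubling per layer, ReLU activations, zero ('same') padding and
an additive residual connection between successive layers. Two heads:

* profile — a wide no-padding convolution over the trunk output,
  centre-cropped to the output window, stacked channel-wise with the
  control profile tracks and mixed by a kernel-size-1 convolution into
  one logit per strand and base;
* counts — global average pooling of the trunk output through a dense
  layer, concatenated with the log total counts of the control
  experiment, and a final dense layer predicting the log of total counts
  across both strands.
"""
from __future__ import annotations

import numpy as np

from .config import ProfileModelConfig
from .layers import Adam, Conv1D, Dense, ReLU


class ProfileModel:
    def __init__(self, config: ProfileModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.conv_first = Conv1D(4, c.n_filters, c.first_kernel, rng=rng)
        self.relu_first = ReLU()
        self.dilated: list[Conv1D] = []
        self.relus: list[ReLU] = []
        for layer in range(2, c.n_conv_layers + 1):
            dilation = c.dilation_base ** (layer - 1)
            self.dilated.append(Conv1D(c.n_filters, c.n_filters, c.dilated_kernel,
                                       dilation=dilation, rng=rng))
            self.relus.append(ReLU())
        self.conv_profile = Conv1D(c.n_filters, 2, c.profile_kernel,
                                   pad_same=False, rng=rng)
        self.conv_mix = Conv1D(4, 2, 1, pad_same=False, rng=rng)
        self.dense1 = Dense(c.n_filters, c.counts_hidden, rng=rng)
        self.relu_counts = ReLU()
        self.dense2 = Dense(c.counts_hidden + 1, 1, rng=rng)
        self._cache: dict = {}

    # ---- parameter plumbing -------------------------------------------------
    def _layers(self):
        return ([self.conv_first] + self.dilated +
                [self.conv_profile, self.conv_mix, self.dense1, self.dense2])

    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _), w in zip(self.params(), weights):
            p[...] = w

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.params(), lr=lr)

    # ---- forward ------------------------------------------------------------
    def forward(self, seq: np.ndarray, control_profile: np.ndarray | None = None,
                control_log_total: np.ndarray | None = None,
                ) -> tuple[np.ndarray, np.ndarray]:
        """seq (B, 4, input_length) -> (profile logits (B, 2, output_length),
        predicted log totals (B,))."""
        c = self.config
        B = seq.shape[0]
        if seq.shape[1:] != (4, c.input_length):
            raise ValueError(f"expected (B, 4, {c.input_length}) input, got {seq.shape}")
        if control_profile is None or not c.use_control:
            control_profile = np.zeros((B, 2, c.output_length))
        if control_log_total is None or not c.use_control:
            control_log_total = np.zeros((B, 1))
        control_log_total = np.asarray(control_log_total, dtype=np.float64).reshape(B, 1)

        x = self.relu_first.forward(self.conv_first.forward(seq))
        for conv, relu in zip(self.dilated, self.relus):
            x = x + relu.forward(conv.forward(x))
        trunk = x

        head = self.conv_profile.forward(trunk)  # (B, 2, L_head), no padding
        L_head = head.shape[2]
        crop = (L_head - c.output_length) // 2
        if crop < 0:
            raise ValueError("profile head output shorter than output_length")
        cropped = head[:, :, crop : crop + c.output_length]
        stacked = np.concatenate([cropped, control_profile], axis=1)  # (B, 4, L_out)
        logits = self.conv_mix.forward(stacked)

        pooled = trunk.mean(axis=2)  # (B, F)
        hidden = self.relu_counts.forward(self.dense1.forward(pooled))
        concat = np.concatenate([hidden, control_log_total], axis=1)
        log_total = self.dense2.forward(concat)[:, 0]

        self._cache = {"B": B, "L_head": L_head, "crop": crop,
                       "trunk_len": trunk.shape[2], "hidden_dim": hidden.shape[1]}
        return logits, log_total

    # ---- backward -----------------------------------------------------------
    def backward(self, dlogits: np.ndarray, dlog_total: np.ndarray) -> None:
        """Accumulate parameter gradients for the last forward batch."""
        c = self._cache
        B, L_head, crop = c["B"], c["L_head"], c["crop"]

        dstacked = self.conv_mix.backward(dlogits)
        dcropped = dstacked[:, :2, :]  # control channels receive no gradient
        dhead = np.zeros((B, 2, L_head))
        dhead[:, :, crop : crop + dcropped.shape[2]] = dcropped
        dtrunk = self.conv_profile.backward(dhead)

        dconcat = self.dense2.backward(np.asarray(dlog_total).reshape(B, 1))
        dhidden = dconcat[:, : c["hidden_dim"]]
        dpooled = self.dense1.backward(self.relu_counts.backward(dhidden))
        dtrunk = dtrunk + dpooled[:, :, None] / c["trunk_len"]

        dx = dtrunk
        for conv, relu in zip(reversed(self.dilated), reversed(self.relus)):
            dx = dx + conv.backward(relu.backward(dx))
        self.conv_first.backward(self.relu_first.backward(dx))

    # ---- inference helpers --------------------------------------------------
    def predict_probs(self, seq: np.ndarray, control_profile=None,
                      control_log_total=None) -> tuple[np.ndarray, np.ndarray]:
        """Softmax profile probabilities (B, 2, L_out) and log totals (B,)."""
        from scipy.special import logsumexp

        logits, log_total = self.forward(seq, control_profile, control_log_total)
        flat = logits.reshape(logits.shape[0], -1)
        probs = np.exp(flat - logsumexp(flat, axis=1, keepdims=True))
        return probs.reshape(logits.shape), log_total

    def save(self, path: str) -> None:
        weights = {f"w{i}": w for i, w in enumerate(self.get_weights())}
        np.savez(path, **weights)

    @classmethod
    def load(cls, path: str, config: ProfileModelConfig) -> "ProfileModel":
        model = cls(config)
        with np.load(path) as data:
            model.set_weights([data[f"w{i}"] for i in range(len(data.files))])
        return model
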