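"""Model and training hyper-parameter blocks."""
from __future__ import annotations

from dataclasses import dataclass


@dataclass
class ProfileModelConfig:
    """Architecture hyper-parameters.

    Defaults give the full-size architecture: 2,114-bp one-hot input,
    1,000-bp output window, a 21-bp first convolution followed by eight
    dilated 3-bp convolutions (dilation doubling per layer, 64 filters,
    residual additions, zero padding), a 75-bp no-padding profile head
    whose output is centre-cropped to the output window, and a counts
    head fed by global average pooling.
    """

    input_length: int = 2114
    output_length: int = 1000
    n_conv_layers: int = 9
    n_filters: int = 64
    first_kernel: int = 21
    dilated_kernel: int = 3
    dilation_base: int = 2
    profile_kernel: int = 75
    use_control: bool = True
    counts_loss_weight: float = 1.0
    counts_hidden: int = 32

    def __post_init__(self) -> None:
        if self.input_length <= self.output_length:
            raise ValueError("input_length must exceed output_length")
        for k in (self.first_kernel, self.dilated_kernel, self.profile_kernel):
            if k % 2 == 0:
                raise ValueError("kernel sizes must be odd")
        if self.n_conv_layers < 2:
            raise ValueError("need at least 2 convolutional layers")
        if self.counts_loss_weight < 0:
            raise ValueError("counts_loss_weight must be non-negative")

    @property
    def receptive_field(self) -> int:
        """Trunk receptive field from the stated kernels and dilations."""
        rf = self.first_kernel
        for layer in range(2, self.n_conv_layers + 1):
            rf += (self.dilated_kernel - 1) * self.dilation_base ** (layer - 1)
        return rf

    @classmethod
    def tiny(cls, **overrides) -> "ProfileModelConfig":
        """Scaled-down configuration for CPU tests and demos."""
        kwargs = dict(input_length=514, output_length=250, n_conv_layers=4,
                      n_filters=16, profile_kernel=25, counts_hidden=8)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class TrainingConfig:
    """Training-set construction and optimisation settings.

    ``peak_to_nonpeak_ratio`` is peaks:non-peaks (peaks >= non-peaks);
    outlier peaks above ``outlier_multiplier x quantile(totals,
    outlier_quantile)`` are dropped; peak windows are jittered afresh
    every epoch by up to ``jitter_max`` bases and (optionally)
    reverse-complement augmented; folds group windows by contig.
    """

    peak_to_nonpeak_ratio: float = 3.0
    outlier_quantile: float = 0.99
    outlier_multiplier: float = 1.2
    jitter_max: int = 128
    rc_augment: bool = True
    n_folds: int = 5
    gc_tolerance: float = 0.02
    seed: int = 0
    batch_size: int = 64
    learning_rate: float = 1e-3
    max_epochs: int = 100
    patience: int = 5

    def __post_init__(self) -> None:
        if self.peak_to_nonpeak_ratio < 1:
            raise ValueError("ratio is peaks:non-peaks with peaks >= non-peaks")
        if self.jitter_max < 0:
            raise ValueError("jitter_max must be >= 0")
        if self.n_folds < 1:
            raise ValueError("n_folds must be >= 1")
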