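"""Tiled prediction around the circular genome and corroboration scoring.

Windows of ``input_length`` are taken at steps of ``output_length``
around the circle (the sequence is padded modularly by the flank on each
side); each window is predicted as the average of the forward and
reverse-complement passes; per-base expected counts are the softmax
probability times the exponentiated predicted log total. Bases covered
by more than one window (the wrap overlap of the last tile, or several
fold models) are averaged, so every base receives exactly one stitched
value.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ..genome import CircularGenome
from ..screen import PeakCall
from ..tracks import StrandedTrack
from .network import ProfileModel


@dataclass
class PredictedTrack:
    track: StrandedTrack  # kind == "predicted"
    provenance: dict = field(default_factory=dict)

    @property
    def plus(self) -> np.ndarray:
        return self.track.plus

    @property
    def minus(self) -> np.ndarray:
        return self.track.minus

    @property
    def total(self) -> np.ndarray:
        return self.track.total

    @property
    def length(self) -> int:
        return self.track.length


def tile_starts(genome_length: int, output_length: int, offset: int = 0) -> np.ndarray:
    """Output-window start coordinates covering the whole circle."""
    n_tiles = int(np.ceil(genome_length / output_length))
    return (offset + np.arange(n_tiles) * output_length) % genome_length


def _predict_window(model: ProfileModel, seq: np.ndarray,
                    control_profile: np.ndarray | None,
                    control_log_total: np.ndarray | None,
                    ) -> tuple[np.ndarray, float]:
    """Forward/RC-averaged (2, L_out) probabilities and expected total."""
    rc_seq = seq[:, ::-1, ::-1].copy()
    rc_control = (control_profile[:, ::-1, ::-1].copy()
                  if control_profile is not None else None)
    probs_fwd, log_fwd = model.predict_probs(seq, control_profile, control_log_total)
    probs_rc, log_rc = model.predict_probs(rc_seq, rc_control, control_log_total)
    probs_rc = probs_rc[:, ::-1, ::-1]  # swap strands, flip positions
    probs = 0.5 * (probs_fwd + probs_rc)
    total = 0.5 * (np.expm1(log_fwd[0]) + np.expm1(log_rc[0]))
    return probs[0], max(float(total), 0.0)


def predict_circular(models: ProfileModel | list[ProfileModel],
                     genome: CircularGenome,
                     control_tracks: StrandedTrack | None = None,
                     tile_offset: int = 0) -> PredictedTrack:
    if isinstance(models, ProfileModel):
        models = [models]
    if not models:
        raise ValueError("at least one trained model is required")
    cfg = models[0].config
    n = genome.length
    if n < cfg.output_length:
        raise ValueError("genome shorter than the model output window")
    flank = (cfg.input_length - cfg.output_length) // 2
    starts = tile_starts(n, cfg.output_length, tile_offset)

    acc_plus = np.zeros(n)
    acc_minus = np.zeros(n)
    hits = np.zeros(n)
    for model in models:
        for start in starts:
            seq = genome.onehot((start - flank) % n, cfg.input_length)[None]
            if control_tracks is not None:
                pos = (start + np.arange(cfg.output_length)) % n
                ctrl = np.stack([control_tracks.plus[pos],
                                 control_tracks.minus[pos]])[None]
                ctrl_log = np.array([[np.log1p(ctrl.sum())]])
            else:
                ctrl, ctrl_log = None, None
            probs, total = _predict_window(model, seq, ctrl, ctrl_log)
            pos = (start + np.arange(cfg.output_length)) % n
            acc_plus[pos] += probs[0] * total
            acc_minus[pos] += probs[1] * total
            hits[pos] += 1
    acc_plus /= hits
    acc_minus /= hits
    track = StrandedTrack(genome.name, "predicted", acc_plus, acc_minus)
    return PredictedTrack(track, provenance={
        "n_models": len(models), "tile_offset": tile_offset,
        "input_length": cfg.input_length, "output_length": cfg.output_length,
    })


def predicted_peaks(predicted: PredictedTrack, quantile: float = 0.95,
                    smooth_window: int = 15, min_prominence_fold: float = 2.0,
                    ) -> np.ndarray:
    """Local maxima of the smoothed predicted total above a quantile
    threshold and above ``min_prominence_fold`` times the track median.

    Gaussian smoothing (not a box filter) so isolated spikes keep a
    unique maximum instead of a flat plateau."""
    total = gaussian_filter1d(predicted.total, sigma=smooth_window / 3.0,
                              mode="wrap")
    thr = np.quantile(total, quantile)
    floor = min_prominence_fold * max(np.median(total), 1e-12)
    left = np.roll(total, 1)
    right = np.roll(total, -1)
    is_peak = (total >= left) & (total > right) & (total > thr) & (total >= floor)
    return np.nonzero(is_peak)[0]


def corroboration_score(observed_calls: list[PeakCall], predicted: PredictedTrack,
                        d_max: int = 100, quantile: float = 0.95,
                        ) -> tuple[float, list[bool]]:
    """Fraction of observed occupancy-like summits within ``d_max`` (modular)
    of a predicted peak; predicted-but-unobserved peaks do not penalize.

    Returns (score, per-call matched flags); score is NaN when no
    occupancy-like calls exist.
    """
    n = predicted.length
    peaks = predicted_peaks(predicted, quantile=quantile)
    flags: list[bool] = []
    occupancy = [c for c in observed_calls if c.label == "occupancy_like"]
    for call in occupancy:
        summit = call.region.site_estimate
        if len(peaks) == 0:
            flags.append(False)
            continue
        d = np.abs((peaks - summit + n // 2) % n - n // 2)
        flags.append(bool((d <= d_max).any()))
    if not occupancy:
        return float("nan"), []
    return float(np.mean(flags)), flags
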