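"""Training-set construction.

Peak windows come from a BED-style peak list; outlier peaks whose total
window counts exceed ``outlier_multiplier`` times the configured
quantile are removed; non-peak windows are sampled from peak-free space
with GC content matched to a peak window within a tolerance, at the
configured peaks:non-peaks ratio. Jitter and reverse-complement
augmentation are applied when windows are materialized, so every epoch
sees a fresh draw.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..genome import CircularGenome
from ..tracks import StrandedTrack
from .config import ProfileModelConfig, TrainingConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingWindow:
    """A (contig, centre) pair before materialization."""

    contig: str
    center: int
    is_peak: bool
    gc: float
    fold_key: str


@dataclass
class TrainingExample:
    sequence: np.ndarray  # (4, input_length) one-hot
    target_profile: np.ndarray  # (2, output_length) 5'-end counts
    target_log_total: float
    control_profile: np.ndarray  # (2, output_length), zeros if absent
    control_log_total: float
    fold_key: str


def _window_counts(track: StrandedTrack, center: int, width: int) -> np.ndarray:
    n = track.length
    pos = (center - width // 2 + np.arange(width)) % n
    return np.stack([track.plus[pos], track.minus[pos]])


def _window_gc(genome: CircularGenome, center: int, width: int) -> float:
    seq = genome.fetch((center - width // 2) % genome.length, width)
    return (seq.count("G") + seq.count("C")) / width


def make_training_set(peaks: list[tuple[str, int]],
                      genomes: dict[str, CircularGenome],
                      tracks: dict[str, StrandedTrack],
                      tcfg: TrainingConfig,
                      mcfg: ProfileModelConfig,
                      ) -> list[TrainingWindow]:
    """Peak + GC-matched non-peak windows with per-contig fold keys.

    ``peaks`` rows are (contig, centre position).
    """
    rng = np.random.default_rng(tcfg.seed)
    width = mcfg.output_length

    peak_windows: list[TrainingWindow] = []
    totals = []
    for contig, center in peaks:
        genome = genomes[contig]
        center = center % genome.length
        totals.append(_window_counts(tracks[contig], center, width).sum())
        peak_windows.append(TrainingWindow(contig, center, True,
                                           _window_gc(genome, center, width), contig))
    totals = np.asarray(totals, dtype=float)
    if len(totals):
        cutoff = tcfg.outlier_multiplier * np.quantile(totals, tcfg.outlier_quantile)
        kept = totals <= cutoff
        n_removed = int((~kept).sum())
        if n_removed:
            logger.info("removed %d outlier peaks above %.1f total counts",
                        n_removed, cutoff)
        peak_windows = [w for w, keep in zip(peak_windows, kept) if keep]

    n_nonpeak = int(len(peak_windows) // tcfg.peak_to_nonpeak_ratio)
    nonpeak_windows = _sample_nonpeaks(peak_windows, n_nonpeak, genomes, rng,
                                       width, tcfg.gc_tolerance)
    return peak_windows + nonpeak_windows


def _sample_nonpeaks(peak_windows, n_nonpeak, genomes, rng, width, gc_tol,
                     max_attempts: int = 20000):
    """Uniformly sample peak-free centres whose window GC matches a peak's."""
    free: dict[str, np.ndarray] = {}
    for contig, genome in genomes.items():
        blocked = np.zeros(genome.length, dtype=bool)
        for w in peak_windows:
            if w.contig != contig:
                continue
            pos = (w.center - width + np.arange(2 * width)) % genome.length
            blocked[pos] = True
        free[contig] = np.nonzero(~blocked)[0]
    contigs = [c for c in free if len(free[c])]
    if n_nonpeak and not contigs:
        raise ValueError("no peak-free space available for non-peak sampling")

    out = []
    attempts = 0
    i = 0
    while len(out) < n_nonpeak:
        target_gc = peak_windows[i % len(peak_windows)].gc
        matched = False
        while not matched:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"insufficient peak-free space for GC matching: found "
                    f"{len(out)}/{n_nonpeak} windows within +/-{gc_tol:.3f} GC"
                )
            contig = contigs[int(rng.integers(len(contigs)))]
            center = int(rng.choice(free[contig]))
            gc = _window_gc(genomes[contig], center, width)
            if abs(gc - target_gc) <= gc_tol:
                out.append(TrainingWindow(contig, center, False, gc, contig))
                matched = True
        i += 1
    return out


def materialize(window: TrainingWindow, genomes: dict[str, CircularGenome],
                tracks: dict[str, StrandedTrack], mcfg: ProfileModelConfig,
                control_tracks: dict[str, StrandedTrack] | None = None,
                jitter: int = 0, reverse: bool = False) -> TrainingExample:
    """Turn a window into arrays, applying jitter and optional RC."""
    genome = genomes[window.contig]
    center = (window.center + jitter) % genome.length
    seq = genome.onehot((center - mcfg.input_length // 2) % genome.length,
                        mcfg.input_length)
    target = _window_counts(tracks[window.contig], center, mcfg.output_length)
    if control_tracks is not None:
        control = _window_counts(control_tracks[window.contig], center,
                                 mcfg.output_length)
    else:
        control = np.zeros_like(target)
    if reverse:
        seq = seq[::-1, ::-1].copy()
        target = target[::-1, ::-1].copy()
        control = control[::-1, ::-1].copy()
    return TrainingExample(
        sequence=seq,
        target_profile=target,
        target_log_total=float(np.log1p(target.sum())),
        control_profile=control,
        control_log_total=float(np.log1p(control.sum())),
        fold_key=window.fold_key,
    )


def epoch_examples(windows: list[TrainingWindow],
                   genomes: dict[str, CircularGenome],
                   tracks: dict[str, StrandedTrack],
                   mcfg: ProfileModelConfig, tcfg: TrainingConfig,
                   rng: np.random.Generator,
                   control_tracks: dict[str, StrandedTrack] | None = None,
                   augment: bool = True) -> list[TrainingExample]:
    """One epoch's worth of materialized examples (fresh jitter, RC)."""
    out = []
    for window in windows:
        jitter = (int(rng.integers(-tcfg.jitter_max, tcfg.jitter_max + 1))
                  if (augment and window.is_peak and tcfg.jitter_max) else 0)
        out.append(materialize(window, genomes, tracks, mcfg, control_tracks,
                               jitter=jitter))
        if augment and tcfg.rc_augment:
            out.append(materialize(window, genomes, tracks, mcfg, control_tracks,
                                   jitter=jitter, reverse=True))
    return out
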