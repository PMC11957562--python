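"""Candidate peak calling and strand-asymmetry classification on chrM.

A true punctate occupancy event shows plus-strand 5' ends piling up
upstream and minus-strand 5' ends downstream of the bound site,
separated by roughly the library fragment length; D-loop-like artifacts
are strand-symmetric however strong their enrichment. The classifier
quantifies this with a strand cross-correlation: the lag that maximizes
the correlation between the plus profile and the (left-shifted) minus
profile, and the correlation gain of that lag over lag zero.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .genome import Annotation, CircularGenome
from .mappability import MappabilityTrack
from .tracks import AlignmentSet, StrandedTrack, coverage_track, five_prime_track

logger = logging.getLogger(__name__)


@dataclass
class ScreenParams:
    """All knobs of the screen, each reported alongside the calls."""

    fold_min: float = 3.0
    w_min: int = 25
    # merge gap must exceed the read-body void between the two strand
    # pileups of one site (~fragment_length - 2*read_length)
    g_max: int = 150
    smooth_window: int = 15
    max_lag: int = 500
    lag_min: int = 50
    lag_max: int = 400
    score_min: float = 0.3
    artifact_fold_min: float = 10.0
    mask_overlap_max: float = 0.5
    low_mappability_warn: float = 0.5


@dataclass
class CandidateRegion:
    start: int
    length: int
    genome_length: int
    fold: float = 0.0
    summit_plus: int = 0
    summit_minus: int = 0

    @property
    def end(self) -> int:
        """Half-open end, reduced modularly (may be < start when wrapping)."""
        return (self.start + self.length) % self.genome_length

    def positions(self) -> np.ndarray:
        return (self.start + np.arange(self.length)) % self.genome_length

    @property
    def site_estimate(self) -> int:
        """Modular midpoint of the per-strand summits — the putative bound site."""
        n = self.genome_length
        d = (self.summit_minus - self.summit_plus) % n
        return (self.summit_plus + d // 2) % n


@dataclass
class AsymmetryResult:
    best_lag: int
    corr_best: float
    corr_zero: float
    score: float
    undefined: bool = False


@dataclass
class PeakCall:
    region: CandidateRegion
    asymmetry: AsymmetryResult
    label: str  # occupancy_like | artifact_like | ambiguous | masked
    mappable_fraction: float = 1.0


def masks_to_bool(masks: list[Annotation], genome_length: int) -> np.ndarray:
    out = np.zeros(genome_length, dtype=bool)
    for m in masks:
        out[m.positions(genome_length)] = True
    return out


def _circular_smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.astype(float)
    return uniform_filter1d(values.astype(float), size=window, mode="wrap")


def _circular_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal modular runs of True as (start, length) pairs."""
    n = len(above)
    if above.all():
        return [(0, n)]
    if not above.any():
        return []
    # rotate so position 0 is False, find linear runs, rotate back
    first_false = int(np.argmin(above))
    rolled = np.roll(above, -first_false)
    d = np.diff(rolled.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    ends = np.nonzero(d == -1)[0] + 1
    if rolled[-1]:
        ends = np.append(ends, n)
    return [(int((s + first_false) % n), int(e - s)) for s, e in zip(starts, ends)]


def _merge_runs(runs: list[tuple[int, int]], g_max: int, n: int) -> list[tuple[int, int]]:
    """Merge runs separated by modular gaps <= g_max (runs sorted by start)."""
    if len(runs) <= 1:
        return runs
    runs = sorted(runs)
    merged = [list(runs[0])]
    for start, length in runs[1:]:
        prev_start, prev_len = merged[-1]
        gap = start - (prev_start + prev_len)
        if gap <= g_max:
            merged[-1][1] = start + length - prev_start
        else:
            merged.append([start, length])
    # wrap-around gap between last and first run
    if len(merged) > 1:
        first_start, first_len = merged[0]
        last_start, last_len = merged[-1]
        gap = (first_start - (last_start + last_len)) % n
        if gap <= g_max:
            merged[0] = [last_start, last_len + gap + first_len]
            merged.pop()
    return [tuple(r) for r in merged]


def call_candidates(track: StrandedTrack, mappability: MappabilityTrack,
                    params: ScreenParams | None = None,
                    masks: list[Annotation] | None = None) -> list[CandidateRegion]:
    """Maximal modular runs of smoothed total coverage above
    ``fold_min x background``; background is the median coverage over
    mappable, unmasked bases."""
    params = params or ScreenParams()
    n = track.length
    if mappability.length != n:
        raise ValueError("track and mappability track lengths differ")
    total = track.total
    if not total.any():
        logger.info("all-zero coverage track: no candidates")
        return []
    mask_bool = masks_to_bool(masks or [], n)
    eligible = (mappability.values == 1) & ~mask_bool
    background = float(np.median(total[eligible])) if eligible.any() else 0.0
    if background == 0.0:
        logger.info("zero background estimate; flooring at 1 count")
        background = 1.0
    smoothed = _circular_smooth(total, params.smooth_window)
    runs = _circular_runs(smoothed >= params.fold_min * background)
    runs = _merge_runs(runs, params.g_max, n)
    sm_plus = _circular_smooth(track.plus, params.smooth_window)
    sm_minus = _circular_smooth(track.minus, params.smooth_window)
    regions = []
    for start, length in runs:
        if length < params.w_min:
            continue
        pos = (start + np.arange(length)) % n
        fold = float(smoothed[pos].max() / background)
        summit_plus = int(pos[np.argmax(sm_plus[pos])])
        summit_minus = int(pos[np.argmax(sm_minus[pos])])
        regions.append(CandidateRegion(start, length, n, fold, summit_plus, summit_minus))
    return regions


def asymmetry(track: StrandedTrack, region: CandidateRegion,
              max_lag: int = 500, smooth_window: int = 15) -> AsymmetryResult:
    """Best-lag cross-correlation of the plus 5' profile against the
    left-shifted minus 5' profile over the region padded by ``max_lag``."""
    n = track.length
    if max_lag >= n // 2:
        raise ValueError("max_lag must be below half the genome length")
    pos = (region.start - max_lag + np.arange(region.length + 2 * max_lag)) % n
    plus = _circular_smooth(track.plus, smooth_window)[pos]
    minus = _circular_smooth(track.minus, smooth_window)[pos]
    if track.plus[pos].sum() == 0 or track.minus[pos].sum() == 0:
        return AsymmetryResult(0, float("nan"), float("nan"), float("nan"), undefined=True)
    corrs = np.full(max_lag + 1, np.nan)
    for lag in range(max_lag + 1):
        x = plus[: len(plus) - lag]
        y = minus[lag:]
        if x.std() == 0 or y.std() == 0:
            continue
        corrs[lag] = np.corrcoef(x, y)[0, 1]
    if np.isnan(corrs).all():
        return AsymmetryResult(0, float("nan"), float("nan"), float("nan"), undefined=True)
    best_lag = int(np.nanargmax(corrs))
    corr_best = float(corrs[best_lag])
    corr_zero = float(corrs[0]) if np.isfinite(corrs[0]) else 0.0
    return AsymmetryResult(best_lag, corr_best, corr_zero, corr_best - corr_zero)


def classify(region: CandidateRegion, asym: AsymmetryResult,
             masks: list[Annotation], params: ScreenParams | None = None,
             mappability: MappabilityTrack | None = None) -> PeakCall:
    params = params or ScreenParams()
    n = region.genome_length
    pos = region.positions()
    mask_bool = masks_to_bool(masks, n)
    overlap = float(mask_bool[pos].mean())
    mappable_fraction = (
        float(mappability.values[pos].mean()) if mappability is not None else 1.0
    )
    if overlap > params.mask_overlap_max:
        label = "masked"
    elif asym.undefined:
        label = "ambiguous"
    elif params.lag_min <= asym.best_lag <= params.lag_max and asym.score >= params.score_min:
        label = "occupancy_like"
    elif region.fold >= params.artifact_fold_min:
        label = "artifact_like"
    else:
        label = "ambiguous"
    if mappable_fraction < params.low_mappability_warn:
        logger.warning(
            "region %d-%d has low mappable fraction %.2f",
            region.start, region.start + region.length, mappable_fraction,
        )
    return PeakCall(region, asym, label, mappable_fraction)


def screen_alignments(aln: AlignmentSet, mappability: MappabilityTrack,
                      masks: list[Annotation] | None = None,
                      params: ScreenParams | None = None,
                      ) -> tuple[list[PeakCall], dict]:
    """Full screen: tracks -> candidates -> asymmetry -> classification."""
    params = params or ScreenParams()
    masks = masks or []
    report: dict = {"n_reads": len(aln), "params": params.__dict__.copy()}
    if len(aln) == 0:
        logger.warning("empty alignment set: no calls")
        report["warning"] = "empty alignment set"
        report["n_candidates"] = 0
        return [], report
    cov = coverage_track(aln)
    fp = five_prime_track(aln)
    regions = call_candidates(cov, mappability, params, masks)
    calls = []
    for region in regions:
        asym = asymmetry(fp, region, params.max_lag, params.smooth_window)
        calls.append(classify(region, asym, masks, params, mappability))
    report["n_candidates"] = len(regions)
    report["labels"] = {
        label: sum(1 for c in calls if c.label == label)
        for label in ("occupancy_like", "artifact_like", "ambiguous", "masked")
    }
    report["background_reads_per_base"] = len(aln) / aln.genome_length
    return calls, report


def screen_dataset(sam_path: str, genome: CircularGenome,
                   mappability: MappabilityTrack,
                   masks: list[Annotation] | None = None,
                   params: ScreenParams | None = None,
                   paired: bool = False) -> tuple[list[PeakCall], dict]:
    from .tracks import load_alignments

    aln = load_alignments(sam_path, genome.name, genome.length, paired=paired)
    return screen_alignments(aln, mappability, masks, params)


def write_calls(calls: list[PeakCall], genome_name: str, path: str) -> None:
    """Calls as BED with label, fold, lag and score columns (wrapping
    regions keep one line with end beyond the contig length, flagged)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tlabel\tfold\tbest_lag\tscore\t"
                 "site_estimate\tmappable_fraction\twraps\n")
        for call in calls:
            r = call.region
            wraps = int(r.start + r.length > r.genome_length)
            score = call.asymmetry.score
            fh.write(
                f"{genome_name}\t{r.start}\t{r.start + r.length}\t{call.label}\t"
                f"{r.fold:.4g}\t{call.asymmetry.best_lag}\t"
                f"{'nan' if not np.isfinite(score) else f'{score:.4f}'}\t"
                f"{r.site_estimate}\t{call.mappable_fraction:.3f}\t{wraps}\n"
            )


def write_report(report: dict, path: str) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
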