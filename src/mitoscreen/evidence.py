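"""Cross-dataset evidence tiering and profile clustering.

Datasets assaying the same target are aggregated into discrete evidence
tiers: concordant occupancy-like sites from two distinct reagent
identities (different antibodies, or an antibody plus an epitope tag)
give the strongest tier; replication with a single reagent, a lone
peak-bearing dataset, or disagreement between datasets give weaker ones.
Model corroboration is tracked as an independent flag.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .screen import PeakCall

TIERS = ("orthogonally_replicated", "replicated_same_reagent", "single_dataset",
         "discordant_only", "no_evidence")


@dataclass
class Reagent:
    reagent_class: str  # antibody | epitope_tag
    identifier: str
    lot: str | None = None

    def __post_init__(self) -> None:
        if self.reagent_class not in ("antibody", "epitope_tag"):
            raise ValueError(f"unknown reagent class {self.reagent_class!r}")

    def identity(self, lot_sensitive: bool = False) -> tuple:
        if lot_sensitive:
            return (self.reagent_class, self.identifier, self.lot)
        return (self.reagent_class, self.identifier)


@dataclass
class DatasetRecord:
    dataset_id: str
    target: str
    cell_context: str
    reagent: Reagent
    calls: list[PeakCall] = field(default_factory=list)
    corroboration: float | None = None
    production_group: str = ""

    @property
    def occupancy_summits(self) -> list[int]:
        return [c.region.site_estimate for c in self.calls
                if c.label == "occupancy_like"]

    @property
    def has_peaks(self) -> bool:
        return len(self.occupancy_summits) > 0


@dataclass
class EvidenceSummary:
    target: str
    n_datasets: int
    n_with_peaks: int
    orthogonal_reagents_with_peaks: int
    tier: str
    discordant: bool
    model_corroborated: bool
    concordance: list[dict] = field(default_factory=list)


def modular_distance(a: int, b: int, n: int) -> int:
    return int(abs((a - b + n // 2) % n - n // 2))


def site_concordance(calls_a: list[PeakCall], calls_b: list[PeakCall],
                     genome_length: int, d_max: int = 100,
                     ) -> tuple[list[tuple[int, int]], float]:
    """Greedy nearest-first matching of occupancy-like summits within
    ``d_max`` modular bases; returns matched pairs and the Jaccard-style
    overlap fraction (matches / union)."""
    summits_a = [c.region.site_estimate for c in calls_a if c.label == "occupancy_like"]
    summits_b = [c.region.site_estimate for c in calls_b if c.label == "occupancy_like"]
    pairs = sorted(
        ((modular_distance(a, b, genome_length), i, j)
         for i, a in enumerate(summits_a) for j, b in enumerate(summits_b)),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[tuple[int, int]] = []
    for d, i, j in pairs:
        if d > d_max or i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((summits_a[i], summits_b[j]))
    union = len(summits_a) + len(summits_b) - len(matches)
    fraction = len(matches) / union if union else 0.0
    return matches, fraction


def tier_evidence(records: list[DatasetRecord], genome_length: int,
                  d_max: int = 100, corroboration_min: float = 0.5,
                  lot_sensitive: bool = False) -> EvidenceSummary:
    """Pure function of (calls, reagents, corroborations): permutation of
    dataset order never changes the verdict."""
    if not records:
        raise ValueError("no dataset records supplied")
    targets = {r.target for r in records}
    if len(targets) > 1:
        raise ValueError(f"mixed targets in one evidence group: {sorted(targets)}")
    target = records[0].target
    records = sorted(records, key=lambda r: r.dataset_id)

    peak_bearing = [r for r in records if r.has_peaks]
    n_with_peaks = len(peak_bearing)
    discordant = 0 < n_with_peaks < len(records)

    concordance_rows = []
    concordant_identity_pairs: set[frozenset] = set()
    for i, ra in enumerate(peak_bearing):
        for rb in peak_bearing[i + 1 :]:
            matches, fraction = site_concordance(ra.calls, rb.calls,
                                                 genome_length, d_max)
            concordance_rows.append({
                "dataset_a": ra.dataset_id, "dataset_b": rb.dataset_id,
                "n_matches": len(matches), "overlap": fraction,
            })
            if matches:
                ida = ra.reagent.identity(lot_sensitive)
                idb = rb.reagent.identity(lot_sensitive)
                if ida != idb:
                    concordant_identity_pairs.add(frozenset((ida, idb)))

    orthogonal = len({i for pair in concordant_identity_pairs for i in pair})

    if concordant_identity_pairs:
        tier = "orthogonally_replicated"
    elif n_with_peaks >= 2:
        tier = "replicated_same_reagent"
    elif n_with_peaks == 1:
        tier = "single_dataset" if len(records) == 1 else "discordant_only"
    else:
        tier = "no_evidence"

    model_corroborated = any(
        r.corroboration is not None and r.corroboration >= corroboration_min
        for r in peak_bearing
    )
    return EvidenceSummary(
        target=target,
        n_datasets=len(records),
        n_with_peaks=n_with_peaks,
        orthogonal_reagents_with_peaks=orthogonal,
        tier=tier,
        discordant=discordant,
        model_corroborated=model_corroborated,
        concordance=concordance_rows,
    )


def cluster_profiles(profiles: np.ndarray,
                     exclude_mask: np.ndarray | None = None,
                     labels: list[str] | None = None,
                     ) -> tuple[list[int], np.ndarray]:
    """Average-linkage hierarchical clustering of per-dataset coverage
    vectors under correlation distance.

    Tracks are normalized to unit total over unmasked bases; zero-total
    tracks are excluded with a warning. Returns (leaf order over the
    retained rows, scipy linkage matrix). Ties break by input order
    (scipy's deterministic behaviour for equal distances).
    """
    import logging

    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 2:
        raise ValueError("need a (n_tracks >= 2, genome_length) matrix")
    if exclude_mask is not None:
        profiles = profiles[:, ~np.asarray(exclude_mask, dtype=bool)]
    totals = profiles.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        dropped = [labels[i] if labels else i for i in np.nonzero(~keep)[0]]
        logging.getLogger(__name__).warning("excluding zero-total tracks: %s", dropped)
    profiles = profiles[keep] / totals[keep, None]
    if profiles.shape[0] < 2:
        raise ValueError("fewer than 2 non-empty tracks after exclusion")
    # correlation distance, guarded against zero-variance rows
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[norms == 0] = 1.0
    corr = (centered / norms[:, None]) @ (centered / norms[:, None]).T
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    linkage = average(squareform(dist, checks=False))
    order = [int(i) for i in leaves_list(linkage)]
    return order, linkage


def summary_table(summaries: list[EvidenceSummary]) -> "object":
    """Per-target table of tiers and flags (columns mirror the evidence
    report: any peaks, model corroborated, discordant)."""
    import pandas as pd

    rows = [{
        "target": s.target,
        "n_datasets": s.n_datasets,
        "n_with_peaks": s.n_with_peaks,
        "any": s.n_with_peaks > 0,
        "tier": s.tier,
        "model_corroborated": s.model_corroborated,
        "discordant": s.discordant,
    } for s in summaries]
    return pd.DataFrame(rows).set_index("target")
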