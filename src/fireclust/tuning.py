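"""Per-year minPts (k) selection and the annual clustering driver.

The study period is stratified by calendar year (UTC acquisition date) and
each year is clustered independently, which both tolerates bases moving
between years and yields the per-year persistence timelines downstream.

k is chosen per year by sweeping an integer range (3-8 for Iraq-like
scenes, 2-8 for sparser Afghanistan/Djibouti-like scenes) and taking the k
that minimises the number of noise points while keeping a meaningful
cluster structure. "Meaningful" is operationalised as a cap on the largest
cluster's share of clustered fires (default 0.90): the noise argmin guards
against fragmentation at too-small k, the share cap against a single
all-engulfing cluster at too-large k. Ties go to the smaller k; if no k
satisfies the cap, the unconstrained argmin is used and a warning logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .clustering import NOISE, YearClustering, hdbscan
from .firms_io import FireDetection
from .geodesy import pairwise_distance_matrix

__all__ = ["KSweepRow", "sweep_k", "select_k", "annual_clustering"]

log = logging.getLogger(__name__)

DEFAULT_K_RANGE = (2, 8)
#: Country-specific default sweeps: denser Iraqi scenes start at 3.
COUNTRY_K_RANGES = {"Iraq": (3, 8), "Afghanistan": (2, 8), "Djibouti": (2, 8)}
DEFAULT_MAX_SHARE = 0.90


@dataclass(frozen=True)
class KSweepRow:
    """Summary of one full clustering run at a candidate k."""

    k: int
    n_clusters: int
    n_noise: int
    noise_fraction: float
    median_cluster_size: float  # NaN when there are no clusters
    largest_cluster_share: float  # of clustered fires; 0 when none

    @classmethod
    def from_clustering(cls, yc: YearClustering) -> "KSweepRow":
        labels = yc.labels
        n = len(labels)
        n_noise = int(np.sum(labels == NOISE))
        sizes = np.bincount(labels[labels >= 0]) if n - n_noise else np.empty(0, dtype=int)
        sizes = sizes[sizes > 0]
        return cls(
            k=yc.k,
            n_clusters=yc.n_clusters,
            n_noise=n_noise,
            noise_fraction=n_noise / n if n else 0.0,
            median_cluster_size=float(np.median(sizes)) if sizes.size else float("nan"),
            largest_cluster_share=float(sizes.max() / sizes.sum()) if sizes.size else 0.0,
        )


def sweep_k(points, k_range: tuple[int, int] = DEFAULT_K_RANGE) -> list[KSweepRow]:
    """One full hdbscan run per k in the inclusive range; deterministic.

    Values of k exceeding the point count yield all-noise rows; an empty
    point set yields an empty sweep.
    """
    k_min, k_max = k_range
    if k_min < 2:
        raise ValueError("k range must start at 2 or above")
    if k_min > k_max:
        raise ValueError(f"inverted k range: {k_range}")
    n = len(points)
    if n == 0:
        return []
    D = pairwise_distance_matrix(points) if n >= 2 else None
    rows = []
    for k in range(k_min, k_max + 1):
        yc = hdbscan(points, k, D=D if n >= k else None)
        rows.append(KSweepRow.from_clustering(yc))
    return rows


def select_k(sweep: Sequence[KSweepRow], max_share: float = DEFAULT_MAX_SHARE) -> int:
    """Choose k: minimal noise among rows whose largest-cluster share is
    within ``max_share``; ties break to the smaller k.

    If every row with clusters breaches the cap, the unconstrained noise
    argmin is returned and a warning is logged.
    """
    if not sweep:
        raise ValueError("cannot select k from an empty sweep")
    eligible = [r for r in sweep if r.largest_cluster_share <= max_share]
    pool = eligible
    if not eligible:
        log.warning(
            "no k keeps largest-cluster share <= %.2f; falling back to the "
            "unconstrained noise minimum",
            max_share,
        )
        pool = list(sweep)
    best = min(pool, key=lambda r: (r.n_noise, r.k))
    return best.k


def annual_clustering(
    detections: Sequence[FireDetection],
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    max_share: float = DEFAULT_MAX_SHARE,
) -> dict[int, YearClustering]:
    """Stratify detections by calendar year, tune k and cluster each year.

    Each returned :class:`YearClustering` carries ``indices`` (positions of
    its detections in the input sequence, original order preserved), the
    selected ``k`` and the audit ``sweep``. Years with fewer detections
    than min(k_range) are degenerate all-noise years.
    """
    by_year: dict[int, list[int]] = {}
    for i, det in enumerate(detections):
        by_year.setdefault(det.acq_date.year, []).append(i)

    out: dict[int, YearClustering] = {}
    for year in sorted(by_year):
        idx = np.asarray(by_year[year], dtype=int)
        points = [detections[i].point for i in idx]
        if len(points) < k_range[0]:
            yc = YearClustering(
                year=year,
                k=k_range[0],
                labels=np.full(len(points), NOISE, dtype=int),
                membership_prob=np.zeros(len(points)),
                n_clusters=0,
                noise_fraction=1.0 if points else 0.0,
                degenerate=True,
            )
            yc.indices = idx
            out[year] = yc
            continue
        sweep = sweep_k(points, k_range)
        k = select_k(sweep, max_share)
        yc = hdbscan(points, k, year=year)
        yc.indices = idx
        yc.sweep = sweep
        out[year] = yc
    return out
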