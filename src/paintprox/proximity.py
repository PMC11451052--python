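"""Directed nearest-neighbor proximity statistics between channels.

The core statistic: for every localization of a source channel, the
Euclidean distance to its nearest neighbor in a target channel; distances
at or beyond a cutoff (default 500 nm, strict ``<``) are discarded, and
each directed channel pair is summarized by the median of its retained
distances.  The resulting K×K median matrix is the quantity rendered as a
proximity heatmap; the full per-pair distance samples behind it are kept
for violin-style exports.

Also provides a within-channel localization-precision estimator in the
NeNA family: localizations of the same binding event re-appear in adjacent
camera frames, so the distance between a localization and its nearest
neighbor in the following frame is Rayleigh-distributed with scale
``sqrt(2)·sigma`` for same-site pairs; fitting that mixture over a short
range yields the per-coordinate precision ``sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .io import LocalizationTable

__all__ = [
    "ProximityConfig",
    "DistanceSample",
    "ProximityResult",
    "PrecisionEstimate",
    "InsufficientDataError",
    "nn_distances",
    "median_distance_matrix",
    "export_pair_distances",
    "estimate_precision",
    "rank_partners",
]


class InsufficientDataError(ValueError):
    """Too few localizations for a reliable estimate."""


@dataclass(frozen=True)
class ProximityConfig:
    """Cutoff and summarization options for the median-distance matrix."""

    cutoff: float = 500.0
    symmetrize: bool = False
    min_pair_count: int = 50

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.min_pair_count < 1:
            raise ValueError("min_pair_count must be >= 1")


@dataclass(frozen=True)
class DistanceSample:
    """Directed NN distances from every source localization into a target
    channel, after the cutoff."""

    source_channel: str
    target_channel: str
    distances: np.ndarray
    n_source: int

    @property
    def n_kept(self) -> int:
        return len(self.distances)

    @property
    def median(self) -> float:
        return float(np.median(self.distances)) if self.n_kept else float("nan")


@dataclass(frozen=True)
class ProximityResult:
    """Directed median NN-distance matrix plus the samples behind it."""

    channels: tuple[str, ...]
    median_matrix: pd.DataFrame  # K×K, NaN where a pair is missing
    samples: Mapping[tuple[str, str], DistanceSample]
    config: ProximityConfig


@dataclass(frozen=True)
class PrecisionEstimate:
    channel: str
    sigma: float
    method: str
    n_used: int


def nn_distances(
    source: LocalizationTable, target: LocalizationTable, cutoff: float = 500.0
) -> DistanceSample:
    """Distance from every source localization to its nearest target
    localization; distances >= ``cutoff`` are discarded (strict ``<``).

    An empty target channel yields an empty sample, not an error.  Retained
    distances follow source row order.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    src_xy = source.xy
    tgt_xy = target.xy
    if len(src_xy) == 0 or len(tgt_xy) == 0:
        return DistanceSample(
            source.channel, target.channel, np.empty(0), n_source=len(src_xy)
        )
    tree = cKDTree(tgt_xy)
    d, _ = tree.query(src_xy, k=1, distance_upper_bound=cutoff)
    kept = d[np.isfinite(d) & (d < cutoff)]
    return DistanceSample(source.channel, target.channel, kept, n_source=len(src_xy))


def median_distance_matrix(
    dataset: Mapping[str, LocalizationTable], config: ProximityConfig = ProximityConfig()
) -> ProximityResult:
    """Directed median NN-distance matrix over every ordered channel pair.

    Entry [i, j] is the median of the i→j distance sample; entries whose
    sample is smaller than ``config.min_pair_count`` are NaN.  With
    ``config.symmetrize`` the i→j and j→i samples are pooled and the matrix
    is symmetric.
    """
    channels = tuple(dataset)
    if len(channels) < 2:
        raise ValueError("median_distance_matrix requires at least two channels")
    samples: dict[tuple[str, str], DistanceSample] = {}
    for a in channels:
        for b in channels:
            if a == b:
                continue
            samples[(a, b)] = nn_distances(dataset[a], dataset[b], config.cutoff)
    matrix = pd.DataFrame(np.nan, index=list(channels), columns=list(channels))
    for a in channels:
        matrix.loc[a, a] = 0.0
    if config.symmetrize:
        for i, a in enumerate(channels):
            for b in channels[i + 1 :]:
                pooled = np.concatenate(
                    [samples[(a, b)].distances, samples[(b, a)].distances]
                )
                if len(pooled) >= config.min_pair_count:
                    med = float(np.median(pooled))
                    matrix.loc[a, b] = med
                    matrix.loc[b, a] = med
    else:
        for (a, b), sample in samples.items():
            if sample.n_kept >= config.min_pair_count:
                matrix.loc[a, b] = sample.median
    return ProximityResult(
        channels=channels, median_matrix=matrix, samples=samples, config=config
    )


def export_pair_distances(result: ProximityResult) -> pd.DataFrame:
    """Long-format (source_channel, target_channel, distance_nm) table with
    one row per retained distance — the violin-plot export."""
    frames = []
    for (a, b), sample in result.samples.items():
        if sample.n_kept:
            frames.append(
                pd.DataFrame(
                    {
                        "source_channel": a,
                        "target_channel": b,
                        "distance_nm": sample.distances,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["source_channel", "target_channel", "distance_nm"])
    return pd.concat(frames, ignore_index=True)


def rank_partners(
    result: ProximityResult, query: str
) -> list[tuple[str, float]]:
    """Channels ordered by ascending directed median distance from ``query``.

    Missing (NaN) entries are dropped; ties break alphabetically.
    """
    if query not in result.channels:
        raise KeyError(f"unknown query channel '{query}'")
    row = result.median_matrix.loc[query]
    pairs = [
        (other, float(row[other]))
        for other in result.channels
        if other != query and np.isfinite(row[other])
    ]
    return sorted(pairs, key=lambda p: (p[1], p[0]))


# --------------------------------------------------------------------------
# Localization precision


def _nena_model(d: np.ndarray, sigma: float, amp: float, bg: float) -> np.ndarray:
    # same-site term: Rayleigh with scale sqrt(2)*sigma; background term
    # linear in d (uniform 2D density of unrelated neighbors at short range)
    ss = 2.0 * sigma**2
    return amp * (d / ss) * np.exp(-(d**2) / (2.0 * ss)) + bg * d


def _adjacent_frame_nn(table: LocalizationTable) -> np.ndarray:
    """NN distance from each localization to the next frame's localizations."""
    df = table.data
    frames = df["frame"].to_numpy()
    xy = table.xy
    order = np.argsort(frames, kind="stable")
    frames_sorted = frames[order]
    xy_sorted = xy[order]
    uniq, starts = np.unique(frames_sorted, return_index=True)
    bounds = dict(zip(uniq, zip(starts, np.append(starts[1:], len(frames_sorted)))))
    out = []
    for i, f in enumerate(uniq[:-1]):
        if uniq[i + 1] != f + 1:
            continue
        s0, e0 = bounds[f]
        s1, e1 = bounds[f + 1]
        tree = cKDTree(xy_sorted[s1:e1])
        d, _ = tree.query(xy_sorted[s0:e0], k=1)
        out.append(np.atleast_1d(d))
    return np.concatenate(out) if out else np.empty(0)


def estimate_precision(
    table: LocalizationTable, fit_range: float = 100.0
) -> PrecisionEstimate:
    """Estimate the per-coordinate localization precision of one channel.

    Collects the distance from each localization to its nearest neighbor in
    the *following* camera frame (so that repeated localizations of one
    binding event dominate) and fits, over ``[0, fit_range]`` nm, the
    mixture of a same-site Rayleigh term of scale ``sqrt(2)·sigma`` and a
    linear unrelated-neighbor background.
    """
    if len(table) < 100:
        raise InsufficientDataError(
            f"precision estimation needs >= 100 localizations, got {len(table)}"
        )
    d = _adjacent_frame_nn(table)
    d = d[np.isfinite(d) & (d <= fit_range)]
    if len(d) < 50:
        raise InsufficientDataError(
            "too few adjacent-frame neighbor pairs within fit_range"
        )
    # moment-based Rayleigh start: E[d^2] = 4 sigma^2 for pure same-site pairs
    sigma0 = max(float(np.sqrt(np.mean(d**2) / 4.0)), 1e-3)
    if np.median(d) < 0.5:  # degenerate, essentially noiseless re-localizations
        return PrecisionEstimate(
            table.channel, sigma0, method="nena_adjacent_frame", n_used=len(d)
        )
    nbins = 100
    hist, edges = np.histogram(d, bins=nbins, range=(0.0, fit_range))
    centers = 0.5 * (edges[:-1] + edges[1:])
    try:
        popt, _ = curve_fit(
            _nena_model,
            centers,
            hist.astype(float),
            p0=(sigma0, float(hist.sum()) * (fit_range / nbins), 0.0),
            bounds=([1e-4, 0.0, 0.0], [fit_range, np.inf, np.inf]),
            maxfev=10_000,
        )
        sigma = float(popt[0])
    except RuntimeError:
        sigma = sigma0
    return PrecisionEstimate(
        table.channel, sigma, method="nena_adjacent_frame", n_used=len(d)
    )
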