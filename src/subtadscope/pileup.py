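"""Aggregate Hi-C signal around anchors and anchor pairs.

Pileups average observed/expected submatrices centered on anchor bins (or
on anchor-pair pixels) and optionally normalise by the same average over
random anchor sets, mimicking aggregate peak analysis. Insulation
profiles average the insulation score around anchors per condition.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .contacts import ContactMatrix, InsulationTrack, observed_over_expected
from .io_model import FeatureSet

__all__ = ["PileupResult", "anchor_pileup", "paired_pileup", "insulation_profile"]


@dataclasses.dataclass
class PileupResult:
    """Mean obs/exp window around anchors or anchor pairs."""

    matrix: np.ndarray
    flank: int
    resolution: int
    n_used: int
    n_dropped: int
    normalization: str

    @property
    def center(self) -> int:
        return self.matrix.shape[0] // 2

    def quadrant_means(self) -> dict[str, float]:
        """Mean obs/exp of the four corner quadrants (center row/col excluded).

         'on_diagonal' averages the upstream-upstream and downstream-
        downstream quadrants (within-domain signal); 'cross' averages the
        two cross-anchor quadrants (between-domain signal). Less cross
        signal than on-diagonal signal means the anchor insulates.
        """
        c = self.center
        m = self.matrix
        ul = np.nanmean(m[:c, :c])
        lr = np.nanmean(m[c + 1 :, c + 1 :])
        ur = np.nanmean(m[:c, c + 1 :])
        ll = np.nanmean(m[c + 1 :, :c])
        return {
            "on_diagonal": float((ul + lr) / 2),
            "cross": float((ur + ll) / 2),
        }


def _anchor_bins(anchors: FeatureSet, chrom: str, resolution: int) -> np.ndarray:
    return anchors.midpoints(chrom) // resolution


def _mean_stack(oe: np.ndarray, bins: np.ndarray, w: int) -> tuple[np.ndarray, int, int]:
    n = oe.shape[0]
    acc = np.zeros((2 * w + 1, 2 * w + 1))
    cnt = np.zeros_like(acc)
    used = dropped = 0
    for b in bins.tolist():
        b = int(b)
        if b - w < 0 or b + w >= n:
            dropped += 1
            continue
        win = oe[b - w : b + w + 1, b - w : b + w + 1]
        finite = np.isfinite(win)
        acc[finite] += win[finite]
        cnt += finite
        used += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / cnt, np.nan)
    return mean, used, dropped


def anchor_pileup(
    matrix: ContactMatrix,
    anchors: FeatureSet,
    flank: int = 200_000,
    n_random_sets: int = 10,
    seed: int = 0,
    oe: np.ndarray | None = None,
) -> PileupResult:
    """Average obs/exp window centered on each anchor's diagonal pixel.

    With ``n_random_sets`` > 0 the average is divided element-wise by the
    mean pileup over that many equinumerous uniform anchor sets, removing
    residual distance-decay structure; with 0 the raw obs/exp average is
    returned. Anchors whose window leaves the matrix are dropped and
    counted.
    """
    if flank % matrix.resolution != 0:
        raise ValueError("flank must be a multiple of the resolution")
    w = flank // matrix.resolution
    if oe is None:
        oe = observed_over_expected(matrix)
    bins = _anchor_bins(anchors, matrix.chrom, matrix.resolution)
    mean, used, dropped = _mean_stack(oe, bins, w)
    if used == 0:
        raise ValueError("no usable anchors (all windows leave the matrix)")
    norm = "oe"
    if n_random_sets > 0:
        rng = np.random.default_rng(seed)
        acc = np.zeros_like(mean)
        for _ in range(n_random_sets):
            rand_bins = rng.integers(w, matrix.n_bins - w, size=used)
            rmean, _, _ = _mean_stack(oe, rand_bins, w)
            acc += rmean
        mean = mean / (acc / n_random_sets)
        norm = f"oe/random({n_random_sets})"
    return PileupResult(mean, flank, matrix.resolution, used, dropped, norm)


def paired_pileup(
    matrix: ContactMatrix,
    anchors_a: FeatureSet,
    anchors_b: FeatureSet,
    flank: int = 50_000,
    min_sep: int = 100_000,
    max_sep: int = 2_000_000,
    oe: np.ndarray | None = None,
) -> PileupResult:
    """Average obs/exp window centered on off-diagonal anchor-pair pixels.

    Pairs (a, b) on the matrix chromosome with min_sep <= |a - b| <=
    max_sep contribute the window centered on pixel (a, b) with the
    upstream anchor as the row. ``min_sep`` must exceed 2 x flank so
    windows never cross the diagonal.
    """
    if flank % matrix.resolution != 0:
        raise ValueError("flank must be a multiple of the resolution")
    if min_sep <= 2 * flank:
        raise ValueError("min_sep must exceed 2 x flank")
    w = flank // matrix.resolution
    if oe is None:
        oe = observed_over_expected(matrix)
    n = matrix.n_bins
    ba = _anchor_bins(anchors_a, matrix.chrom, matrix.resolution)
    bb = _anchor_bins(anchors_b, matrix.chrom, matrix.resolution)
    lo, hi = min_sep // matrix.resolution, max_sep // matrix.resolution
    acc = np.zeros((2 * w + 1, 2 * w + 1))
    cnt = np.zeros_like(acc)
    used = dropped = 0
    for a in ba.tolist():
        for b in bb.tolist():
            if not (lo <= abs(a - b) <= hi):
                continue
            i, j = (int(a), int(b)) if a < b else (int(b), int(a))
            if i - w < 0 or j + w >= n:
                dropped += 1
                continue
            win = oe[i - w : i + w + 1, j - w : j + w + 1]
            finite = np.isfinite(win)
            acc[finite] += win[finite]
            cnt += finite
            used += 1
    if used == 0:
        raise ValueError("no valid anchor pairs in the separation range")
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / cnt, np.nan)
    return PileupResult(mean, flank, matrix.resolution, used, dropped, "oe")


def center_enrichment(result: PileupResult) -> float:
    """Central-pixel value over the mean of the window's outer frame."""
    c = result.center
    m = result.matrix
    frame = np.concatenate([m[0, :], m[-1, :], m[1:-1, 0], m[1:-1, -1]])
    return float(m[c, c] / np.nanmean(frame))


def insulation_profile(
    tracks: dict[str, InsulationTrack], anchors: FeatureSet, flank: int = 200_000
) -> dict[str, np.ndarray]:
    """Per-condition mean insulation score around anchors.

    For each condition, the mean score at every offset in [-flank, +flank]
    across anchors; missing bins are excluded per offset. All tracks must
    share the resolution.
    """
    if len(anchors) == 0:
        raise ValueError("empty anchor set")
    out: dict[str, np.ndarray] = {}
    for name, track in tracks.items():
        if flank % track.resolution != 0:
            raise ValueError("flank must be a multiple of the resolution")
        w = flank // track.resolution
        bins = _anchor_bins(anchors, track.chrom, track.resolution)
        n = len(track.scores)
        acc = np.zeros(2 * w + 1)
        cnt = np.zeros(2 * w + 1)
        for b in bins.tolist():
            b = int(b)
            if b - w < 0 or b + w >= n:
                continue
            win = track.scores[b - w : b + w + 1]
            finite = np.isfinite(win)
            acc[finite] += win[finite]
            cnt += finite
        with np.errstate(invalid="ignore"):
            out[name] = np.where(cnt > 0, acc / cnt, np.nan)
    return out
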