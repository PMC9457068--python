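"""Contact-matrix numerics.

Balancing (iterative proportional fitting), distance-decay expected
profiles, diamond insulation scores, and cross-sample correlation of
observed/expected maps. Everything here is cis (per chromosome); trans
contacts are out of scope.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "ContactMatrix",
    "ExpectedProfile",
    "InsulationTrack",
    "balance",
    "expected_profile",
    "observed_over_expected",
    "insulation_track",
    "matrix_correlation",
]


@dataclasses.dataclass
class ContactMatrix:
    """Symmetric binned contact counts for one chromosome.

    ``mask`` flags valid bins; masked bins are excluded from every
    downstream statistic.
    """

    chrom: str
    resolution: int
    counts: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if self.mask is None:
            self.mask = np.ones(self.n_bins, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.n_bins,):
                raise ValueError("mask length must equal number of bins")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def bin_of(self, position: int) -> int:
        return int(position // self.resolution)


@dataclasses.dataclass
class ExpectedProfile:
    """Mean contact per bin-separation for one chromosome."""

    chrom: str
    resolution: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclasses.dataclass
class InsulationTrack:
    """Per-bin insulation score (log2 ratio to chromosome mean).

    ``scores`` is NaN where undefined (within the window of a chromosome
    edge, or at masked bins).
    """

    chrom: str
    resolution: int
    window_bins: int
    scores: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.scores)


def balance(
    matrix: ContactMatrix, tol: float = 1e-3, max_iter: int = 200
) -> ContactMatrix:
    """Iteratively balance a matrix so valid-bin row sums are equal.

    Standard ICE-style proportional fitting: each round divides the matrix
    by the outer product of its (mean-normalised) row sums. Rows with zero
    sum are masked out. Raises if the relative row-sum deviation does not
    reach ``tol`` within ``max_iter`` rounds.
    """
    m = matrix.counts.copy()
    mask = matrix.mask.copy()
    mask &= m.sum(axis=1) > 0
    if not mask.any():
        raise ValueError("no valid bins to balance")
    m[~mask, :] = 0.0
    m[:, ~mask] = 0.0
    residual = np.inf
    for _ in range(max_iter):
        s = m[np.ix_(mask, mask)].sum(axis=1)
        s = s / s.mean()
        residual = float(np.abs(s - 1.0).max())
        if residual <= tol:
            break
        full = np.ones(matrix.n_bins)
        full[mask] = np.sqrt(s)  # damped symmetric update; plain division oscillates
        m /= np.outer(full, full)
    else:
        raise RuntimeError(
            f"balancing did not converge in {max_iter} iterations "
            f"(last residual {residual:.3g})"
        )
    return ContactMatrix(matrix.chrom, matrix.resolution, m, mask)


def expected_profile(matrix: ContactMatrix) -> ExpectedProfile:
    """Mean contact over valid bin pairs at each separation."""
    n = matrix.n_bins
    mask = matrix.mask.astype(float)
    values = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(matrix.counts, offset=d)
        w = mask[: n - d] * mask[d:]
        if w.sum() > 0:
            values[d] = (diag * w).sum() / w.sum()
    return ExpectedProfile(matrix.chrom, matrix.resolution, values)


def observed_over_expected(
    matrix: ContactMatrix, expected: ExpectedProfile | None = None
) -> np.ndarray:
    """Observed/expected matrix; NaN at masked bins or zero expectation."""
    if expected is None:
        expected = expected_profile(matrix)
    n = matrix.n_bins
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    exp = expected.values[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp > 0, matrix.counts / exp, np.nan)
    invalid = ~matrix.mask
    oe[invalid, :] = np.nan
    oe[:, invalid] = np.nan
    return oe


def insulation_track(
    matrix: ContactMatrix, window: int, normalization: str = "chrom_mean"
) -> InsulationTrack:
    """Diamond insulation score after the square-window convention.

    For bin i the raw score S(i) sums contacts between the ``w`` bins to the
    left and the ``w`` bins to the right of i (bin i excluded), where
    w = window / resolution. The reported score is log2(S(i) / mean S over
    valid bins). Undefined within w bins of either chromosome edge and at
    masked bins.
    """
    if normalization != "chrom_mean":
        raise ValueError(f"unknown normalization {normalization!r}")
    if window % matrix.resolution != 0:
        raise ValueError("window must be a multiple of the resolution")
    w = window // matrix.resolution
    if w < 2:
        raise ValueError("window must span at least 2 bins")
    n = matrix.n_bins
    if 2 * w + 1 > n:
        raise ValueError("window larger than chromosome")
    # summed-area table for O(1) rectangle sums
    sat = np.zeros((n + 1, n + 1))
    sat[1:, 1:] = matrix.counts.cumsum(axis=0).cumsum(axis=1)

    def rect(r0: int, r1: int, c0: int, c1: int) -> float:
        # sum of counts[r0:r1, c0:c1]
        return sat[r1, c1] - sat[r0, c1] - sat[r1, c0] + sat[r0, c0]

    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        raw[i] = rect(i - w, i, i + 1, i + w + 1)
    raw[~matrix.mask] = np.nan
    valid = np.isfinite(raw)
    mean = np.nanmean(raw[valid]) if valid.any() else np.nan
    if not valid.any() or mean <= 0:
        raise ValueError("insulation undefined: no valid window sums")
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(valid & (raw > 0), np.log2(raw / mean), np.nan)
    return InsulationTrack(matrix.chrom, matrix.resolution, w, scores)


def matrix_correlation(
    a: ContactMatrix, b: ContactMatrix, max_distance: int = 2_000_000
) -> float:
    """Pearson correlation of obs/exp values between two samples.

    Restricted to valid bin pairs (upper triangle including the diagonal)
    separated by at most ``max_distance``; both matrices must share the
    chromosome, resolution and bin count.
    """
    if (a.chrom, a.resolution, a.n_bins) != (b.chrom, b.resolution, b.n_bins):
        raise ValueError("matrices must share chromosome, resolution and shape")
    max_bins = max_distance // a.resolution
    oe_a = observed_over_expected(a)
    oe_b = observed_over_expected(b)
    n = a.n_bins
    ii, jj = np.triu_indices(n)
    keep = (jj - ii) <= max_bins
    va, vb = oe_a[ii[keep], jj[keep]], oe_b[ii[keep], jj[keep]]
    finite = np.isfinite(va) & np.isfinite(vb)
    if finite.sum() < 2:
        raise ValueError("no shared valid pixels within the distance cap")
    return float(np.corrcoef(va[finite], vb[finite])[0, 1])
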