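"""Differential occupancy classification and genomic-context annotation.

Peaks are quantified as library-size-normalised mean signal per replicate;
differential binding uses a pooled-variance z-test on log2 densities with
Benjamini-Hochberg adjustment, and classes follow fold-change / FDR
thresholds (FDR < 0.01 with |logFC| > 1 for CTCF-style calls; FDR <= 0.05
with |logFC| >= 1 for histone marks).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import FeatureSet

__all__ = [
    "DiffThresholds",
    "CTCF_THRESHOLDS",
    "MARK_THRESHOLDS",
    "score_peaks",
    "pooled_z_pvalues",
    "classify_differential",
    "annotate_context",
    "tss_metaprofile",
]


@dataclasses.dataclass(frozen=True)
class DiffThresholds:
    fdr_max: float = 0.01
    logfc_min: float = 1.0
    # mark-style calls use inclusive comparisons (|logFC| >= 1, FDR <= 0.05)
    inclusive: bool = False


CTCF_THRESHOLDS = DiffThresholds(fdr_max=0.01, logfc_min=1.0, inclusive=False)
MARK_THRESHOLDS = DiffThresholds(fdr_max=0.05, logfc_min=1.0, inclusive=True)


def score_peaks(
    peaks: FeatureSet,
    tracks: dict[str, "BinnedTrack"],
) -> pd.DataFrame:
    """Library-size-normalised mean signal per peak per replicate.

    ``tracks`` maps replicate name to a BinnedTrack. Each peak's density
    is the mean per-bp signal over the peak interval, divided by the
    track's total signal and scaled to reads-per-million.
    """
    rows = {}
    for rep, track in tracks.items():
        total = track.total()
        if total <= 0:
            rows[rep] = np.zeros(len(peaks))
            continue
        vals = np.empty(len(peaks))
        for i, iv in enumerate(peaks):
            vals[i] = track.mean_over(iv.chrom, iv.start, iv.end)
        rows[rep] = vals / total * 1e6
    return pd.DataFrame(rows)


class BinnedTrack:
    """Per-chromosome signal defined on fixed-size bins (bedGraph-like)."""

    def __init__(self, values: dict[str, np.ndarray], bin_size: int):
        self.values = {c: np.asarray(v, dtype=float) for c, v in values.items()}
        self.bin_size = bin_size

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        if chrom not in self.values:
            raise ValueError(f"peak on {chrom} outside track extent")
        v = self.values[chrom]
        if end > len(v) * self.bin_size:
            raise ValueError(f"peak [{start},{end}) outside track extent on {chrom}")
        # bp-weighted mean over partially covered bins
        acc = 0.0
        b0, b1 = start // self.bin_size, (end - 1) // self.bin_size
        for b in range(b0, b1 + 1):
            lo = max(start, b * self.bin_size)
            hi = min(end, (b + 1) * self.bin_size)
            acc += v[b] * (hi - lo)
        return acc / (end - start)

    @staticmethod
    def from_bedgraph(fs: FeatureSet, bin_size: int, chrom_sizes: dict[str, int]) -> "BinnedTrack":
        vals = {c: np.zeros(-(-chrom_sizes[c] // bin_size)) for c in chrom_sizes}
        if fs.scores is None:
            raise ValueError("bedGraph FeatureSet lacks values")
        for iv, s in zip(fs.intervals, fs.scores):
            b0, b1 = iv.start // bin_size, (iv.end - 1) // bin_size
            for b in range(b0, b1 + 1):
                vals[iv.chrom][b] = s
        return BinnedTrack(vals, bin_size)


def pooled_z_pvalues(log_treat: np.ndarray, log_ctl: np.ndarray) -> np.ndarray:
    """Two-sided p-values from a z-test with variance pooled across peaks.

    Per-peak replicate variances (on log2 densities) are averaged over all
    peaks and both conditions, giving a stable noise estimate at two
    replicates per condition.
    """
    log_treat = np.atleast_2d(log_treat)
    log_ctl = np.atleast_2d(log_ctl)
    n_t, n_c = log_treat.shape[1], log_ctl.shape[1]
    if n_t < 2 or n_c < 2:
        raise ValueError("need >= 2 replicates per condition")
    var_within = np.concatenate(
        [log_treat.var(axis=1, ddof=1), log_ctl.var(axis=1, ddof=1)]
    )
    pooled = float(var_within.mean())
    if pooled <= 0:
        pooled = 1e-12
    se = np.sqrt(pooled * (1.0 / n_t + 1.0 / n_c))
    z = (log_treat.mean(axis=1) - log_ctl.mean(axis=1)) / se
    return 2.0 * stats.norm.sf(np.abs(z))


def classify_differential(
    densities: pd.DataFrame,
    thresholds: DiffThresholds = CTCF_THRESHOLDS,
    treat_cols: list[str] | None = None,
    ctl_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Classify peaks constant / lost / gained from replicate densities.

    logFC = log2((mean_treat + 1) / (mean_ctl + 1)) with a pseudo-count of
    one; p-values from the pooled-variance z-test on log2(density + 1);
    FDR by Benjamini-Hochberg over all peaks. lost: FDR below threshold
    and logFC below -logfc_min; gained symmetric; otherwise constant.
    """
    treat_cols = treat_cols or [c for c in densities.columns if c.startswith("trt")]
    ctl_cols = ctl_cols or [c for c in densities.columns if c.startswith("ctl")]
    if len(treat_cols) < 2 or len(ctl_cols) < 2:
        raise ValueError("need >= 2 replicates per condition")
    t = densities[treat_cols].to_numpy(dtype=float)
    c = densities[ctl_cols].to_numpy(dtype=float)
    logfc = np.log2((t.mean(axis=1) + 1) / (c.mean(axis=1) + 1))
    pvals = pooled_z_pvalues(np.log2(t + 1), np.log2(c + 1))
    fdr = multipletests(pvals, method="fdr_bh")[1]
    th = thresholds
    if th.inclusive:
        sig = fdr <= th.fdr_max
        lost = sig & (logfc <= -th.logfc_min)
        gained = sig & (logfc >= th.logfc_min)
    else:
        sig = fdr < th.fdr_max
        lost = sig & (logfc < -th.logfc_min)
        gained = sig & (logfc > th.logfc_min)
    out = densities.copy()
    out["logfc"] = logfc
    out["pvalue"] = pvals
    out["fdr"] = fdr
    out["class"] = np.where(lost, "lost", np.where(gained, "gained", "constant"))
    return out


def annotate_context(
    features: FeatureSet, genes: pd.DataFrame, promoter_flank: int = 3_000
) -> pd.Series:
    """Assign each feature a genomic context category.

    ``genes`` needs columns chrom, tss, start, end (gene extents). A
    feature overlapping any TSS +/- ``promoter_flank`` is a promoter;
    otherwise overlap with a gene body makes it gene_body; otherwise
    distal_intergenic. Precedence promoter > gene body > distal.
    """
    if len(genes) == 0:
        warnings.warn("empty gene model: all features distal intergenic")
        return pd.Series(["distal_intergenic"] * len(features))
    cats = []
    by_chrom = {c: g for c, g in genes.groupby("chrom")}
    for iv in features:
        g = by_chrom.get(iv.chrom)
        if g is None:
            cats.append("distal_intergenic")
            continue
        tss = g["tss"].to_numpy()
        if ((iv.start < tss + promoter_flank + 1) & (iv.end > tss - promoter_flank)).any():
            cats.append("promoter")
        elif ((iv.start < g["end"].to_numpy()) & (iv.end > g["start"].to_numpy())).any():
            cats.append("gene_body")
        else:
            cats.append("distal_intergenic")
    return pd.Series(cats)


def tss_metaprofile(
    track: BinnedTrack, genes: pd.DataFrame, flank: int = 3_000
) -> np.ndarray:
    """Average signal around TSSs, strand-oriented.

    Returns the per-bin mean across genes over [-flank, +flank] at the
    track's bin size; minus-strand windows are reversed before averaging.
    Genes whose window leaves the track extent are dropped (a warning
    reports how many).
    """
    if len(genes) == 0:
        raise ValueError("empty gene subset")
    bs = track.bin_size
    w = flank // bs
    profiles = []
    dropped = 0
    for g in genes.itertuples():
        v = track.values.get(g.chrom)
        if v is None:
            dropped += 1
            continue
        b = int(g.tss) // bs
        if b - w < 0 or b + w >= len(v):
            dropped += 1
            continue
        win = v[b - w : b + w + 1]
        if getattr(g, "strand", "+") == "-":
            win = win[::-1]
        profiles.append(win)
    if not profiles:
        raise ValueError("no gene window fits the track extent")
    if dropped:
        warnings.warn(f"{dropped} genes dropped (window outside track extent)")
    return np.mean(profiles, axis=0)
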