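"""Core genomic containers and plain-text readers/writers.

All coordinates are 0-based half-open internally. Chromosome names are taken
verbatim (no ``chr`` prefix munging). Supported external formats: BED (3-6
columns), bedGraph, tab-separated expression tables with a header, GMT gene
sets, and sparse triplet text (``bin_i<TAB>bin_j<TAB>count``) plus a
``chrom.sizes`` file for contact matrices.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "FeatureSet",
    "ExpressionThresholds",
    "load_feature_set",
    "write_feature_set",
    "load_contact_matrix",
    "write_contact_matrix",
    "load_expression_table",
    "classify_expression",
    "load_gene_sets",
    "load_chrom_sizes",
]

VALID_STRANDS = {"+", "-", "."}


@dataclasses.dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def tss(self) -> int:
        """Transcription start: interval start on +/. strands, end-1 on -."""
        return self.end - 1 if self.strand == "-" else self.start


class FeatureSet:
    """An ordered collection of intervals with optional scalar scores.

    Intervals are kept sorted by (chrom, start, end). Scores, when present,
    are floats aligned with the intervals; NaN is rejected unless the feature
    is explicitly flagged missing at load time.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        scores: Iterable[float] | None = None,
        names: Iterable[str] | None = None,
    ) -> None:
        ivs = list(intervals)
        sc = None if scores is None else np.asarray(list(scores), dtype=float)
        nm = None if names is None else list(names)
        if sc is not None and len(sc) != len(ivs):
            raise ValueError("scores length must match intervals")
        if nm is not None and len(nm) != len(ivs):
            raise ValueError("names length must match intervals")
        if sc is not None and np.isnan(sc).any():
            raise ValueError("NaN scores not allowed")
        order = sorted(range(len(ivs)), key=lambda i: (ivs[i].chrom, ivs[i].start, ivs[i].end))
        self.intervals = [ivs[i] for i in order]
        self.scores = None if sc is None else sc[order]
        self.names = None if nm is None else [nm[i] for i in order]

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureSet):
            return NotImplemented
        if self.intervals != other.intervals:
            return False
        if len(self.intervals) == 0:
            return True
        a, b = self.scores, other.scores
        if (a is None) != (b is None):
            return False
        return a is None or bool(np.allclose(a, b))

    def midpoints(self, chrom: str | None = None) -> np.ndarray:
        ivs = self.intervals if chrom is None else [iv for iv in self.intervals if iv.chrom == chrom]
        return np.array([iv.midpoint for iv in ivs], dtype=np.int64)

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def subset(self, mask: Iterable[bool]) -> "FeatureSet":
        mask = list(mask)
        ivs = [iv for iv, m in zip(self.intervals, mask) if m]
        sc = None if self.scores is None else self.scores[np.asarray(mask, dtype=bool)]
        nm = None if self.names is None else [n for n, m in zip(self.names, mask) if m]
        return FeatureSet(ivs, sc, nm)


def load_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom.sizes`` file into an ordered mapping."""
    sizes: dict[str, int] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 'chrom<TAB>size'")
        sizes[parts[0]] = int(parts[1])
    return sizes


def load_feature_set(path: str | Path, format: str = "BED") -> FeatureSet:
    """Load a BED (3-6 col) or bedGraph file as a sorted FeatureSet.

    Unsorted input is sorted, not rejected. bedGraph values become scores;
    BED column 5 becomes the score when present.
    """
    fmt = format.upper()
    if fmt not in {"BED", "BEDGRAPH"}:
        raise ValueError(f"unsupported format {format!r}")
    intervals: list[GenomicInterval] = []
    scores: list[float] = []
    names: list[str] = []
    has_scores = False
    has_names = False
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        try:
            if fmt == "BEDGRAPH":
                if len(parts) != 4:
                    raise ValueError("bedGraph needs 4 columns")
                chrom, start, end, value = parts
                intervals.append(GenomicInterval(chrom, int(start), int(end)))
                scores.append(float(value))
                names.append("")
                has_scores = True
            else:
                if len(parts) < 3:
                    raise ValueError("BED needs >= 3 columns")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                strand = parts[5] if len(parts) >= 6 else "."
                intervals.append(GenomicInterval(chrom, start, end, strand))
                if len(parts) >= 4:
                    names.append(parts[3])
                    has_names = True
                else:
                    names.append("")
                if len(parts) >= 5:
                    scores.append(float(parts[4]))
                    has_scores = True
                else:
                    scores.append(0.0)
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: {exc}") from exc
    return FeatureSet(
        intervals,
        scores if has_scores else None,
        names if has_names else None,
    )


def write_feature_set(fs: FeatureSet, path: str | Path, format: str = "BED") -> None:
    fmt = format.upper()
    lines = []
    for i, iv in enumerate(fs.intervals):
        if fmt == "BEDGRAPH":
            val = 0.0 if fs.scores is None else fs.scores[i]
            lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{val:g}")
        else:
            name = fs.names[i] if fs.names is not None else "."
            score = fs.scores[i] if fs.scores is not None else 0.0
            lines.append(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name or '.'}\t{score:g}\t{iv.strand}"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def load_contact_matrix(
    path: str | Path, resolution: int, chrom_sizes: Mapping[str, int], chrom: str
):
    """Load a sparse triplet file into a symmetric ContactMatrix.

    Rows are ``bin_i<TAB>bin_j<TAB>count``; missing entries are zero, the
    matrix is symmetrised (M[i,j] = M[j,i]).
    """
    from .contacts import ContactMatrix

    n_bins = -(-chrom_sizes[chrom] // resolution)
    mat = np.zeros((n_bins, n_bins), dtype=float)
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{ln}: expected 'bin_i bin_j count'")
        i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
        if not (0 <= i < n_bins and 0 <= j < n_bins):
            raise ValueError(f"{path}:{ln}: bin index outside chromosome extent")
        if c < 0:
            raise ValueError(f"{path}:{ln}: negative count")
        mat[i, j] = c
        mat[j, i] = c
    return ContactMatrix(chrom=chrom, resolution=resolution, counts=mat)


def write_contact_matrix(matrix, path: str | Path) -> None:
    """Write the upper triangle of a ContactMatrix as triplet text."""
    ii, jj = np.nonzero(np.triu(matrix.counts))
    with open(path, "w") as fh:
        for i, j in zip(ii.tolist(), jj.tolist()):
            fh.write(f"{i}\t{j}\t{matrix.counts[i, j]:.17g}\n")


@dataclasses.dataclass(frozen=True)
class ExpressionThresholds:
    """Significance configuration for expression class calls.

    A gene is called up/down when its mean normalised count clears
    ``basemean_min``, |log2FC| clears ``lfc_min`` and the BH-adjusted p is
    below ``padj_max``; unaltered requires padj above ``unaltered_padj_min``
    with |log2FC| under ``unaltered_lfc_max``; everything else is "other".
    """

    basemean_min: float = 100.0
    lfc_min: float = 1.0
    padj_max: float = 0.05
    unaltered_padj_min: float = 0.05
    unaltered_lfc_max: float = 0.5


EXPRESSION_COLUMNS = ["gene_id", "chrom", "tss", "strand", "basemean", "log2fc", "padj"]


def classify_expression(
    df: pd.DataFrame, thresholds: ExpressionThresholds | None = None
) -> pd.Series:
    """Assign each gene exactly one class: up, down, unaltered or other."""
    th = thresholds or ExpressionThresholds()
    sig = (df["basemean"] > th.basemean_min) & (df["padj"] < th.padj_max)
    up = sig & (df["log2fc"] > th.lfc_min)
    down = sig & (df["log2fc"] < -th.lfc_min)
    unaltered = (
        ~up
        & ~down
        & (df["padj"] > th.unaltered_padj_min)
        & (df["log2fc"].abs() < th.unaltered_lfc_max)
    )
    cls = pd.Series("other", index=df.index, dtype=object)
    cls[unaltered] = "unaltered"
    cls[up] = "up"
    cls[down] = "down"
    return cls


def load_expression_table(
    path: str | Path, thresholds: ExpressionThresholds | None = None
) -> pd.DataFrame:
    """Load a TSV expression table and assign significance classes.

    Required columns: gene_id, chrom, tss, strand, basemean, log2fc, padj.
    Rows with missing padj are rejected (the upstream differential test is
    expected to report a p for every retained gene).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df["padj"].isna().any():
        raise ValueError(f"{path}: missing padj values are not supported")
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise ValueError(f"{path}: padj outside [0, 1]")
    if (df["basemean"] < 0).any():
        raise ValueError(f"{path}: negative basemean")
    df = df.copy()
    df["class"] = classify_expression(df, thresholds)
    return df


def load_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets: name<TAB>description<TAB>gene1<TAB>gene2..."""
    sets: dict[str, list[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT needs name, description, >=1 gene")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
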