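"""Boundary calling and cross-condition boundary classification.

Boundaries are local minima of the insulation score; a two-scale scan
(coarse window for TADs, fine window for subTADs) yields a two-level
hierarchy. Boundary sets from a control and two perturbed clones are
classified constant / lost / gained / discordant by optimal one-to-one
matching within a genomic tolerance.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.signal import find_peaks

from .contacts import ContactMatrix, InsulationTrack, balance, insulation_track

__all__ = [
    "BoundarySet",
    "BoundaryClassTable",
    "CalledHierarchy",
    "call_boundaries",
    "call_hierarchy",
    "classify_boundaries",
    "gained_lost_adjacency",
]


@dataclasses.dataclass
class BoundarySet:
    """Called boundaries of one level across chromosomes.

    ``df`` columns: chrom, bin, pos (bp, the bin start), strength
    (prominence of the insulation minimum, log2 units).
    """

    level: str
    resolution: int
    df: pd.DataFrame
    chrom_sizes: dict[str, int] | None = None

    def positions(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "pos"].to_numpy(dtype=np.int64)

    def __len__(self) -> int:
        return len(self.df)

    @staticmethod
    def from_bins(
        level: str,
        resolution: int,
        bins_by_chrom: dict[str, np.ndarray],
        strengths_by_chrom: dict[str, np.ndarray] | None = None,
        chrom_sizes: dict[str, int] | None = None,
    ) -> "BoundarySet":
        rows = []
        for chrom, bins in bins_by_chrom.items():
            s = (
                strengths_by_chrom[chrom]
                if strengths_by_chrom is not None
                else np.ones(len(bins))
            )
            for b, st in zip(np.asarray(bins).tolist(), np.asarray(s).tolist()):
                rows.append(dict(chrom=chrom, bin=int(b), pos=int(b) * resolution, strength=st))
        df = pd.DataFrame(rows, columns=["chrom", "bin", "pos", "strength"])
        return BoundarySet(level, resolution, df, chrom_sizes)


@dataclasses.dataclass
class CalledHierarchy:
    """Two-level called boundary model (TAD + subTAD sets)."""

    tad: BoundarySet
    subtad: BoundarySet


@dataclasses.dataclass
class BoundaryClassTable:
    """Cross-condition boundary classes.

    One row per distinct boundary event: class in {constant, lost, gained,
    discordant}, the reference position (control position for control-borne
    events, mean clone position for gained), and matched partner positions
    (NaN when absent).
    """

    level: str
    resolution: int
    df: pd.DataFrame
    chrom_sizes: dict[str, int] | None = None

    def positions(self, cls: str, chrom: str | None = None) -> np.ndarray:
        sel = self.df["class"] == cls
        if chrom is not None:
            sel &= self.df["chrom"] == chrom
        return self.df.loc[sel, "pos"].to_numpy(dtype=np.int64)

    def counts(self) -> dict[str, int]:
        return self.df["class"].value_counts().to_dict()


def call_boundaries(track: InsulationTrack, min_prominence: float = 0.15) -> BoundarySet:
    """Boundaries = local minima of the insulation score with prominence
    at least ``min_prominence`` (log2 units).

    NaN stretches split the track; minima are searched within each finite
    segment independently, so prominence never leaks across gaps.
    """
    scores = track.scores
    finite = np.isfinite(scores)
    if not finite.any():
        raise ValueError("insulation track has no defined bins")
    bins: list[int] = []
    strengths: list[float] = []
    # iterate over maximal finite runs
    idx = np.flatnonzero(finite)
    splits = np.flatnonzero(np.diff(idx) > 1)
    for seg in np.split(idx, splits + 1):
        if len(seg) < 3:
            continue
        seg_scores = scores[seg]
        peaks, props = find_peaks(-seg_scores, prominence=min_prominence)
        bins.extend((seg[0] + peaks).tolist())
        strengths.extend(props["prominences"].tolist())
    return BoundarySet.from_bins(
        "generic",
        track.resolution,
        {track.chrom: np.array(bins, dtype=np.int64)},
        {track.chrom: np.array(strengths)},
        chrom_sizes={track.chrom: len(scores) * track.resolution},
    )


def call_hierarchy(
    matrix: ContactMatrix,
    coarse_window: int = 100_000,
    fine_window: int = 50_000,
    min_prominence: tuple[float, float] = (2.5, 0.5),
    balanced: bool = False,
) -> CalledHierarchy:
    """Two-scale boundary calling on one chromosome's matrix.

    TAD boundaries come from the coarse-window insulation track; subTAD
    boundaries are fine-window minima not within one bin of a TAD
    boundary. The raw matrix is balanced first unless ``balanced``.
    """
    if coarse_window <= fine_window:
        raise ValueError("coarse_window must exceed fine_window")
    for w in (coarse_window, fine_window):
        if w % matrix.resolution != 0:
            raise ValueError("windows must be multiples of the resolution")
    m = matrix if balanced else balance(matrix)
    coarse = call_boundaries(insulation_track(m, coarse_window), min_prominence[0])
    fine = call_boundaries(insulation_track(m, fine_window), min_prominence[1])
    coarse.level = "TAD"
    tad_bins = coarse.df["bin"].to_numpy()
    sub = fine.df[
        ~fine.df["bin"].apply(lambda b: bool((np.abs(tad_bins - b) <= 1).any()) if tad_bins.size else False)
    ].reset_index(drop=True)
    subtad = BoundarySet("subTAD", matrix.resolution, sub, coarse.chrom_sizes)
    return CalledHierarchy(coarse, subtad)


def _match_positions(a: np.ndarray, b: np.ndarray, tol: int) -> list[tuple[int, int]]:
    """Optimal one-to-one matching of positions within ``tol``.

    Maximises the number of matched pairs, then minimises total distance
    (linear assignment with a large penalty for out-of-tolerance pairs);
    scipy's deterministic assignment resolves exact ties, which favours
    earlier (smaller-coordinate) entries of the sorted inputs.
    """
    if len(a) == 0 or len(b) == 0:
        return []
    d = np.abs(a[:, None].astype(np.int64) - b[None, :].astype(np.int64)).astype(float)
    big = float(tol) * (len(a) + len(b) + 1) + 1e9
    cost = np.where(d <= tol, d, big)
    ri, ci = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(ri, ci) if d[i, j] <= tol]


def classify_boundaries(
    control: BoundarySet, clone1: BoundarySet, clone2: BoundarySet, tol: int = 10_000
) -> BoundaryClassTable:
    """Classify boundaries across a control and two clones.

    Control boundary: constant if matched (within ``tol``) in both clones,
    lost if matched in neither, discordant if matched in exactly one.
    Clone boundaries unmatched in control: gained if mutually matched
    between the clones, otherwise discordant. Swapping the clones leaves
    the table unchanged up to partner-column order.
    """
    if not (control.level == clone1.level == clone2.level):
        raise ValueError("boundary sets must be the same level")
    if not (control.resolution == clone1.resolution == clone2.resolution):
        raise ValueError("boundary sets must share the resolution")
    if tol < control.resolution:
        warnings.warn("tolerance below the bin size; matching may be brittle")
    rows = []
    chroms = sorted(
        set(control.df["chrom"]) | set(clone1.df["chrom"]) | set(clone2.df["chrom"])
    )
    for chrom in chroms:
        pc = np.sort(control.positions(chrom))
        p1 = np.sort(clone1.positions(chrom))
        p2 = np.sort(clone2.positions(chrom))
        m1 = dict(_match_positions(pc, p1, tol))
        m2 = dict(_match_positions(pc, p2, tol))
        for i, pos in enumerate(pc.tolist()):
            in1, in2 = i in m1, i in m2
            cls = "constant" if (in1 and in2) else ("lost" if not (in1 or in2) else "discordant")
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "partner1": float(p1[m1[i]]) if in1 else np.nan,
                    "partner2": float(p2[m2[i]]) if in2 else np.nan,
                    "source": "control",
                    "class": cls,
                }
            )
        un1 = np.array([j for j in range(len(p1)) if j not in set(m1.values())], dtype=int)
        un2 = np.array([j for j in range(len(p2)) if j not in set(m2.values())], dtype=int)
        mg = _match_positions(p1[un1], p2[un2], tol) if un1.size and un2.size else []
        gained1 = set()
        gained2 = set()
        for a, b in mg:
            j1, j2 = int(un1[a]), int(un2[b])
            gained1.add(j1)
            gained2.add(j2)
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(round((p1[j1] + p2[j2]) / 2)),
                    "partner1": float(p1[j1]),
                    "partner2": float(p2[j2]),
                    "source": "clones",
                    "class": "gained",
                }
            )
        for j in un1.tolist():
            if j not in gained1:
                rows.append(
                    {"chrom": chrom, "pos": int(p1[j]), "partner1": float(p1[j]),
                     "partner2": np.nan, "source": "clone1", "class": "discordant"}
                )
        for j in un2.tolist():
            if j not in gained2:
                rows.append(
                    {"chrom": chrom, "pos": int(p2[j]), "partner1": np.nan,
                     "partner2": float(p2[j]), "source": "clone2", "class": "discordant"}
                )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "partner1", "partner2", "source", "class"])
    sizes = control.chrom_sizes or clone1.chrom_sizes
    return BoundaryClassTable(control.level, control.resolution, df, sizes)


def gained_lost_adjacency(
    table: BoundaryClassTable, n_random: int = 999, seed: int = 0
) -> dict[str, float]:
    """Test whether gained boundaries sit near lost ones.

    Statistic: median over gained boundaries of the distance to the
    nearest lost boundary on the same chromosome. Null: the gained set is
    re-placed uniformly on the chromosome's bins (per-chromosome counts
    preserved) ``n_random`` times. Returns the observed median, the ratio
    null-median / observed-median (> 1 means gained are closer to lost
    than chance), and the empirical p ``(1 + #null <= observed) /
    (n_random + 1)``.
    """
    if table.chrom_sizes is None:
        raise ValueError("table lacks chromosome sizes for the null model")
    gained = {c: table.positions("gained", c) for c in table.chrom_sizes}
    lost = {c: table.positions("lost", c) for c in table.chrom_sizes}
    if sum(v.size for v in gained.values()) == 0 or sum(v.size for v in lost.values()) == 0:
        raise ValueError("need at least one gained and one lost boundary")

    def stat(gained_by_chrom: dict[str, np.ndarray]) -> float:
        dists = []
        for c, g in gained_by_chrom.items():
            if g.size == 0 or lost[c].size == 0:
                continue
            dists.append(np.abs(g[:, None] - lost[c][None, :]).min(axis=1))
        return float(np.median(np.concatenate(dists)))

    observed = stat(gained)
    rng = np.random.default_rng(seed)
    res = table.resolution
    null = np.empty(n_random)
    for t in range(n_random):
        placed = {
            c: rng.integers(0, max(table.chrom_sizes[c] // res, 1), size=gained[c].size) * res
            for c in gained
        }
        null[t] = stat(placed)
    k = int((null <= observed).sum())
    return {
        "observed_median": observed,
        "null_median": float(np.median(null)),
        "ratio": float(np.median(null) / observed) if observed > 0 else np.inf,
        "p": (1 + k) / (n_random + 1),
        "n_random": n_random,
    }
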