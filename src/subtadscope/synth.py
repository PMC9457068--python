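"""Paired-condition synthetic genomes with known domain architecture.

The generator emulates the statistical structure of a CTCF copy-number-loss
experiment: a control genome with nested TAD/subTAD domains and
distance-decay Hi-C contacts; a perturbed genome in which a fraction of
boundaries (mostly subTAD-level) is removed and a smaller fraction gained
next to the removed ones; CTCF peaks anchoring boundaries, with weaker
occupancy at the sites destined to be lost; histone-mark sites gained at
new subTAD boundaries and coupled to expression changes; and an expression
table whose true log2 fold-changes rise next to gained subTAD boundaries.
A machine-readable ChangeRecord carries the ground truth for
parameter-recovery tests.

All randomness flows from a single integer seed through one
``numpy.random.Generator`` per operation, in documented draw order, so a
fixed seed reproduces every placement bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .contacts import ContactMatrix
from .io_model import FeatureSet, GenomicInterval

__all__ = [
    "GenomeSpec",
    "HierarchyParams",
    "ContactParams",
    "PerturbParams",
    "FeatureParams",
    "DomainHierarchy",
    "ChangeRecord",
    "SimulatedFeatures",
    "generate_domain_hierarchy",
    "simulate_contact_matrix",
    "perturb_hierarchy",
    "simulate_features",
    "simulate_experiment",
    "Experiment",
]


@dataclasses.dataclass(frozen=True)
class GenomeSpec:
    """Chromosome sizes (bp) and the bin size shared by all tracks."""

    chrom_sizes: dict[str, int]
    resolution: int = 10_000

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.resolution)


@dataclasses.dataclass(frozen=True)
class HierarchyParams:
    """Domain-geometry parameters (all sizes in bp).

    TADs are drawn uniformly in ``tad_size_range`` (the 100 kb - 1 Mb scale
    of mammalian TADs); each TAD holds ``subtads_per_tad`` interior cuts
    when it is large enough. Insulation factors are the fraction of
    cross-boundary contacts retained: TAD boundaries insulate harder
    (smaller f) than subTAD boundaries.
    """

    tad_size_range: tuple[int, int] = (100_000, 1_000_000)
    subtads_per_tad: tuple[int, int] = (1, 3)
    min_subtad_size: int = 50_000
    tad_factor_range: tuple[float, float] = (0.08, 0.25)
    subtad_factor_range: tuple[float, float] = (0.40, 0.65)


@dataclasses.dataclass(frozen=True)
class ContactParams:
    """Contact-intensity model: lambda(i,j) = depth * (1+d)^-alpha * e * f.

    ``depth`` sets the Poisson mean at distance zero (defaults give bin row
    sums of order 10^3, the coverage of a deeply sequenced Hi-C library at
    10-kb bins); ``alpha`` is the distance-decay exponent; ``e_tad`` and
    ``e_subtad`` multiply pairs sharing a TAD / subTAD; f is the product of
    insulation factors of boundaries separating the pair.
    """

    depth: float = 100.0
    alpha: float = 1.0
    e_tad: float = 1.7
    e_subtad: float = 2.5
    lognormal_sigma: float = 0.0  # per-bin multiplicative overdispersion, off by default


@dataclasses.dataclass(frozen=True)
class PerturbParams:
    """Fractions of boundaries removed/added per level.

    Defaults mirror the observed reorganisation scale in the study system:
    17% of subTAD boundaries lost / 11% gained, 10% of TAD boundaries lost
    / 7% gained; gained boundaries are placed near lost ones
    (``near_window`` bp, probability ``near_prob``).
    """

    subtad_removed: float = 0.17
    subtad_added: float = 0.11
    tad_removed: float = 0.10
    tad_added: float = 0.07
    near_window: int = 100_000
    near_prob: float = 0.7


@dataclasses.dataclass(frozen=True)
class FeatureParams:
    """Peak/mark/expression generation parameters.

    ``ctcf_coupling``: probability that a removed boundary's anchoring CTCF
    peak is truth-lost. ``mark_coupling``: probability a gained subTAD
    boundary receives a gained H3K27ac site. ``mark_expr_rho``: latent
    correlation between mark log-fold-changes and expression log2FC at
    coupled promoter sites. ``boundary_expr_effect``: true log2FC offset
    given to genes whose TSS lies within ``boundary_tol`` of a gained
    subTAD boundary. Replicate densities carry lognormal noise
    (``rep_sigma_log2`` in log2 units); differential effects are
    ``lost_effect_log2`` / ``gained_effect_log2``.
    """

    peak_halfwidth: int = 200
    background_peak_per_mb: float = 10.0
    ctcf_coupling: float = 0.9
    background_lost_frac: float = 0.02
    background_gained_frac: float = 0.015
    lost_occupancy_ratio: float = 0.5
    base_occupancy: float = 10.0
    occupancy_sigma: float = 0.5
    rep_sigma_log2: float = 0.35
    lost_effect_log2: float = 2.0
    gained_effect_log2: float = 2.0
    # marks
    background_mark_per_mb: float = 12.0
    mark_coupling: float = 0.9
    n_coupled_promoter_marks: int = 300
    mark_expr_rho: float = 0.6
    mark_lfc_sigma: float = 1.5
    # expression
    gene_per_mb: float = 40.0
    basemean_log_mean: float = 6.0
    basemean_log_sigma: float = 0.8
    nb_dispersion: float = 0.05
    boundary_expr_effect: float = 1.0
    expr_coupling: float = 1.0
    boundary_tol: int = 10_000


@dataclasses.dataclass
class DomainHierarchy:
    """Two-level boundary model over a genome.

    Boundaries are interior cut positions in bin units: a boundary at bin k
    separates bins < k from bins >= k. ``*_factors`` align with the sorted
    boundary arrays and give the fraction of cross-boundary contacts
    retained (f in (0, 1]).
    """

    genome: GenomeSpec
    tad_boundaries: dict[str, np.ndarray]
    subtad_boundaries: dict[str, np.ndarray]
    tad_factors: dict[str, np.ndarray]
    subtad_factors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom in self.genome.chrom_sizes:
            tb = self.tad_boundaries[chrom]
            sb = self.subtad_boundaries[chrom]
            if np.intersect1d(tb, sb).size:
                raise ValueError("a boundary may belong to exactly one level")
            for arr, fac in ((tb, self.tad_factors[chrom]), (sb, self.subtad_factors[chrom])):
                if len(arr) != len(fac):
                    raise ValueError("factors must align with boundaries")
                if len(np.unique(arr)) != len(arr):
                    raise ValueError("duplicate boundary positions")
                if ((fac <= 0) | (fac > 1)).any():
                    raise ValueError("insulation factors must lie in (0, 1]")

    def tads(self, chrom: str) -> list[tuple[int, int]]:
        """TAD intervals in bins, tiling the chromosome."""
        n = self.genome.n_bins(chrom)
        cuts = [0, *sorted(self.tad_boundaries[chrom].tolist()), n]
        return [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]

    def subtads(self, chrom: str) -> list[tuple[int, int]]:
        """subTAD intervals in bins; they tile within their parent TADs."""
        out = []
        sub = np.sort(self.subtad_boundaries[chrom])
        for s, e in self.tads(chrom):
            inner = sub[(sub > s) & (sub < e)]
            cuts = [s, *inner.tolist(), e]
            out.extend((cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1))
        return out

    def boundaries_bp(self, chrom: str, level: str) -> np.ndarray:
        arr = (self.tad_boundaries if level == "TAD" else self.subtad_boundaries)[chrom]
        return arr * self.genome.resolution

    def copy(self) -> "DomainHierarchy":
        return DomainHierarchy(
            self.genome,
            {c: v.copy() for c, v in self.tad_boundaries.items()},
            {c: v.copy() for c, v in self.subtad_boundaries.items()},
            {c: v.copy() for c, v in self.tad_factors.items()},
            {c: v.copy() for c, v in self.subtad_factors.items()},
        )


@dataclasses.dataclass
class ChangeRecord:
    """Ground truth of a perturbation, in bin units per chromosome."""

    removed_tad: dict[str, np.ndarray]
    added_tad: dict[str, np.ndarray]
    removed_subtad: dict[str, np.ndarray]
    added_subtad: dict[str, np.ndarray]

    def removed(self, level: str) -> dict[str, np.ndarray]:
        return self.removed_tad if level == "TAD" else self.removed_subtad

    def added(self, level: str) -> dict[str, np.ndarray]:
        return self.added_tad if level == "TAD" else self.added_subtad

    def n_removed(self, level: str) -> int:
        return sum(len(v) for v in self.removed(level).values())

    def n_added(self, level: str) -> int:
        return sum(len(v) for v in self.added(level).values())


DEFAULT_GENOME = GenomeSpec({"synth1": 20_000_000, "synth2": 20_000_000}, 10_000)


def generate_domain_hierarchy(
    genome: GenomeSpec = DEFAULT_GENOME,
    params: HierarchyParams = HierarchyParams(),
    seed: int = 0,
) -> DomainHierarchy:
    """Draw a nested TAD/subTAD hierarchy for every chromosome.

    Deterministic under a fixed seed. TAD sizes are drawn uniformly within
    ``tad_size_range`` and laid end to end; each sufficiently large TAD is
    cut into subTADs at uniformly drawn interior positions respecting
    ``min_subtad_size``.
    """
    res = genome.resolution
    lo, hi = params.tad_size_range
    if lo >= hi or lo < 2 * res:
        raise ValueError("infeasible TAD size range")
    for chrom, size in genome.chrom_sizes.items():
        if size < 2 * hi:
            raise ValueError(
                f"chromosome {chrom} shorter than 2x max TAD size"
            )
    rng = np.random.default_rng(seed)
    tad_b: dict[str, np.ndarray] = {}
    sub_b: dict[str, np.ndarray] = {}
    tad_f: dict[str, np.ndarray] = {}
    sub_f: dict[str, np.ndarray] = {}
    min_sub_bins = max(2, params.min_subtad_size // res)
    for chrom in genome.chrom_sizes:
        n = genome.n_bins(chrom)
        cuts: list[int] = []
        pos = 0
        while True:
            size_bins = int(rng.integers(lo // res, hi // res + 1))
            pos += size_bins
            if pos >= n - lo // res:
                break
            cuts.append(pos)
        tads = np.array(cuts, dtype=np.int64)
        subs: list[int] = []
        edges = [0, *cuts, n]
        for s, e in zip(edges[:-1], edges[1:]):
            k = int(rng.integers(params.subtads_per_tad[0], params.subtads_per_tad[1] + 1))
            # feasible interior cuts keeping every piece >= min_subtad_size
            placed: list[int] = []
            for _ in range(k):
                candidates = [
                    b
                    for b in range(s + min_sub_bins, e - min_sub_bins + 1)
                    if all(abs(b - p) >= min_sub_bins for p in placed)
                ]
                if not candidates:
                    break
                placed.append(int(rng.choice(candidates)))
            subs.extend(sorted(placed))
        subs_arr = np.array(sorted(subs), dtype=np.int64)
        tad_b[chrom] = tads
        sub_b[chrom] = subs_arr
        tad_f[chrom] = rng.uniform(*params.tad_factor_range, size=len(tads))
        sub_f[chrom] = rng.uniform(*params.subtad_factor_range, size=len(subs_arr))
    return DomainHierarchy(genome, tad_b, sub_b, tad_f, sub_f)


def _domain_ids(n: int, cuts: np.ndarray) -> np.ndarray:
    """Label each bin with the index of its enclosing domain."""
    return np.searchsorted(np.sort(cuts), np.arange(n), side="right")


def simulate_contact_matrix(
    hierarchy: DomainHierarchy,
    chrom: str,
    params: ContactParams = ContactParams(),
    seed: int = 0,
    loops: Sequence[tuple[int, int, float]] = (),
) -> ContactMatrix:
    """Sample a symmetric Poisson contact matrix for one chromosome.

    The Poisson mean for bins i < j is
    ``depth * (1+j-i)^-alpha * e(i,j) * f(i,j)`` where e multiplies
    ``e_tad`` (``e_subtad``) when both bins share a TAD (subTAD) and f is
    the product of insulation factors of all boundaries between i and j.
    Optional ``loops`` are (bin_a, bin_b, strength) focal multiplicative
    enrichments. depth = 0 yields the all-zero matrix.
    """
    if params.depth < 0:
        raise ValueError("depth must be nonnegative")
    if params.alpha <= 0:
        raise ValueError("alpha must be positive")
    if params.e_tad < 1 or params.e_subtad < 1:
        raise ValueError("domain enrichments must be >= 1")
    rng = np.random.default_rng(seed)
    n = hierarchy.genome.n_bins(chrom)
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    lam = params.depth * (1.0 + d) ** (-params.alpha)

    tad_id = _domain_ids(n, hierarchy.tad_boundaries[chrom])
    same_tad = tad_id[:, None] == tad_id[None, :]
    lam *= np.where(same_tad, params.e_tad, 1.0)

    sub_cuts = np.sort(
        np.concatenate([hierarchy.tad_boundaries[chrom], hierarchy.subtad_boundaries[chrom]])
    )
    sub_id = _domain_ids(n, sub_cuts)
    lam *= np.where(sub_id[:, None] == sub_id[None, :], params.e_subtad, 1.0)

    # prefix sums of log insulation factors: boundary k affects pairs i < k <= j
    logf = np.zeros(n)
    for cuts, facs in (
        (hierarchy.tad_boundaries[chrom], hierarchy.tad_factors[chrom]),
        (hierarchy.subtad_boundaries[chrom], hierarchy.subtad_factors[chrom]),
    ):
        for k, f in zip(cuts.tolist(), facs.tolist()):
            logf[k:] += np.log(f)
    lam *= np.exp(-np.abs(logf[:, None] - logf[None, :]))

    if params.lognormal_sigma > 0:
        bias = rng.lognormal(0.0, params.lognormal_sigma, size=n)
        lam *= np.outer(bias, bias)

    for a, b, strength in loops:
        if strength <= 0:
            raise ValueError("loop strength must be positive")
        lam[max(a - 1, 0) : a + 2, max(b - 1, 0) : b + 2] *= strength
        lam[max(b - 1, 0) : b + 2, max(a - 1, 0) : a + 2] *= strength

    upper = np.triu(rng.poisson(lam)).astype(float)
    counts = upper + np.triu(upper, 1).T
    return ContactMatrix(chrom=chrom, resolution=hierarchy.genome.resolution, counts=counts)


def perturb_hierarchy(
    hierarchy: DomainHierarchy,
    params: PerturbParams = PerturbParams(),
    seed: int = 0,
) -> tuple[DomainHierarchy, ChangeRecord]:
    """Remove and add boundaries per level, recording ground truth.

    Removal counts are ``round(fraction x level count)`` genome-wide,
    sampled uniformly. Added boundaries are placed, with probability
    ``near_prob``, uniformly within ``near_window`` of a removed boundary
    of the same level (otherwise uniformly on the chromosome), at bins not
    already occupied and keeping domains at least 2 bins wide. Removing a
    TAD boundary merges its two TADs.
    """
    for frac in (params.subtad_removed, params.subtad_added, params.tad_removed, params.tad_added):
        if not 0 <= frac <= 1:
            raise ValueError("perturbation fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    new = hierarchy.copy()
    genome = hierarchy.genome
    chroms = list(genome.chrom_sizes)
    record = ChangeRecord(*({c: np.array([], dtype=np.int64) for c in chroms} for _ in range(4)))

    for level, frac_rm, frac_add in (
        ("TAD", params.tad_removed, params.tad_added),
        ("subTAD", params.subtad_removed, params.subtad_added),
    ):
        bmap = new.tad_boundaries if level == "TAD" else new.subtad_boundaries
        fmap = new.tad_factors if level == "TAD" else new.subtad_factors
        all_pos = [(c, k) for c in chroms for k in bmap[c].tolist()]
        n_level = len(all_pos)
        n_rm = int(round(frac_rm * n_level))
        n_add = int(round(frac_add * n_level))
        if n_rm > 0:
            if n_rm == n_level and n_add > 0 and level == "TAD":
                raise ValueError("cannot add boundaries after removing every parent domain")
            chosen = rng.choice(n_level, size=n_rm, replace=False)
            removed = sorted(all_pos[i] for i in chosen)
        else:
            removed = []
        rm_by_chrom = {c: np.array(sorted(k for cc, k in removed if cc == c), dtype=np.int64) for c in chroms}
        for c in chroms:
            keep = ~np.isin(bmap[c], rm_by_chrom[c])
            bmap[c] = bmap[c][keep]
            fmap[c] = fmap[c][keep]
        # additions, preferentially near removals of the same level
        win = params.near_window // genome.resolution
        frange = (
            HierarchyParams().tad_factor_range if level == "TAD" else HierarchyParams().subtad_factor_range
        )
        added: list[tuple[int, int]] = []  # (chrom index, bin)
        attempts = 0
        while len(added) < n_add and attempts < 200 * max(n_add, 1):
            attempts += 1
            near = removed and rng.random() < params.near_prob
            if near:
                c, k = removed[int(rng.integers(len(removed)))]
                b = int(k + rng.integers(-win, win + 1))
            else:
                c = chroms[int(rng.integers(len(chroms)))]
                b = int(rng.integers(2, genome.n_bins(c) - 2))
            nb = genome.n_bins(c)
            if not (2 <= b <= nb - 2):
                continue
            occupied = np.concatenate(
                [new.tad_boundaries[c], new.subtad_boundaries[c], np.array([x for cc, x in added if cc == c], dtype=np.int64)]
            )
            if occupied.size and np.abs(occupied - b).min() < 2:
                continue
            if np.isin(b, rm_by_chrom[c]):
                continue  # added must be disjoint from original (removed were original)
            added.append((c, b))
        if len(added) < n_add:
            raise ValueError(f"could not place {n_add} added {level} boundaries")
        add_by_chrom = {c: np.array(sorted(b for cc, b in added if cc == c), dtype=np.int64) for c in chroms}
        for c in chroms:
            if add_by_chrom[c].size:
                merged = np.concatenate([bmap[c], add_by_chrom[c]])
                facs = np.concatenate([fmap[c], rng.uniform(*frange, size=add_by_chrom[c].size)])
                order = np.argsort(merged)
                bmap[c], fmap[c] = merged[order], facs[order]
            else:
                order = np.argsort(bmap[c])
                bmap[c], fmap[c] = bmap[c][order], fmap[c][order]
        if level == "TAD":
            record.removed_tad, record.added_tad = rm_by_chrom, add_by_chrom
        else:
            record.removed_subtad, record.added_subtad = rm_by_chrom, add_by_chrom

    # drop subTAD boundaries that now collide with added TAD boundaries
    for c in chroms:
        bad = np.isin(new.subtad_boundaries[c], new.tad_boundaries[c])
        if bad.any():
            new.subtad_boundaries[c] = new.subtad_boundaries[c][~bad]
            new.subtad_factors[c] = new.subtad_factors[c][~bad]
    return new, record


@dataclasses.dataclass
class SimulatedFeatures:
    """Feature-level output of :func:`simulate_features`.

    Peak/mark tables carry one row per union site with replicate densities
    (ctl_1, ctl_2, trt_1, trt_2) and a ``truth_class`` column; expression
    tables are per-condition-pair with observed summary statistics plus the
    implanted ``true_log2fc``.
    """

    ctcf_peaks: FeatureSet
    ctcf_table: pd.DataFrame
    mark_sites: FeatureSet
    mark_table: pd.DataFrame
    expression: pd.DataFrame


def _replicate_densities(
    rng: np.random.Generator, base: np.ndarray, lfc: np.ndarray, sigma: float, n_rep: int = 2
) -> dict[str, np.ndarray]:
    cols = {}
    for r in range(n_rep):
        cols[f"ctl_{r + 1}"] = base * rng.lognormal(0.0, sigma * np.log(2), size=base.size)
    treat_base = base * 2.0 ** lfc
    for r in range(n_rep):
        cols[f"trt_{r + 1}"] = treat_base * rng.lognormal(0.0, sigma * np.log(2), size=base.size)
    return cols


def simulate_features(
    hierarchy: DomainHierarchy,
    record: ChangeRecord,
    params: FeatureParams = FeatureParams(),
    seed: int = 0,
) -> SimulatedFeatures:
    """Generate CTCF peaks, histone-mark sites and expression tables.

    ``hierarchy`` must be the CONTROL (pre-perturbation) hierarchy; the
    perturbation ground truth comes from ``record``. Draw order: CTCF
    placement and occupancy, mark placement, gene placement, expression
    counts.
    """
    if not 0 <= params.ctcf_coupling <= 1 or not 0 <= params.mark_coupling <= 1:
        raise ValueError("coupling strengths must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genome = hierarchy.genome
    res = genome.resolution
    chroms = list(genome.chrom_sizes)
    hw = params.peak_halfwidth
    if hw * 2 >= res:
        raise ValueError("peaks wider than the bin resolution would overlap")

    # --- CTCF peaks: one per control boundary (both levels) + background
    rows: list[dict] = []
    for c in chroms:
        for level in ("TAD", "subTAD"):
            cuts = (hierarchy.tad_boundaries if level == "TAD" else hierarchy.subtad_boundaries)[c]
            removed = set(record.removed(level)[c].tolist())
            for k in cuts.tolist():
                is_removed = k in removed
                if is_removed and rng.random() < params.ctcf_coupling:
                    truth = "lost"
                elif rng.random() < params.background_lost_frac:
                    truth = "lost"  # baseline loss rate applies everywhere
                else:
                    truth = "constant"
                rows.append(
                    dict(chrom=c, pos=k * res, at_level=level, at_removed=is_removed, truth_class=truth)
                )
        n_bg = int(round(params.background_peak_per_mb * genome.chrom_sizes[c] / 1e6))
        bg_pos = rng.integers(hw, genome.chrom_sizes[c] - hw, size=n_bg)
        for p in sorted(bg_pos.tolist()):
            u = rng.random()
            if u < params.background_lost_frac:
                truth = "lost"
            elif u < params.background_lost_frac + params.background_gained_frac:
                truth = "gained"
            else:
                truth = "constant"
            rows.append(dict(chrom=c, pos=int(p), at_level="none", at_removed=False, truth_class=truth))
    ctcf = pd.DataFrame(rows)
    base = params.base_occupancy * rng.lognormal(0.0, params.occupancy_sigma, size=len(ctcf))
    lost = (ctcf["truth_class"] == "lost").to_numpy()
    gained = (ctcf["truth_class"] == "gained").to_numpy()
    base[lost] *= params.lost_occupancy_ratio  # weaker occupancy at to-be-lost sites
    lfc = np.zeros(len(ctcf))
    lfc[lost] = -params.lost_effect_log2
    lfc[gained] = params.gained_effect_log2
    for col, vals in _replicate_densities(rng, base, lfc, params.rep_sigma_log2).items():
        ctcf[col] = vals
    ctcf_fs = FeatureSet(
        GenomicInterval(r.chrom, max(r.pos - hw, 0), r.pos + hw) for r in ctcf.itertuples()
    )
    ctcf = ctcf.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    # --- genes (placed before marks so promoter marks can reference them)
    grows: list[dict] = []
    gid = 0
    for c in chroms:
        n_genes = int(round(params.gene_per_mb * genome.chrom_sizes[c] / 1e6))
        tss = np.sort(rng.integers(0, genome.chrom_sizes[c], size=n_genes))
        strands = rng.choice(["+", "-"], size=n_genes)
        for t, s in zip(tss.tolist(), strands.tolist()):
            grows.append(dict(gene_id=f"g{gid:05d}", chrom=c, tss=int(t), strand=s))
            gid += 1
    genes = pd.DataFrame(grows)
    true_lfc = np.zeros(len(genes))
    # boundary-coupled up-regulation at gained subTAD boundaries
    for c in chroms:
        gained_bp = record.added_subtad[c] * res
        if gained_bp.size == 0:
            continue
        on_c = (genes["chrom"] == c).to_numpy()
        tss = genes.loc[on_c, "tss"].to_numpy()
        near = (np.abs(tss[:, None] - gained_bp[None, :]) <= params.boundary_tol).any(axis=1)
        hit = near & (rng.random(near.size) < params.expr_coupling)
        idx = np.flatnonzero(on_c)[hit]
        true_lfc[idx] += params.boundary_expr_effect

    # --- promoter mark sites with latent mark-expression coupling
    n_coupled = min(params.n_coupled_promoter_marks, len(genes))
    coupled_idx = rng.choice(len(genes), size=n_coupled, replace=False)
    latent = rng.normal(0.0, params.mark_lfc_sigma, size=n_coupled)
    true_lfc[coupled_idx] += latent
    rho = params.mark_expr_rho
    mark_lfc_coupled = rho * latent + np.sqrt(1 - rho**2) * rng.normal(
        0.0, params.mark_lfc_sigma, size=n_coupled
    )

    mrows: list[dict] = []
    mark_lfc: list[float] = []
    for i, lf in zip(coupled_idx.tolist(), mark_lfc_coupled.tolist()):
        g = genes.iloc[i]
        mrows.append(dict(chrom=g.chrom, pos=int(g.tss), origin="promoter"))
        mark_lfc.append(lf)
    for c in chroms:
        for k in record.added_subtad[c].tolist():
            if rng.random() < params.mark_coupling:
                mrows.append(dict(chrom=c, pos=k * res, origin="gained_boundary"))
                mark_lfc.append(params.gained_effect_log2)
        n_bg = int(round(params.background_mark_per_mb * genome.chrom_sizes[c] / 1e6))
        for p in rng.integers(hw, genome.chrom_sizes[c] - hw, size=n_bg).tolist():
            mrows.append(dict(chrom=c, pos=int(p), origin="background"))
            mark_lfc.append(0.0)
    marks = pd.DataFrame(mrows)
    marks["true_lfc"] = np.array(mark_lfc)
    marks["truth_class"] = np.where(
        marks["true_lfc"] >= 1, "gained", np.where(marks["true_lfc"] <= -1, "lost", "constant")
    )
    mbase = params.base_occupancy * rng.lognormal(0.0, params.occupancy_sigma, size=len(marks))
    for col, vals in _replicate_densities(
        rng, mbase, marks["true_lfc"].to_numpy(), params.rep_sigma_log2
    ).items():
        marks[col] = vals
    marks_fs = FeatureSet(
        GenomicInterval(r.chrom, max(r.pos - hw, 0), r.pos + hw) for r in marks.itertuples()
    )
    marks = marks.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    # --- expression counts: 2 vs 2 negative binomial replicates
    genes["true_log2fc"] = true_lfc
    basemean = np.exp(
        rng.normal(params.basemean_log_mean, params.basemean_log_sigma, size=len(genes))
    )
    phi = params.nb_dispersion
    mu_ctl = basemean
    mu_trt = basemean * 2.0 ** true_lfc

    def _nb(mu: np.ndarray) -> np.ndarray:
        return rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))

    counts = np.column_stack([_nb(mu_ctl), _nb(mu_ctl), _nb(mu_trt), _nb(mu_trt)]).astype(float)
    from .diffbind import pooled_z_pvalues  # local import to avoid a cycle

    log_ctl = np.log2(counts[:, :2] + 1)
    log_trt = np.log2(counts[:, 2:] + 1)
    pvals = pooled_z_pvalues(log_trt, log_ctl)
    from statsmodels.stats.multitest import multipletests

    genes["basemean"] = counts.mean(axis=1)
    genes["log2fc"] = np.log2((counts[:, 2:].mean(axis=1) + 1) / (counts[:, :2].mean(axis=1) + 1))
    genes["padj"] = multipletests(pvals, method="fdr_bh")[1]
    return SimulatedFeatures(ctcf_fs, ctcf, marks_fs, marks, genes)


@dataclasses.dataclass
class Experiment:
    """A full paired-condition synthetic experiment."""

    genome: GenomeSpec
    control: DomainHierarchy
    perturbed: DomainHierarchy
    record: ChangeRecord
    control_matrices: dict[str, ContactMatrix]
    clone1_matrices: dict[str, ContactMatrix]
    clone2_matrices: dict[str, ContactMatrix]
    features: SimulatedFeatures


def simulate_experiment(
    genome: GenomeSpec = DEFAULT_GENOME,
    hierarchy_params: HierarchyParams = HierarchyParams(),
    contact_params: ContactParams = ContactParams(),
    perturb_params: PerturbParams = PerturbParams(),
    feature_params: FeatureParams = FeatureParams(),
    seed: int = 0,
) -> Experiment:
    """Simulate control + two perturbed clones sharing one perturbation.

    The two clones share the perturbed hierarchy (clonal architecture) but
    get independent Poisson contact noise, mirroring a control line and two
    derived clones profiled separately. Sub-seeds are derived from ``seed``
    via fixed offsets.
    """
    control = generate_domain_hierarchy(genome, hierarchy_params, seed=seed)
    perturbed, record = perturb_hierarchy(control, perturb_params, seed=seed + 1)
    ctl_m, c1_m, c2_m = {}, {}, {}
    for k, chrom in enumerate(genome.chrom_sizes):
        ctl_m[chrom] = simulate_contact_matrix(control, chrom, contact_params, seed=seed + 10 + 3 * k)
        c1_m[chrom] = simulate_contact_matrix(perturbed, chrom, contact_params, seed=seed + 11 + 3 * k)
        c2_m[chrom] = simulate_contact_matrix(perturbed, chrom, contact_params, seed=seed + 12 + 3 * k)
    features = simulate_features(control, record, feature_params, seed=seed + 2)
    return Experiment(genome, control, perturbed, record, ctl_m, c1_m, c2_m, features)
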