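"""Colocalization enrichment and multi-omic coupling statistics.

Observed/expected (O/E) enrichment of features at boundaries with a
uniform-permutation null, gene-set enrichment of a query peak set against
equinumerous constant-site subsets, boundary-class expression association,
delta-delta (feature change vs expression change) correlation, and per-gene
correlation ranking against a reference gene. All empirical p-values use
the (1 + k) / (n + 1) convention and are never zero.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .domains import BoundaryClassTable, BoundarySet
from .io_model import FeatureSet

__all__ = [
    "EnrichmentResult",
    "oe_boundary_enrichment",
    "geneset_enrichment_vs_constant",
    "boundary_expression_association",
    "delta_delta_correlation",
    "correlation_ranking",
]


@dataclasses.dataclass
class EnrichmentResult:
    """O/E enrichment against a permutation null.

    ``p`` is the two-sided empirical p (smaller tail doubled, capped at 1);
    ``p_enrichment`` / ``p_depletion`` are the one-sided versions. All use
    the (1 + k) / (n + 1) convention, so none can be zero.
    """

    observed: float
    expected: float
    oe_ratio: float
    p: float
    n_null: int
    p_enrichment: float = 1.0
    p_depletion: float = 1.0


def _count_within(points: np.ndarray, targets: np.ndarray, tol: int) -> int:
    """Number of points within +-tol of any target (both sorted or not)."""
    if points.size == 0 or targets.size == 0:
        return 0
    t = np.sort(targets)
    idx = np.searchsorted(t, points)
    left = np.abs(points - t[np.clip(idx - 1, 0, len(t) - 1)])
    right = np.abs(points - t[np.clip(idx, 0, len(t) - 1)])
    return int((np.minimum(left, right) <= tol).sum())


def oe_boundary_enrichment(
    features: FeatureSet,
    boundaries: BoundarySet | BoundaryClassTable,
    tol: int = 10_000,
    n_perm: int = 999,
    seed: int = 0,
    boundary_class: str | None = None,
) -> EnrichmentResult:
    """O/E enrichment of features at boundaries with a permutation null.

    Observed = number of feature midpoints within ``tol`` of any boundary.
    Null = the features re-placed uniformly on each chromosome's bins,
    ``n_perm`` times. O/E = observed / mean(null); two-sided empirical p by
    doubling the smaller tail (capped at 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if len(features) == 0:
        raise ValueError("empty feature set")
    if isinstance(boundaries, BoundaryClassTable):
        sizes = boundaries.chrom_sizes
        res = boundaries.resolution
        pos = {
            c: boundaries.positions(boundary_class, c)
            if boundary_class
            else boundaries.df.loc[boundaries.df["chrom"] == c, "pos"].to_numpy(np.int64)
            for c in (sizes or {})
        }
    else:
        sizes = boundaries.chrom_sizes
        res = boundaries.resolution
        pos = {c: boundaries.positions(c) for c in (sizes or {})}
    if sizes is None:
        raise ValueError("boundaries lack chromosome sizes for the null model")
    if sum(v.size for v in pos.values()) == 0:
        raise ValueError("empty boundary set")
    feat = {c: features.midpoints(c) for c in sizes}

    def count(feature_pos: dict[str, np.ndarray]) -> int:
        return sum(_count_within(feature_pos[c], pos[c], tol) for c in sizes)

    observed = count(feat)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for t in range(n_perm):
        placed = {
            c: rng.integers(0, max(sizes[c] // res, 1), size=feat[c].size) * res
            for c in sizes
        }
        null[t] = count(placed)
    expected = float(null.mean())
    hi = (1 + int((null >= observed).sum())) / (n_perm + 1)
    lo = (1 + int((null <= observed).sum())) / (n_perm + 1)
    return EnrichmentResult(
        observed=float(observed),
        expected=expected,
        oe_ratio=observed / expected if expected > 0 else math.inf,
        p=min(1.0, 2.0 * min(hi, lo)),
        n_null=n_perm,
        p_enrichment=hi,
        p_depletion=lo,
    )


def _genes_near(sites: FeatureSet, genes: pd.DataFrame, tol: int) -> set[str]:
    hits: set[str] = set()
    by_chrom = {c: g for c, g in genes.groupby("chrom")}
    for chrom in sites.chroms():
        g = by_chrom.get(chrom)
        if g is None:
            continue
        tss = g["tss"].to_numpy()
        ids = g["gene_id"].to_numpy()
        mids = sites.midpoints(chrom)
        near = (np.abs(tss[:, None] - mids[None, :]) <= tol).any(axis=1)
        hits.update(ids[near].tolist())
    return hits


def geneset_enrichment_vs_constant(
    query: FeatureSet,
    constant_pool: FeatureSet,
    genes: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    n_subsets: int = 100,
    tol: int = 3_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-set enrichment of a query peak set vs equinumerous constant subsets.

    Sites map to genes whose TSS lies within ``tol``. For each gene set the
    query's gene-hit count is compared to the counts from ``n_subsets``
    random constant-site subsets of the query's size: ratio to the subset
    mean, SEM across subsets, and empirical p. Sub-seeding makes the
    permutation stream independent across gene sets.
    """
    if len(constant_pool) < len(query):
        raise ValueError("constant pool smaller than the query set")
    query_genes = _genes_near(query, genes, tol)
    pool_idx = np.arange(len(constant_pool))
    rows = []
    for si, (name, members) in enumerate(sorted(gene_sets.items())):
        member_set = set(members)
        mappable = member_set & set(genes["gene_id"])
        if not mappable:
            warnings.warn(f"gene set {name!r} has no mappable genes; skipped")
            continue
        obs = len(query_genes & member_set)
        rng = np.random.default_rng((seed, si))
        counts = np.empty(n_subsets)
        for t in range(n_subsets):
            take = rng.choice(pool_idx, size=len(query), replace=False)
            mask = np.zeros(len(constant_pool), dtype=bool)
            mask[take] = True
            sub_genes = _genes_near(constant_pool.subset(mask), genes, tol)
            counts[t] = len(sub_genes & member_set)
        mean = counts.mean()
        sem = counts.std(ddof=1) / math.sqrt(n_subsets)
        hi = int((counts >= obs).sum())
        lo = int((counts <= obs).sum())
        p = min(1.0, 2.0 * min(1 + hi, 1 + lo) / (n_subsets + 1))
        rows.append(
            dict(
                gene_set=name,
                observed=obs,
                subset_mean=mean,
                subset_sem=sem,
                ratio=obs / mean if mean > 0 else (math.inf if obs > 0 else math.nan),
                p=p,
                n_subsets=n_subsets,
            )
        )
    return pd.DataFrame(rows)


def boundary_expression_association(
    table: BoundaryClassTable, expr: pd.DataFrame, tol: int = 10_000
) -> pd.DataFrame:
    """Mean expression log2FC of genes colocalizing with each boundary class.

    A gene belongs to a class when its TSS lies within ``tol`` of a
    boundary of that class (genes may belong to several classes). Reports
    per class: n genes, mean log2FC, SEM, and a two-sided rank-sum p
    against all genes.
    """
    all_lfc = expr["log2fc"].to_numpy(dtype=float)
    rows = []
    for cls in ("constant", "lost", "gained", "discordant"):
        sel = np.zeros(len(expr), dtype=bool)
        for chrom, g in expr.groupby("chrom"):
            pos = table.positions(cls, chrom)
            if pos.size == 0:
                continue
            tss = g["tss"].to_numpy()
            near = (np.abs(tss[:, None] - pos[None, :]) <= tol).any(axis=1)
            sel[g.index[near]] = True
        lfc = all_lfc[sel]
        if lfc.size == 0:
            rows.append(dict(class_=cls, n_genes=0, mean_log2fc=np.nan, sem=np.nan, p=np.nan))
            continue
        if np.ptp(np.concatenate([lfc, all_lfc])) == 0:
            p = 1.0  # rank-sum undefined when every value ties
        else:
            p = stats.mannwhitneyu(lfc, all_lfc, alternative="two-sided").pvalue
        rows.append(
            dict(
                class_=cls,
                n_genes=int(lfc.size),
                mean_log2fc=float(lfc.mean()),
                sem=float(lfc.std(ddof=1) / math.sqrt(lfc.size)) if lfc.size > 1 else np.nan,
                p=float(p),
            )
        )
    return pd.DataFrame(rows)


def delta_delta_correlation(
    features: pd.DataFrame,
    expr: pd.DataFrame,
    tol: int = 3_000,
    method: str = "spearman",
) -> tuple[float, float, int]:
    """Correlate feature logFC with expression log2FC for colocalized pairs.

    ``features`` needs columns chrom, pos (site midpoint) and logfc. Each
    gene pairs with its nearest feature within ``tol`` of the TSS (one
    feature per gene, so a gene flanked by several altered sites is not
    double-counted). Returns (r, p, n_pairs).
    """
    if method not in {"spearman", "pearson"}:
        raise ValueError(f"unknown method {method!r}")
    xs, ys = [], []
    for chrom, g in expr.groupby("chrom"):
        f = features[features["chrom"] == chrom]
        if len(f) == 0:
            continue
        fpos = f["pos"].to_numpy()
        flfc = f["logfc"].to_numpy()
        order = np.argsort(fpos)
        fpos, flfc = fpos[order], flfc[order]
        tss = g["tss"].to_numpy()
        idx = np.searchsorted(fpos, tss)
        best = np.full(len(tss), -1)
        bestd = np.full(len(tss), np.inf)
        for cand in (np.clip(idx - 1, 0, len(fpos) - 1), np.clip(idx, 0, len(fpos) - 1)):
            d = np.abs(tss - fpos[cand])
            better = d < bestd
            best[better] = cand[better]
            bestd[better] = d[better]
        ok = bestd <= tol
        xs.extend(flfc[best[ok]].tolist())
        ys.extend(g["log2fc"].to_numpy()[ok].tolist())
    if len(xs) < 3:
        raise ValueError("fewer than 3 colocalized feature-gene pairs")
    if method == "spearman":
        r, p = stats.spearmanr(xs, ys)
    else:
        r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), len(xs)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman's rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in permutations(ry):
        r = abs(np.corrcoef(rx, np.asarray(perm))[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return count / total


def correlation_ranking(
    expr_matrix: pd.DataFrame, reference_gene: str, method: str = "spearman"
) -> pd.DataFrame:
    """Rank genes by signed correlation strength with a reference gene.

    ``expr_matrix`` is genes x samples. For every other gene, Spearman rho
    and p against the reference across samples; score = sign(rho) x
    (-log10 p); sorted by score descending. Exact permutation p is used
    for n <= 8 samples, the t-approximation beyond. Zero-variance genes
    are excluded with a warning.
    """
    if reference_gene not in expr_matrix.index:
        raise ValueError(f"reference gene {reference_gene!r} not in matrix")
    n = expr_matrix.shape[1]
    if n < 5:
        raise ValueError("need at least 5 samples")
    ref = expr_matrix.loc[reference_gene].to_numpy(dtype=float)
    if np.ptp(ref) == 0:
        raise ValueError("reference gene has zero variance")
    rows = []
    dropped = 0
    for gene, vals in expr_matrix.iterrows():
        if gene == reference_gene:
            continue
        y = vals.to_numpy(dtype=float)
        if np.ptp(y) == 0:
            dropped += 1
            continue
        rho = float(stats.spearmanr(ref, y).statistic)
        if n <= 8:
            p = _exact_spearman_p(ref, y)
        else:
            p = float(stats.spearmanr(ref, y).pvalue)
        p = max(p, np.finfo(float).tiny)
        rows.append(dict(gene=gene, rho=rho, p=p, score=math.copysign(-math.log10(p), rho) if rho != 0 else 0.0))
    if dropped:
        warnings.warn(f"{dropped} zero-variance genes excluded")
    out = pd.DataFrame(rows).sort_values("score", ascending=False, kind="stable")
    return out.reset_index(drop=True)
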