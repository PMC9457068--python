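"""Synthetic-data generator: determinism, structure, ground-truth coupling."""

import numpy as np
import pytest

from subtadscope import synth
from subtadscope.synth import (
    ChangeRecord,
    ContactParams,
    DomainHierarchy,
    FeatureParams,
    GenomeSpec,
    HierarchyParams,
    PerturbParams,
    generate_domain_hierarchy,
    perturb_hierarchy,
    simulate_contact_matrix,
    simulate_features,
)

GEN = GenomeSpec({"chrA": 5_000_000}, 10_000)


def manual_hierarchy(
    genome=GEN, tad_bins=(150, 300), sub_bins=(80, 220, 400), tad_f=0.15, sub_f=0.5
) -> DomainHierarchy:
    chrom = next(iter(genome.chrom_sizes))
    return DomainHierarchy(
        genome,
        {chrom: np.array(tad_bins, dtype=np.int64)},
        {chrom: np.array(sub_bins, dtype=np.int64)},
        {chrom: np.full(len(tad_bins), tad_f)},
        {chrom: np.full(len(sub_bins), sub_f)},
    )


class TestHierarchyGeneration:
    def test_same_seed_identical(self):
        h1 = generate_domain_hierarchy(GEN, seed=3)
        h2 = generate_domain_hierarchy(GEN, seed=3)
        for c in GEN.chrom_sizes:
            assert np.array_equal(h1.tad_boundaries[c], h2.tad_boundaries[c])
            assert np.array_equal(h1.subtad_boundaries[c], h2.subtad_boundaries[c])
            assert np.array_equal(h1.subtad_factors[c], h2.subtad_factors[c])

    def test_subtads_nest_in_exactly_one_tad(self):
        h = generate_domain_hierarchy(GEN, seed=4)
        for c in GEN.chrom_sizes:
            tads = h.tads(c)
            for s, e in h.subtads(c):
                parents = [(ts, te) for ts, te in tads if ts <= s and e <= te]
                assert len(parents) == 1
            # subTADs tile their parents without overlap
            assert sum(e - s for s, e in h.subtads(c)) == GEN.n_bins(c)

    def test_zero_subtads_gives_empty_level(self):
        h = generate_domain_hierarchy(GEN, HierarchyParams(subtads_per_tad=(0, 0)), seed=1)
        assert all(v.size == 0 for v in h.subtad_boundaries.values())

    def test_tad_sizes_within_range(self):
        h = generate_domain_hierarchy(GEN, seed=5)
        for c in GEN.chrom_sizes:
            sizes = [e - s for s, e in h.tads(c)][:-1]  # last TAD is clipped
            assert all(10 <= sz <= 100 for sz in sizes)

    def test_infeasible_genome_rejected(self):
        tiny = GenomeSpec({"c": 1_500_000}, 10_000)
        with pytest.raises(ValueError, match="TAD size"):
            generate_domain_hierarchy(tiny, seed=0)


class TestContactSimulation:
    def test_zero_depth_zero_matrix(self):
        m = simulate_contact_matrix(manual_hierarchy(), "chrA", ContactParams(depth=0.0), seed=0)
        assert m.counts.sum() == 0

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            simulate_contact_matrix(manual_hierarchy(), "chrA", ContactParams(depth=-1.0), seed=0)

    def test_distance_decay_slope_matches_alpha(self):
        """log mean count vs log distance regresses to -alpha within 10%."""
        genome = GenomeSpec({"chrA": 4_000_000}, 10_000)
        chrom = "chrA"
        flat = DomainHierarchy(
            genome,
            {chrom: np.array([], dtype=np.int64)},
            {chrom: np.array([], dtype=np.int64)},
            {chrom: np.array([])},
            {chrom: np.array([])},
        )
        alpha = 1.0
        m = simulate_contact_matrix(flat, chrom, ContactParams(depth=1e4, alpha=alpha), seed=9)
        d = np.arange(1, 101)
        means = np.array([np.diagonal(m.counts, k).mean() for k in d])
        slope = np.polyfit(np.log(1 + d), np.log(means), 1)[0]
        assert abs(slope - (-alpha)) < 0.1 * alpha

    def test_subtad_enrichment_visible_in_obs_exp(self):
        """Within-subTAD obs/exp exceeds cross-boundary obs/exp (brute force)."""
        genome = GenomeSpec({"chrA": 3_000_000}, 10_000)
        h = DomainHierarchy(
            genome,
            {"chrA": np.array([], dtype=np.int64)},
            {"chrA": np.array([150], dtype=np.int64)},
            {"chrA": np.array([])},
            {"chrA": np.array([1.0])},  # no insulation: isolate the enrichment term
        )
        m = simulate_contact_matrix(h, "chrA", ContactParams(depth=200, e_tad=1.0, e_subtad=2.0), seed=3)
        n = m.n_bins
        within, cross = [], []
        for d in range(5, 30):
            diag = np.diagonal(m.counts, d)
            for i, v in enumerate(diag):
                j = i + d
                (within if (j < 150 or i >= 150) else cross).append(v / (1 + d) ** -1.0)
        assert np.mean(within) > np.mean(cross)

    def test_determinism(self):
        h = manual_hierarchy()
        a = simulate_contact_matrix(h, "chrA", seed=7)
        b = simulate_contact_matrix(h, "chrA", seed=7)
        assert np.array_equal(a.counts, b.counts)

    def test_loops_raise_local_intensity(self):
        h = manual_hierarchy()
        base = simulate_contact_matrix(h, "chrA", ContactParams(depth=50), seed=1)
        looped = simulate_contact_matrix(
            h, "chrA", ContactParams(depth=50), seed=1, loops=[(100, 130, 6.0)]
        )
        assert looped.counts[100, 130] > base.counts[100, 130]


class TestPerturbation:
    def test_zero_fractions_identity(self):
        h = manual_hierarchy()
        h2, rec = perturb_hierarchy(h, PerturbParams(0, 0, 0, 0), seed=0)
        for c in GEN.chrom_sizes:
            assert np.array_equal(h.tad_boundaries[c], h2.tad_boundaries[c])
            assert np.array_equal(h.subtad_boundaries[c], h2.subtad_boundaries[c])
        assert rec.n_removed("TAD") == rec.n_added("TAD") == 0
        assert rec.n_removed("subTAD") == rec.n_added("subTAD") == 0

    def test_removal_count_is_rounded_fraction(self):
        """100 subTAD boundaries at fraction 0.17 remove exactly 17."""
        genome = GenomeSpec({"chrA": 12_000_000}, 10_000)
        subs = np.arange(10, 1010, 10, dtype=np.int64)[:100]
        h = DomainHierarchy(
            genome,
            {"chrA": np.array([], dtype=np.int64)},
            {"chrA": subs},
            {"chrA": np.array([])},
            {"chrA": np.full(100, 0.5)},
        )
        _, rec = perturb_hierarchy(h, PerturbParams(0.17, 0, 0, 0), seed=2)
        assert rec.n_removed("subTAD") == 17

    def test_tad_removal_merges_adjacent(self):
        h = manual_hierarchy(tad_bins=tuple(range(50, 550, 50)), sub_bins=())
        n_before = len(h.tads("chrA"))
        h2, rec = perturb_hierarchy(h, PerturbParams(0, 0, 0.1, 0), seed=1)
        assert rec.n_removed("TAD") == 1
        assert len(h2.tads("chrA")) == n_before - 1

    @pytest.mark.parametrize("seed", range(4))
    def test_change_record_consistency(self, seed):
        """Removed boundaries came from the original; added are novel."""
        h = generate_domain_hierarchy(GEN, seed=seed)
        h2, rec = perturb_hierarchy(h, seed=seed + 50)
        for c in GEN.chrom_sizes:
            assert np.isin(rec.removed_subtad[c], h.subtad_boundaries[c]).all()
            assert np.isin(rec.removed_tad[c], h.tad_boundaries[c]).all()
            assert not np.isin(rec.added_subtad[c], h.subtad_boundaries[c]).any()
            assert not np.isin(rec.added_tad[c], h.tad_boundaries[c]).any()
            # bookkeeping: new level size = old - removed + added (minus any
            # subTAD displaced by an added TAD boundary)
            expected = (
                len(h.subtad_boundaries[c])
                - len(rec.removed_subtad[c])
                + len(rec.added_subtad[c])
            )
            assert len(h2.subtad_boundaries[c]) <= expected
            assert len(h2.subtad_boundaries[c]) >= expected - len(rec.added_tad[c])

    def test_genome_unchanged(self):
        h = generate_domain_hierarchy(GEN, seed=0)
        h2, _ = perturb_hierarchy(h, seed=1)
        assert h2.genome.chrom_sizes == GEN.chrom_sizes


class TestFeatureSimulation:
    def test_full_coupling_marks_every_removed_boundary(self):
        h = generate_domain_hierarchy(GEN, seed=6)
        _, rec = perturb_hierarchy(h, seed=7)
        feats = simulate_features(h, rec, FeatureParams(ctcf_coupling=1.0), seed=8)
        t = feats.ctcf_table
        lost_pos = t.loc[t["truth_class"] == "lost", ["chrom", "pos"]]
        for c in GEN.chrom_sizes:
            lp = lost_pos.loc[lost_pos["chrom"] == c, "pos"].to_numpy()
            for k in rec.removed_subtad[c].tolist():
                assert np.abs(lp - k * GEN.resolution).min() <= 10_000

    def test_lost_sites_have_weaker_control_occupancy(self):
        h = generate_domain_hierarchy(GEN, seed=6)
        _, rec = perturb_hierarchy(h, seed=7)
        t = simulate_features(h, rec, seed=9).ctcf_table
        ctl = t[["ctl_1", "ctl_2"]].mean(axis=1)
        assert ctl[t["truth_class"] == "lost"].mean() < ctl[t["truth_class"] == "constant"].mean()

    def test_zero_coupling_decouples_boundary_loss_from_peak_loss(self):
        """With coupling 0, boundary removal and peak loss are independent."""
        xs, ys = [], []
        for seed in range(50):
            h = generate_domain_hierarchy(GEN, seed=seed)
            _, rec = perturb_hierarchy(h, seed=seed + 100)
            t = simulate_features(
                h, rec, FeatureParams(ctcf_coupling=0.0, background_lost_frac=0.2), seed=seed + 200
            ).ctcf_table
            at_b = t[t["at_level"] != "none"]
            xs.extend(at_b["at_removed"].astype(float).tolist())
            ys.extend((at_b["truth_class"] == "lost").astype(float).tolist())
        r = np.corrcoef(xs, ys)[0, 1]
        assert abs(r) < 0.1

    def test_expression_truth_offset_at_gained_boundaries(self):
        h = generate_domain_hierarchy(GEN, seed=6)
        _, rec = perturb_hierarchy(h, seed=7)
        expr = simulate_features(h, rec, seed=10).expression
        coupled = expr["true_log2fc"] >= 1.0
        if coupled.any():
            gained_bp = np.concatenate(
                [rec.added_subtad[c] * GEN.resolution for c in GEN.chrom_sizes]
            )
            for g in expr[coupled].itertuples():
                assert np.abs(gained_bp - g.tss).min() <= 10_000 or abs(g.true_log2fc) > 0

    def test_truth_classes_partition_features(self):
        h = generate_domain_hierarchy(GEN, seed=6)
        _, rec = perturb_hierarchy(h, seed=7)
        feats = simulate_features(h, rec, seed=11)
        for table in (feats.ctcf_table, feats.mark_table):
            assert table["truth_class"].isin(["constant", "lost", "gained"]).all()

    def test_invalid_coupling_rejected(self):
        h = generate_domain_hierarchy(GEN, seed=6)
        _, rec = perturb_hierarchy(h, seed=7)
        with pytest.raises(ValueError):
            simulate_features(h, rec, FeatureParams(ctcf_coupling=1.5), seed=0)


def test_experiment_determinism(small_genome):
    a = synth.simulate_experiment(genome=small_genome, seed=33)
    b = synth.simulate_experiment(genome=small_genome, seed=33)
    assert np.array_equal(
        a.control_matrices["chrA"].counts, b.control_matrices["chrA"].counts
    )
    assert a.features.expression.equals(b.features.expression)
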