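import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest
from sklearn.metrics import adjusted_rand_score

from tilecall.chip import (ChipBindingModel, apply_promoter_filter,
                           apply_transcribed_filter, assign_closest_orf,
                           build_probe_sets, cluster_binding_profiles,
                           collapse_bound_regions, combine_probe_set,
                           score_probes)
from .conftest import make_score_frame
from .oracles import (bound_regions_oracle, random_score_table,
                      stouffer_oracle_mpmath)


def _annotation(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss",
                                       "orf_start", "orf_end"])


class TestScoreProbes:
    def test_requires_enough_probes(self):
        spots = pd.DataFrame(dict(probe_id=["p"], chrom="chr1", start=[0],
                                  end=[50], ch1_net=[100.0], ch2_net=[100.0]))
        with pytest.raises(ValueError, match="500"):
            score_probes(spots)

    def test_null_p_values_uniform(self, null_chip_simulation):
        scores = score_probes(null_chip_simulation["qc_spots"])
        stat = kstest(scores["p_single"], "uniform")
        assert stat.pvalue > 0.01
        # symmetric null: the median probe sits near p = 0.5
        assert abs(np.median(scores["p_single"]) - 0.5) < 0.02

    def test_spiked_probes_score_extreme(self, chip_simulation):
        scores = score_probes(chip_simulation["qc_spots"])
        truth = chip_simulation["truth"].bound_regions
        mids = 0.5 * (scores["start"] + scores["end"])
        hot = np.zeros(len(scores), dtype=bool)
        for r in truth.itertuples(index=False):
            hot |= ((scores["chrom"] == r.chrom).to_numpy()
                    & (mids >= r.start).to_numpy() & (mids < r.end).to_numpy())
        assert np.median(scores.loc[hot, "p_single"]) < 1e-4

    def test_sorted_and_floor_applied(self, chip_simulation):
        scores = score_probes(chip_simulation["qc_spots"])
        assert (scores["p_single"] >= 1e-300).all()
        grouped = scores.groupby("chrom", sort=False)["start"]
        assert all(s.is_monotonic_increasing for _, s in grouped)


class TestCombineProbeSet:
    def test_null_triple_stays_at_half(self):
        assert combine_probe_set(0.5, 0.5, 0.5) == pytest.approx(0.5)

    def test_strong_triple_matches_oracle(self):
        got = combine_probe_set(0.001, 0.001, 0.001)
        assert got == pytest.approx(4.3388193535682354e-08, rel=1e-10)
        assert got == pytest.approx(stouffer_oracle_mpmath(0.001, 0.001, 0.001),
                                    rel=1e-10)

    @given(st.tuples(*[st.floats(min_value=1e-12, max_value=1.0,
                                 allow_nan=False)] * 3))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_in_arguments(self, ps):
        a, b, c = ps
        ref = combine_probe_set(a, b, c)
        assert combine_probe_set(c, a, b) == ref
        assert combine_probe_set(b, c, a) == ref

    def test_zero_input_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            out = combine_probe_set(0.0, 0.5, 0.5)
        assert 0 < out <= 1


class TestBuildProbeSets:
    def test_five_probes_give_three_windows(self):
        sets = build_probe_sets(make_score_frame([0.5] * 5))
        assert len(sets) == 3
        assert sets["center_index"].tolist() == [1, 2, 3]

    def test_large_gap_excludes_spanning_windows(self):
        scores = make_score_frame([0.5] * 6)
        scores.loc[3:, "start"] += 5000
        scores.loc[3:, "end"] += 5000
        sets = build_probe_sets(scores, max_gap=1000)
        assert sets["center_index"].tolist() == [1, 4]

    def test_two_probes_no_windows(self):
        assert len(build_probe_sets(make_score_frame([0.5, 0.5]))) == 0

    def test_chromosome_boundaries_respected(self):
        scores = pd.concat([make_score_frame([0.5] * 3, chrom="chr1"),
                            make_score_frame([0.5] * 3, chrom="chr2")],
                           ignore_index=True)
        sets = build_probe_sets(scores)
        assert len(sets) == 2
        assert sets["chrom"].tolist() == ["chr1", "chr2"]


def _sets_from_p(p_center, p_flank1, p_flank2, p_combined):
    return pd.DataFrame(dict(chrom=["chr1"], start=[0], end=[650],
                             center_index=[1], p_center=[p_center],
                             p_flank1=[p_flank1], p_flank2=[p_flank2],
                             p_combined=[p_combined]))


class TestFilters:
    @pytest.mark.parametrize("pc,pf1,pf2,comb,expected", [
        (5e-4, 5e-3, 0.5, 4e-4, True),
        (2e-3, 1e-4, 1e-4, 1e-6, False),   # center not < 0.001
        (5e-4, 0.02, 0.5, 4e-4, False),    # no flank < 0.01
        (5e-4, 5e-3, 0.5, 2e-3, False),    # combined not < 0.001
        (1e-3, 5e-3, 0.5, 4e-4, False),    # strict at the boundary
    ])
    def test_promoter_rule(self, pc, pf1, pf2, comb, expected):
        mask = apply_promoter_filter(_sets_from_p(pc, pf1, pf2, comb))
        assert bool(mask[0]) is expected

    def test_transcribed_rule_uses_neighbor_window_combined_p(self):
        # five probes; make neighbor windows' combined P controllable
        scores = make_score_frame([0.5, 1e-4, 1e-3, 0.5, 0.5])
        sets = build_probe_sets(scores)
        by_center = sets.set_index("center_index")
        mask = apply_transcribed_filter(sets)
        center = by_center.loc[2]
        left_comb = by_center.loc[1, "p_combined"]
        expect = (center["p_center"] < 5e-3
                  and center["p_combined"] < 1e-4
                  and left_comb < 1e-3)
        got = bool(mask[sets["center_index"].tolist().index(2)])
        assert got == bool(expect)

    def test_edge_window_fails_neighbor_clause(self):
        # only one window exists: no neighbor windows -> clause fails
        scores = make_score_frame([1e-6, 1e-6, 1e-6])
        sets = build_probe_sets(scores)
        assert len(sets) == 1
        assert not apply_transcribed_filter(sets)[0]
        assert apply_promoter_filter(sets)[0]  # same window passes rule 1

    @given(st.floats(min_value=1e-10, max_value=1.0, exclude_max=False),
           st.floats(min_value=1e-10, max_value=1.0),
           st.floats(min_value=1e-10, max_value=1.0),
           st.integers(min_value=0, max_value=2))
    @settings(max_examples=60, deadline=None)
    def test_decreasing_a_member_p_never_unpasses(self, pc, pf1, pf2, which):
        ps = [pc, pf1, pf2]
        sets = _sets_from_p(ps[0], ps[1], ps[2],
                            combine_probe_set(*ps))
        before = apply_promoter_filter(sets)[0]
        ps[which] /= 10.0
        sets2 = _sets_from_p(ps[0], ps[1], ps[2], combine_probe_set(*ps))
        after = apply_promoter_filter(sets2)[0]
        assert after or not before


class TestCollapse:
    def test_overlapping_windows_merge(self):
        scores = make_score_frame([0.5] * 6)
        sets = pd.DataFrame(dict(chrom="chr1", start=[100, 200],
                                 end=[300, 400], center_index=[1, 2],
                                 p_center=0.5, p_flank1=0.5, p_flank2=0.5,
                                 p_combined=[1e-4, 1e-5]))
        out = collapse_bound_regions(sets, scores)
        assert len(out) == 1
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (100, 400)
        assert out.loc[0, "n_probe_sets"] == 2
        assert out.loc[0, "best_p"] == 1e-5

    def test_different_chromosomes_never_merge(self):
        scores = pd.concat([make_score_frame([0.5] * 3, chrom="chr1"),
                            make_score_frame([0.5] * 3, chrom="chr2")],
                           ignore_index=True)
        sets = build_probe_sets(scores)
        out = collapse_bound_regions(sets, scores)
        assert len(out) == 2

    def test_max_enrichment_from_member_probes(self):
        scores = make_score_frame([0.5] * 3, ratios=[1.0, 2.0, 1.5])
        sets = build_probe_sets(scores)
        out = collapse_bound_regions(sets, scores)
        assert out.loc[0, "max_enrichment"] == pytest.approx(4.0)

    def test_disjoint_windows_pass_through_unchanged(self):
        scores = make_score_frame([0.5] * 9)
        sets = build_probe_sets(scores).iloc[[0, 6]]  # far apart
        out = collapse_bound_regions(sets, scores)
        assert out["start"].tolist() == sets["start"].tolist()
        assert out["end"].tolist() == sets["end"].tolist()


class TestAssignClosestOrf:
    def test_nearest_tss_with_signed_distance(self):
        ann = _annotation([("geneA", "chr1", "+", 1200, 1200, 2000),
                           ("geneB", "chr1", "+", 5000, 5000, 6000)])
        regions = pd.DataFrame(dict(chrom=["chr1"], start=[900], end=[1100]))
        out = assign_closest_orf(regions, ann)
        assert out.loc[0, "gene_id"] == "geneA"
        assert out.loc[0, "tss_distance"] == -200.0

    def test_tie_prefers_plus_strand_then_lexicographic(self):
        ann = _annotation([("geneB", "chr1", "-", 900, 500, 900),
                           ("geneA", "chr1", "+", 1100, 1100, 1500)])
        regions = pd.DataFrame(dict(chrom=["chr1"], start=[950], end=[1050]))
        out = assign_closest_orf(regions, ann)
        assert out.loc[0, "gene_id"] == "geneA"
        ann2 = _annotation([("geneZ", "chr1", "+", 900, 900, 1500),
                            ("geneA", "chr1", "+", 1100, 1100, 1500)])
        out2 = assign_closest_orf(regions, ann2)
        assert out2.loc[0, "gene_id"] == "geneA"

    def test_nearest_tss_beats_containing_orf(self):
        # region inside geneA's ORF but closer to geneB's TSS
        ann = _annotation([("geneA", "chr1", "+", 0, 0, 10000),
                           ("geneB", "chr1", "+", 5100, 5100, 7000)])
        regions = pd.DataFrame(dict(chrom=["chr1"], start=[4900], end=[5100]))
        out = assign_closest_orf(regions, ann)
        assert out.loc[0, "gene_id"] == "geneB"
        out_orf = assign_closest_orf(regions, ann, mode="orf")
        assert out_orf.loc[0, "gene_id"] == "geneA"

    def test_empty_annotation_rejected(self):
        regions = pd.DataFrame(dict(chrom=["chr1"], start=[0], end=[100]))
        with pytest.raises(ValueError):
            assign_closest_orf(regions, _annotation([]))


class TestClusterProfiles:
    @staticmethod
    def _profiled_scores(n_genes=40, seed=0):
        """Half the genes carry a TSS-proximal peak, half a uniform level."""
        rng = np.random.default_rng(seed)
        rows, ann_rows, truth = [], [], {}
        for g in range(n_genes):
            gene = f"g{g:03d}"
            tss = 2000
            chrom = f"c{g}"
            archetype = g % 2
            truth[gene] = archetype
            for i in range(10):
                start = i * 200
                mid = start + 25
                if archetype == 0:
                    val = 3.0 * np.exp(-((tss - mid) / 300.0) ** 2)
                else:
                    val = 1.5
                rows.append(dict(probe_id=f"{gene}_{i}", chrom=chrom,
                                 start=start, end=start + 50, A=10.0,
                                 ratio_log2=val + rng.normal(0, 0.05),
                                 p_single=0.5))
            ann_rows.append(dict(gene_id=gene, chrom=chrom, strand="+",
                                 tss=tss, orf_start=tss, orf_end=tss + 1000,
                                 promoter_start=0, promoter_end=2000))
        scores = pd.DataFrame(rows)
        ann = pd.DataFrame(ann_rows)
        regions = pd.DataFrame(dict(chrom=[f"c{g}" for g in range(n_genes)],
                                    start=0, end=2000,
                                    gene_id=[f"g{g:03d}" for g in range(n_genes)]))
        return scores, regions, ann, truth

    def test_two_archetypes_perfectly_separated(self):
        scores, regions, ann, truth = self._profiled_scores()
        labels = cluster_binding_profiles(scores, regions, ann, k=2, seed=0)
        ari = adjusted_rand_score([truth[g] for g in labels.index],
                                  labels.to_numpy())
        assert ari == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        scores, regions, ann, _ = self._profiled_scores()
        a = cluster_binding_profiles(scores, regions, ann, k=2, seed=3)
        b = cluster_binding_profiles(scores, regions, ann, k=2, seed=3)
        assert a.equals(b)

    def test_k_equal_genes_gives_singletons(self):
        scores, regions, ann, _ = self._profiled_scores(n_genes=6)
        labels = cluster_binding_profiles(scores, regions, ann, k=6, seed=0)
        assert sorted(labels.to_numpy()) == list(range(6))

    def test_fewer_genes_than_k_rejected(self):
        scores, regions, ann, _ = self._profiled_scores(n_genes=4)
        with pytest.raises(ValueError):
            cluster_binding_profiles(scores, regions, ann, k=5)


class TestOracleEquivalence:
    def test_pipeline_matches_brute_force_on_random_arrays(self):
        rng = np.random.default_rng(2024)
        from tilecall.chip import collapse_bound_regions
        for _ in range(40):
            scores = random_score_table(rng, max_probes=300)
            sets = build_probe_sets(scores, max_gap=1000)
            if len(sets):
                passing = sets[apply_promoter_filter(sets)
                               | apply_transcribed_filter(sets)]
            else:
                passing = sets
            got = {(r.chrom, r.start, r.end)
                   for r in collapse_bound_regions(passing, scores)
                   .itertuples(index=False)}
            expected = bound_regions_oracle(scores, max_gap=1000)
            assert got == expected


class TestModelEndToEnd:
    def test_spike_in_recovery(self, chip_simulation):
        res = ChipBindingModel(chip_simulation["qc_spots"],
                               chip_simulation["annotation"]).fit()
        truth = chip_simulation["truth"].bound_regions

        def overlaps(r, t):
            return (r["chrom"] == t["chrom"] and r["start"] < t["end"]
                    and t["start"] < r["end"])

        regs = res.regions.to_dict("records")
        gts = truth.to_dict("records")
        sens = np.mean([any(overlaps(r, t) for r in regs) for t in gts])
        fdr = np.mean([not any(overlaps(r, t) for t in gts) for r in regs])
        assert sens >= 0.9
        assert fdr <= 0.1

    def test_summary_and_bed_output(self, chip_simulation, tmp_path):
        res = ChipBindingModel(chip_simulation["qc_spots"],
                               chip_simulation["annotation"]).fit()
        assert f"bound regions: {len(res.regions)}" in res.summary()
        res.to_bed(tmp_path / "bound.bed")
        res.to_tsv(tmp_path / "bound.tsv")
        back = pd.read_csv(tmp_path / "bound.tsv", sep="\t")
        assert len(back) == len(res.regions)
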