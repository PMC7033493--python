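"""Filter cascade: per-rule semantics, boundary behavior, oracle equivalence."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _utils import brute_force_cascade, cascade_keys, manual_quantile
from editscan.editcall import (FilterThresholds, editing_degree, finalize_sites,
                               quality_filter, quantile_spread_keep,
                               recurrence_keep, remove_full_degree,
                               remove_known_snps_and_indels,
                               remove_sample_mutations, run_cascade,
                               site_filters)
from editscan.formats import GeneModel, GenomicInterval, Transcript
from editscan.simulate import simulate_filter_stress


def make_obs(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt",
                                       "ref_reads", "alt_reads", "fs", "qd"])


class TestEditingDegree:
    @pytest.mark.parametrize("alt,total,expected",
                             [(3, 12, 0.25), (0, 10, 0.0), (10, 10, 1.0)])
    def test_degree_is_edited_read_fraction(self, alt, total, expected):
        assert editing_degree(alt, total) == expected

    def test_zero_coverage_is_undefined(self):
        with pytest.raises(ValueError):
            editing_degree(0, 0)


class TestPerObservationFilters:
    def test_mutation_removal_is_per_sample(self):
        obs = make_obs([("S1", "chr1", 500, "A", "G", 10, 5, 1.0, 10.0),
                        ("S2", "chr1", 500, "A", "G", 10, 5, 1.0, 10.0),
                        ("S1", "chr1", 900, "A", "G", 10, 5, 1.0, 10.0)])
        muts = pd.DataFrame({"sample": ["S1"], "chrom": ["chr1"], "pos": [500]})
        out = remove_sample_mutations(obs, muts)
        assert set(zip(out["sample"], out["pos"])) == {("S2", 500), ("S1", 900)}

    def test_snp_removal_is_cohort_wide_and_indels_drop(self):
        obs = make_obs([("S1", "chr1", 10, "A", "G", 10, 5, 1, 10),
                        ("S2", "chr1", 10, "A", "G", 10, 5, 1, 10),
                        ("S1", "chr1", 20, "A", "AG", 10, 5, 1, 10),
                        ("S1", "chr1", 30, "C", "T", 10, 5, 1, 10)])
        out = remove_known_snps_and_indels(obs, {("chr1", 10)})
        assert list(out["pos"]) == [30]

    @pytest.mark.parametrize("fs,qd,alt,cov,kept", [
        (25.0, 5.0, 3, 30, False),   # FS > 20 removed
        (20.0, 5.0, 3, 30, True),    # boundary: strict comparison, FS = 20 survives
        (1.0, 1.9, 3, 30, False),    # QD < 2 removed
        (1.0, 2.0, 3, 30, True),     # QD = 2 survives
        (0.0, 5.0, 1, 30, False),    # support < 2 reads removed
        (0.0, 5.0, 2, 10, True),     # boundary: alt = 2, coverage = 10 survive
        (0.0, 5.0, 3, 9, False),     # coverage < 10 removed
        (np.nan, np.nan, 3, 30, True),  # absent FS/QD pass
    ])
    def test_quality_thresholds_are_strict_as_printed(self, fs, qd, alt, cov, kept):
        obs = make_obs([("S1", "chr1", 1, "A", "G", cov - alt, alt, fs, qd)])
        assert (len(quality_filter(obs)) == 1) is kept

    def test_full_degree_observation_mode_keeps_the_site(self):
        obs = make_obs([("S1", "chr1", 1, "A", "G", 0, 20, 1, 10),
                        ("S2", "chr1", 1, "A", "G", 10, 10, 1, 10)])
        out = remove_full_degree(obs, "observation")
        assert list(out["sample"]) == ["S2"]
        assert remove_full_degree(obs, "site").empty

    def test_per_observation_steps_commute(self):
        obs, muts, snps, _ = simulate_filter_stress(800, seed=3)
        steps = [lambda o: remove_sample_mutations(o, muts),
                 lambda o: remove_known_snps_and_indels(o, snps),
                 lambda o: quality_filter(o)]
        results = []
        for perm in itertools.permutations(range(3)):
            cur = obs
            for i in perm:
                cur = steps[i](cur)
            results.append(cascade_keys(cur))
        assert all(r == results[0] for r in results)


class TestSiteFilters:
    def test_constant_degrees_have_zero_spread(self):
        assert not quantile_spread_keep(np.full(30, 0.30), 30)

    def test_uniform_grid_of_degrees_keeps(self):
        assert quantile_spread_keep(np.arange(10) / 10.0, 10)

    def test_spread_decision_matches_independent_quantile_oracle(self):
        degrees = np.array([0.5] * 10)
        vec = [0.0] * 90 + [0.5] * 10
        expected = (manual_quantile(vec, 0.9) - manual_quantile(vec, 0.1)) >= 0.10
        assert quantile_spread_keep(degrees, 100) is expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, width=32), min_size=1, max_size=40),
           st.integers(1, 80))
    def test_spread_agrees_with_oracle_for_random_vectors(self, degrees, extra):
        n = len(degrees) + extra
        vec = list(degrees) + [0.0] * extra
        expected = (manual_quantile(vec, 0.9) - manual_quantile(vec, 0.1)) \
            >= 0.10 - 1e-12
        assert quantile_spread_keep(np.array(degrees), n) == expected

    @pytest.mark.parametrize("n_edited,n_samples,kept",
                             [(4, 423, False), (5, 423, True), (1, 100, True)])
    def test_recurrence_uses_ceiling_of_one_percent(self, n_edited, n_samples, kept):
        assert recurrence_keep(n_edited, n_samples) is kept


def _gene(gene_id, chrom, start, end, strand):
    tx = Transcript(transcript_id=f"{gene_id}.t", strand=strand,
                    exons=[GenomicInterval(chrom, start, end, strand)])
    return GeneModel(gene_id=gene_id, gene_name=gene_id,
                     gene_type="protein_coding", chrom=chrom, strand=strand,
                     transcripts=[tx])


class TestFinalize:
    def test_dual_strand_noncanonical_and_strand_assignment(self):
        genes = [_gene("gp", "chr1", 0, 1000, "+"),
                 _gene("gm", "chr1", 500, 1500, "-"),
                 _gene("gm2", "chr2", 0, 1000, "-")]
        obs = make_obs([
            ("S1", "chr1", 700, "A", "G", 10, 5, 1, 10),    # dual strand -> gone
            ("S1", "chr1", 1200, "T", "C", 10, 5, 1, 10),   # single - gene
            ("S1", "chrUn_x", 10, "A", "G", 10, 5, 1, 10),  # unplaced -> gone
            ("S1", "chr2", 100, "T", "C", 10, 5, 1, 10),
        ])
        roles = pd.Series({"S1": "tumor"})
        cat = finalize_sites(obs, genes, {"chr1", "chr2"}, roles)
        assert list(cat.sites["pos"]) == [1200, 100]
        assert list(cat.sites["strand"]) == ["-", "-"]


class TestCascadeOracle:
    def test_pipeline_equals_single_pass_brute_force(self):
        obs, muts, snps, roles = simulate_filter_stress(2000, seed=9)
        cat = run_cascade(obs, muts, snps, [], {"chr1"}, roles)
        expected = brute_force_cascade(obs, muts, snps, len(roles),
                                       canonical={"chr1"})
        got = set()
        for sid, row in cat.sites.iterrows():
            for s in cat.degrees.columns:
                if pd.notna(cat.degrees.loc[sid, s]):
                    got.add((s, row["chrom"], row["pos"], row["ref"], row["alt"]))
        assert got == expected

    def test_tightening_coverage_never_grows_the_survivor_set(self):
        obs, muts, snps, roles = simulate_filter_stress(1500, seed=4)
        loose = run_cascade(obs, muts, snps, [], {"chr1"}, roles)
        tight = run_cascade(obs, muts, snps, [], {"chr1"}, roles,
                            FilterThresholds(min_coverage=15))
        assert set(tight.sites.index) <= set(loose.sites.index)
        for sid in tight.sites.index:
            t_deg = tight.degrees.loc[sid].dropna()
            assert set(t_deg.index) <= set(loose.degrees.loc[sid].dropna().index)

    def test_surviving_degrees_open_interval_and_recurrence(self):
        obs, muts, snps, roles = simulate_filter_stress(1500, seed=6)
        cat = run_cascade(obs, muts, snps, [], {"chr1"}, roles)
        d = cat.degrees.to_numpy()
        finite = d[~np.isnan(d)]
        assert ((finite > 0) & (finite < 1)).all()
        edited = (cat.degrees.fillna(0) > 0).sum(axis=1)
        assert (edited >= np.ceil(0.01 * len(roles))).all()


class TestSiteFilterGrouping:
    def test_site_filters_drop_low_spread_and_rare_sites(self):
        rows = []
        for s in range(20):  # constant-degree site at pos 1
            rows.append((f"S{s}", "chr1", 1, "A", "G", 7, 3, 1, 10))
        rows.append(("S0", "chr1", 2, "A", "G", 5, 5, 1, 10))  # spread but rare?
        for s in range(8):  # spread site at pos 3
            rows.append((f"S{s}", "chr1", 3, "A", "G", 10 - s, s + 2, 1, 10))
        out = site_filters(make_obs(rows), n_samples=20)
        assert set(out["pos"]) == {3}
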