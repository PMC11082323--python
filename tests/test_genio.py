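"""IO round-trips, quality-control rules, phenotype screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ssgblup import genio
from ssgblup.genio import (GenotypeMatrix, hwe_chisq_p, hwe_exact_p, impute_mean,
                           intersect_snps, make_snp_map, qc_animals, qc_snps,
                           read_dosage_csv, read_plink_pedmap, scc_to_scs,
                           screen_phenotypes, write_dosage_csv, write_plink_pedmap)


def _gm(dosages, breeds=None, ids=None):
    dosages = np.asarray(dosages, dtype=float)
    n = dosages.shape[0]
    ids = ids or [f"a{i}" for i in range(n)]
    breeds = breeds or ["b1"] * n
    return GenotypeMatrix(ids, dosages, breeds)


def _map(n, chrom=1, start=1000, step=1000):
    return make_snp_map([f"s{i}" for i in range(n)], [chrom] * n,
                        [start + i * step for i in range(n)])


class TestPlinkRoundTrip:
    def test_ped_map_round_trip(self, tmp_path):
        dos = [[0, 1, 2, 1], [2, 1, 0, np.nan], [1, 0, 1, 2]]
        gm = _gm(dos, breeds=["b1", "b1", "b2"])
        snp_map = _map(4)
        write_plink_pedmap(gm, snp_map, tmp_path / "x.ped", tmp_path / "x.map")
        gm2, map2 = read_plink_pedmap(tmp_path / "x.ped", tmp_path / "x.map")
        np.testing.assert_array_equal(gm2.dosages, gm.dosages)
        assert list(gm2.animal_ids) == list(gm.animal_ids)
        assert list(gm2.breeds) == list(gm.breeds)
        assert list(map2.snp_id) == list(snp_map.snp_id)

    def test_missing_allele_pair_reads_as_nan(self, tmp_path):
        (tmp_path / "m.map").write_text("1 s0 0 1000\n")
        (tmp_path / "m.ped").write_text("f1 a0 0 0 0 -9 0 0\nf1 a1 0 0 0 -9 A B\n")
        gm, _ = read_plink_pedmap(tmp_path / "m.ped", tmp_path / "m.map")
        assert np.isnan(gm.dosages[0, 0]) and gm.dosages[1, 0] == 1

    def test_triallelic_snp_rejected_by_name(self, tmp_path):
        (tmp_path / "t.map").write_text("1 badsnp 0 1000\n")
        (tmp_path / "t.ped").write_text("f a0 0 0 0 -9 A B\nf a1 0 0 0 -9 C C\n")
        with pytest.raises(ValueError, match="badsnp"):
            read_plink_pedmap(tmp_path / "t.ped", tmp_path / "t.map")

    def test_duplicate_animal_rejected(self, tmp_path):
        (tmp_path / "d.map").write_text("1 s0 0 1000\n")
        (tmp_path / "d.ped").write_text("f a0 0 0 0 -9 A A\nf a0 0 0 0 -9 B B\n")
        with pytest.raises(ValueError, match="duplicated"):
            read_plink_pedmap(tmp_path / "d.ped", tmp_path / "d.map")


class TestDosageCsv:
    def test_round_trip_with_missing(self, tmp_path):
        gm = _gm([[0, 1, 2], [np.nan, 2, 0]], breeds=["b1", "b2"])
        write_dosage_csv(gm, _map(3), tmp_path / "d.csv")
        gm2 = read_dosage_csv(tmp_path / "d.csv")
        np.testing.assert_array_equal(gm2.dosages, gm.dosages)
        assert list(gm2.breeds) == ["b1", "b2"]

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_round_trip_random_matrices(self, seed):
        import io

        rng = np.random.default_rng(seed)
        dos = rng.choice([0.0, 1.0, 2.0, np.nan], size=(4, 6), p=[0.3, 0.3, 0.3, 0.1])
        gm = _gm(dos)
        buf = io.StringIO()
        write_dosage_csv(gm, _map(6), buf)
        buf.seek(0)
        np.testing.assert_array_equal(read_dosage_csv(buf).dosages, dos)

    def test_simulated_file_dimensions_match_manifest(self, tmp_path):
        from ssgblup.simdata import SimConfig, write_dataset

        cfg = SimConfig(n_animals_per_breed=50, n_snps=40, n_chromosomes=2, seed=3)
        info = write_dataset(tmp_path, cfg)
        gm = read_dosage_csv(tmp_path / "genotypes.csv")
        assert gm.n_animals == info["n_animals"] == 100
        assert gm.n_snps == info["n_snps"] == 40
        gm_ped, _ = read_plink_pedmap(tmp_path / "genotypes.ped", tmp_path / "genotypes.map")
        assert gm_ped.n_animals == 100 and gm_ped.n_snps == 40


class TestQcAnimals:
    def test_complete_animal_retained(self):
        gm = _gm([[0, 1], [np.nan, np.nan]])
        out, rep = qc_animals(gm, 0.90)
        assert list(out.animal_ids) == ["a0"]
        assert rep.animal_rules["call_rate"] == 1

    def test_call_rate_just_below_threshold_removed(self):
        row = np.ones(100)
        row[:11] = np.nan  # call rate 0.89
        gm = _gm([np.ones(100), row])
        out, _ = qc_animals(gm, 0.90)
        assert list(out.animal_ids) == ["a0"]

    def test_exact_removal_count_matches_brute_force(self):
        rng = np.random.default_rng(42)
        dos = rng.choice([0.0, 1.0, 2.0], size=(20, 50))
        for i in (3, 7, 15):
            miss = rng.choice(50, size=10, replace=False)
            dos[i, miss] = np.nan
        gm = _gm(dos)
        out, rep = qc_animals(gm, 0.90)
        expected = [i for i in range(20)
                    if (~np.isnan(dos[i])).sum() / 50 >= 0.90]
        assert list(out.animal_ids) == [f"a{i}" for i in expected]
        assert rep.animal_rules["call_rate"] == 3
        assert rep.n_animals_in - rep.n_animals_out == 3

    def test_all_removed_is_error(self):
        gm = _gm([[np.nan, np.nan]])
        with pytest.raises(ValueError, match="all animals"):
            qc_animals(gm, 0.90)


class TestQcSnps:
    def test_perfect_hwe_retained(self):
        # genotype counts (25, 50, 25): chi-square 0, p = 1
        col = np.array([0.0] * 25 + [1.0] * 50 + [2.0] * 25)
        assert hwe_chisq_p(25, 50, 25) == pytest.approx(1.0)
        gm = _gm(col[:, None])
        out, _, rep = qc_snps(gm, _map(1))
        assert out.n_snps == 1 and rep.snp_rules["hwe"] == 0

    def test_low_maf_removed(self):
        col = np.zeros(1000)
        col[:10] = 1.0  # MAF 0.005
        gm = _gm(col[:, None])
        out, _, rep = qc_snps(gm, _map(1))
        assert out.n_snps == 0 and rep.snp_rules["maf"] == 1

    def test_hwe_violation_detected_by_both_tests(self):
        # 50 hom + 50 hom, no hets: gross disequilibrium
        assert hwe_chisq_p(50, 0, 50) < 1e-20
        assert hwe_exact_p(50, 0, 50) < 1e-6
        assert hwe_exact_p(25, 50, 25) > 0.5

    def test_chromosome_filter(self):
        gm = _gm(np.tile([0.0, 1.0, 2.0, 1.0], (2, 1)).T)
        snp_map = make_snp_map(["s0", "s1"], [31, 5], [100, 100])
        out, out_map, rep = qc_snps(gm, snp_map)
        assert list(out_map.snp_id) == ["s1"] and rep.snp_rules["chromosome"] == 1

    def test_crafted_panel_matches_rule_by_rule_oracle(self):
        """200-SNP panel with seeded violations equals an independent filter."""
        rng = np.random.default_rng(0)
        n = 60
        cols, chroms = [], []
        for j in range(200):
            p = rng.uniform(0.1, 0.9)
            col = rng.binomial(2, p, size=n).astype(float)
            kind = j % 5
            if kind == 1:   # low MAF
                col = np.zeros(n)
                col[0] = 1.0
            elif kind == 2:  # missing-heavy
                col[rng.choice(n, size=10, replace=False)] = np.nan
            elif kind == 3:  # HWE violation: no heterozygotes
                col = rng.choice([0.0, 2.0], size=n)
            chroms.append(31 if kind == 4 else 1 + j % 3)
            cols.append(col)
        dos = np.column_stack(cols)
        gm = _gm(dos)
        snp_map = make_snp_map([f"s{j}" for j in range(200)], chroms,
                               [1000 * (j + 1) for j in range(200)])
        out, out_map, rep = qc_snps(gm, snp_map, max_missing=0.10, min_maf=0.01,
                                    hwe_alpha=1e-6, chromosomes=set(range(1, 31)))

        def oracle_keep(j):
            col = dos[:, j]
            obs = col[~np.isnan(col)]
            if chroms[j] not in range(1, 31):
                return False
            if np.isnan(col).mean() >= 0.10:
                return False
            p = obs.mean() / 2
            if min(p, 1 - p) <= 0.01:
                return False
            return hwe_chisq_p(int((obs == 0).sum()), int((obs == 1).sum()),
                               int((obs == 2).sum())) > 1e-6

        expected = [f"s{j}" for j in range(200) if oracle_keep(j)]
        assert list(out_map.snp_id) == expected

    def test_hwe_tested_within_breeds(self):
        """A SNP in HWE within each breed but Wahlund-disequilibrated overall
        must survive the within-breed test."""
        rng = np.random.default_rng(1)
        a = rng.binomial(2, 0.9, size=300).astype(float)
        b = rng.binomial(2, 0.1, size=300).astype(float)
        col = np.concatenate([a, b])
        pooled_p = hwe_chisq_p(int((col == 0).sum()), int((col == 1).sum()),
                               int((col == 2).sum()))
        assert pooled_p < 1e-6  # pooled test would kill it
        gm = _gm(col[:, None], breeds=["x"] * 300 + ["y"] * 300)
        out, _, _ = qc_snps(gm, _map(1))
        assert out.n_snps == 1

    def test_qc_idempotent_on_survivors(self, small_dataset):
        gm, snp_map = small_dataset["genotypes_raw"], small_dataset["snp_map_raw"]
        gm1, rep_a = qc_animals(gm)
        gm1, map1, _ = qc_snps(gm1, snp_map)
        gm2, _ = qc_animals(gm1)
        gm2, map2, rep2 = qc_snps(gm2, map1)
        assert list(map1.snp_id) == list(map2.snp_id)
        assert list(gm1.animal_ids) == list(gm2.animal_ids)
        assert all(v == 0 for v in rep2.snp_rules.values())


class TestIntersect:
    def test_identical_maps_keep_everything(self):
        gm = _gm(np.tile([0.0, 1.0, 2.0], (4, 1)))
        out_a, out_b, common = intersect_snps(gm, _map(3), gm, _map(3))
        assert len(common) == 3

    def test_disjoint_maps_error(self):
        gm = _gm([[0.0, 1.0]])
        map_b = make_snp_map(["x0", "x1"], [1, 1], [10, 20])
        with pytest.raises(ValueError, match="empty"):
            intersect_snps(gm, _map(2), gm, map_b)

    def test_partial_overlap_matches_set_oracle(self):
        rng = np.random.default_rng(5)
        ids_a = [f"s{i}" for i in range(120)]
        ids_b = [f"s{i}" for i in range(20, 135)]  # shares s20..s119 = 100 ids
        map_a = make_snp_map(ids_a, [1] * 120, range(1, 121))
        map_b = make_snp_map(ids_b, [1] * 115, range(1, 116))
        gm_a = _gm(rng.binomial(2, 0.5, size=(3, 120)).astype(float))
        gm_b = _gm(rng.binomial(2, 0.5, size=(3, 115)).astype(float))
        out_a, out_b, common = intersect_snps(gm_a, map_a, gm_b, map_b)
        assert list(common.snp_id) == sorted(set(ids_a) & set(ids_b),
                                             key=lambda s: int(s[1:]))
        assert len(common) == 100
        assert out_a.n_snps == out_b.n_snps == 100
        # column alignment: same snp order in both outputs
        j = list(common.snp_id).index("s50")
        np.testing.assert_array_equal(out_a.dosages[:, j], gm_a.dosages[:, 50])
        np.testing.assert_array_equal(out_b.dosages[:, j], gm_b.dosages[:, 30])


class TestImpute:
    def test_half_frequency_imputes_to_one(self):
        gm = _gm([[0.0], [2.0], [np.nan]])
        out = impute_mean(gm)
        assert out.dosages[2, 0] == pytest.approx(1.0)

    def test_complete_matrix_unchanged(self):
        dos = np.array([[0.0, 1.0], [2.0, 1.0]])
        out = impute_mean(_gm(dos))
        np.testing.assert_array_equal(out.dosages, dos)

    def test_imputed_values_equal_within_breed_frequency(self):
        rng = np.random.default_rng(9)
        dos = rng.binomial(2, rng.uniform(0.2, 0.8, 30), size=(40, 30)).astype(float)
        breeds = ["x"] * 20 + ["y"] * 20
        mask = rng.random(dos.shape) < 0.10
        masked = dos.copy()
        masked[mask] = np.nan
        out = impute_mean(_gm(masked, breeds=breeds))
        for i, j in zip(*np.where(mask)):
            rows = [k for k in range(40) if breeds[k] == breeds[i] and not mask[k, j]]
            expected = masked[rows, j].mean()
            assert out.dosages[i, j] == pytest.approx(expected)
        assert not np.isnan(out.dosages).any()

    def test_fully_missing_snp_within_breed_errors(self):
        dos = np.array([[np.nan, 1.0], [np.nan, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="entirely missing"):
            impute_mean(_gm(dos, breeds=["x", "x", "y"]))


class TestPhenotypeScreening:
    RULES = {("holstein", "305dMY"): (4000, 15000), ("brown", "305dMY"): (2000, 13000)}

    def _pt(self, rows):
        return pd.DataFrame(rows, columns=["animal", "breed", "trait", "value",
                                           "farm", "year_class", "season", "parity"])

    def test_below_bound_removed_at_bound_retained(self):
        pt = self._pt([("a1", "holstein", "305dMY", 3999, "f", "y", "s", 1),
                       ("a2", "holstein", "305dMY", 4000, "f", "y", "s", 1),
                       ("a3", "holstein", "305dMY", 15000, "f", "y", "s", 1)])
        out, counts = screen_phenotypes(pt, self.RULES)
        assert list(out["animal"]) == ["a2", "a3"]
        assert counts[("holstein", "305dMY")] == 1

    def test_survivors_equal_brute_force(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1000, 16000, size=1000)
        breeds = rng.choice(["holstein", "brown"], size=1000)
        pt = self._pt([(f"a{i}", breeds[i], "305dMY", vals[i], "f", "y", "s", 1)
                       for i in range(1000)])
        out, counts = screen_phenotypes(pt, self.RULES)
        keep = [i for i in range(1000)
                if self.RULES[(breeds[i], "305dMY")][0] <= vals[i]
                <= self.RULES[(breeds[i], "305dMY")][1]]
        assert list(out["animal"]) == [f"a{i}" for i in keep]
        assert sum(counts.values()) == 1000 - len(keep)

    def test_unknown_trait_in_rules_rejected(self):
        pt = self._pt([("a1", "brown", "305dMY", 5000, "f", "y", "s", 1)])
        with pytest.raises(ValueError, match="unknown trait"):
            screen_phenotypes(pt, {("brown", "305dMY"): (0, 1e6),
                                   ("brown", "bogus"): (0, 1)})

    def test_uncovered_breed_trait_rejected(self):
        pt = self._pt([("a1", "brown", "MFP", 5, "f", "y", "s", 1)])
        with pytest.raises(ValueError, match="no screening rule"):
            screen_phenotypes(pt, self.RULES)


class TestTraitTransforms:
    @pytest.mark.parametrize("scc,scs", [(100, 3.0), (400, 5.0), (50, 2.0)])
    def test_scs_reference_points(self, scc, scs):
        assert scc_to_scs(scc) == pytest.approx(scs)

    def test_scs_at_upper_screening_bound(self):
        # 25,000 (1,000 cells/mL) maps to ~10.97, consistent with an observed
        # trait maximum of 10.95 given input rounding
        assert round(float(scc_to_scs(25000)), 2) == 10.97

    @pytest.mark.parametrize("bad", [0, -5])
    def test_nonpositive_scc_rejected(self, bad):
        with pytest.raises(ValueError):
            scc_to_scs(bad)

    def test_component_yield_from_percentage(self):
        # 305-d milk yield x fat percentage / 100
        assert genio.derive_yield(5000, 4.0) == pytest.approx(200.0)
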