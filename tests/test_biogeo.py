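import numpy as np
import pytest
from skbio.stats.distance import mantel as skbio_mantel

from ventpop import biogeo, datasets, phylo
from ventpop import mlsa_typing as mt
from ventpop import synthetic_data as sd
from ventpop.errors import UndefinedStatistic
from ventpop.seqio import LocusAlignment, StrainRecord, distance_matrix

from _oracles import haversine_km, hudson_fst
from conftest import two_pop_config


def _aln(pairs):
    ids, seqs = zip(*pairs)
    return LocusAlignment("t", ids, seqs)


class TestFst:
    def test_fixed_differences_give_one(self):
        aln = _aln([("a1", "AAAA"), ("a2", "AAAA"), ("b1", "TTTT"), ("b2", "TTTT")])
        pops = {"A": ["a1", "a2"], "B": ["b1", "b2"]}
        res = biogeo.pairwise_fst(aln, pops, "A", "B", permutations=100, seed=0)
        assert res.fst == 1.0

    def test_hand_example_matches_direct_formula(self):
        aln = _aln([("a1", "AAAAAAAA"), ("a2", "AAAAAAAT"),
                    ("b1", "TTTTAAAA"), ("b2", "TTTAAAAA")])
        pops = {"A": ["a1", "a2"], "B": ["b1", "b2"]}
        res = biogeo.pairwise_fst(aln, pops, "A", "B", permutations=10, seed=0)
        expected = hudson_fst(["AAAAAAAA", "AAAAAAAT"],
                              ["TTTTAAAA", "TTTAAAAA"])
        assert res.fst == pytest.approx(expected, abs=1e-12)

    def test_label_swap_invariance_and_seeded_p(self):
        aln = _aln([("a1", "AAAA"), ("a2", "AAAT"), ("b1", "TTTT"), ("b2", "TTTA")])
        pops = {"A": ["a1", "a2"], "B": ["b1", "b2"]}
        r1 = biogeo.pairwise_fst(aln, pops, "A", "B", permutations=200, seed=5)
        r2 = biogeo.pairwise_fst(aln, pops, "B", "A", permutations=200, seed=5)
        assert r1.fst == pytest.approx(r2.fst)
        again = biogeo.pairwise_fst(aln, pops, "A", "B", permutations=200, seed=5)
        assert again.p == r1.p

    def test_panmictic_pool_gives_small_fst(self):
        cfg = sd.SimulationConfig(
            loci=(("loc", 600),),
            regions=[sd.Region("R", [sd.Site("s", 0.0, 0.0, 12)])],
            d_between=0.0, d_within=0.02, omega_sim=1.0, rho=0.0, seed=8,
        )
        alns, _ = sd.simulate_sequences(cfg)
        ids = list(alns["loc"].ids)
        pops = {"X": ids[:6], "Y": ids[6:]}  # arbitrary split of one pool
        res = biogeo.pairwise_fst(alns["loc"], pops, "X", "Y",
                                  permutations=500, seed=1)
        assert res.fst < 0.25
        assert res.p > 0.05

    def test_undefined_when_no_between_variation(self):
        aln = _aln([("a1", "AAAA"), ("a2", "AAAA"), ("b1", "AAAA"), ("b2", "AAAA")])
        with pytest.raises(UndefinedStatistic):
            biogeo.pairwise_fst(aln, {"A": ["a1", "a2"], "B": ["b1", "b2"]},
                                "A", "B", permutations=10, seed=0)


class TestMantel:
    def _random_dm(self, rng, n, labels=None):
        a = rng.random((n, n))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0)
        return distance_matrix(d, labels or [f"s{i}" for i in range(n)])

    def test_self_correlation_is_one(self, rng):
        d = self._random_dm(rng, 6)
        res = biogeo.mantel(d, d, permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_shift_invariance(self, rng):
        d = self._random_dm(rng, 6)
        shifted = distance_matrix(
            np.where(np.eye(6, dtype=bool), 0.0, d.data + 0.5), list(d.ids)
        )
        assert biogeo.mantel(d, shifted, permutations=9, seed=0).r == \
            pytest.approx(1.0)

    def test_symmetry_in_arguments(self, rng):
        d1, d2 = self._random_dm(rng, 7), self._random_dm(rng, 7)
        assert biogeo.mantel(d1, d2, permutations=9, seed=0).r == \
            pytest.approx(biogeo.mantel(d2, d1, permutations=9, seed=0).r)

    def test_r_matches_reference_implementation(self, rng):
        d1, d2 = self._random_dm(rng, 8), self._random_dm(rng, 8)
        ours = biogeo.mantel(d1, d2, permutations=200, seed=0)
        ref_r, ref_p, _ = skbio_mantel(d1, d2, permutations=200,
                                       alternative="two-sided")
        assert ours.r == pytest.approx(float(ref_r), abs=1e-12)

    def test_distance_decay_simulation_has_strong_mantel(self):
        cfg = two_pop_config(9)
        alns, truth = sd.simulate_sequences(cfg)
        concat = mt.concatenate_loci(alns, [n for n, _ in cfg.loci])
        dgen = phylo.genetic_distance(concat, "p")
        dgeo = biogeo.geographic_distances(truth.records())
        res = biogeo.mantel(dgen, dgeo, permutations=200, seed=2)
        assert res.r > 0.9
        assert res.p < 0.01


class TestGeoEnvDistances:
    def test_same_site_distance_zero_and_haversine(self):
        recs = [StrainRecord("a", "s1", "R", 10.0, 20.0),
                StrainRecord("b", "s1", "R", 10.0, 20.0),
                StrainRecord("c", "s2", "R", 0.0, 0.0)]
        d = biogeo.geographic_distances(recs)
        assert d["a", "b"] == 0.0
        assert d["a", "c"] == pytest.approx(
            haversine_km(10.0, 20.0, 0.0, 0.0), abs=1e-9
        )

    def test_one_degree_longitude_at_equator(self):
        assert biogeo.haversine_km(0.0, 0.0, 0.0, 1.0) == \
            pytest.approx(111.19, abs=0.01)

    def test_env_distance_from_site_table(self):
        env = datasets.load_table6_env()
        recs = [StrainRecord("x", "iheya_north", "OT"),
                StrainRecord("y", "urashima", "SMT")]
        d = biogeo.env_distances(recs, env, "ph")
        assert d["x", "y"] == pytest.approx(2.0)  # pH 5.0 vs 3.0

    def test_missing_variable_raises(self):
        env = datasets.load_table6_env()
        recs = [StrainRecord("x", "iheya_north", "OT"),
                StrainRecord("y", "urashima", "SMT")]
        with pytest.raises(UndefinedStatistic):
            biogeo.env_distances(recs, env, "h2s_mmol_kg")  # NA for iheya


class TestRegressions:
    def test_distance_decay_exact_line(self):
        n = 5
        geo = np.zeros((n, n))
        gen = np.zeros((n, n))
        x = [0.0, 1.0, 2.0, 3.0, 4.0]
        for i in range(n):
            for j in range(n):
                geo[i, j] = abs(x[i] - x[j])
                gen[i, j] = 0.01 * geo[i, j]
        res = biogeo.distance_decay(
            distance_matrix(gen, list("abcde")), distance_matrix(geo, list("abcde"))
        )
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.01)

    def test_end_member_noiseless_line_exact(self):
        mix = sd.simulate_mixing_series(600.0, 54.0, fractions=np.linspace(0, 1, 6))
        intercept, se = biogeo.end_member(mix)
        assert intercept == pytest.approx(600.0, abs=1e-9)

    def test_end_member_two_points_interpolate(self):
        mix = sd.simulate_mixing_series(100.0, 10.0, fractions=[0.2, 0.8])
        intercept, _ = biogeo.end_member(mix)
        assert intercept == pytest.approx(100.0, abs=1e-9)

    def test_end_member_noisy_within_three_se(self):
        mix = sd.simulate_mixing_series(
            600.0, 54.0, fractions=np.linspace(0, 1, 20), noise_sd=5.0, seed=3
        )
        intercept, se = biogeo.end_member(mix)
        assert abs(intercept - 600.0) <= 3 * se

    def test_degenerate_design_raises(self):
        mix = sd.simulate_mixing_series(100.0, 10.0, fractions=[0.5, 0.5, 0.5])
        with pytest.raises(UndefinedStatistic):
            biogeo.end_member(mix)
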