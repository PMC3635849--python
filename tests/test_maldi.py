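import numpy as np
import pytest

from ventpop import maldi, phylo
from ventpop import synthetic_data as sd
from ventpop.errors import NotComputable
from ventpop.seqio import PeakList

from conftest import two_pop_config


def _pl(strain, rep, peaks):
    mz, inten = zip(*peaks)
    return PeakList(strain, rep, np.array(mz, float), np.array(inten, float))


class TestMergeReplicates:
    def test_identical_triplicates_unchanged(self):
        peaks = [(3000.0, 5000.0), (9678.0, 50000.0)]
        merged = maldi.merge_replicates([_pl("A", str(r), peaks) for r in range(3)])
        np.testing.assert_allclose(merged.mz, [3000, 9678])
        np.testing.assert_allclose(merged.intensity, [5000, 50000])
        assert list(merged.support) == [3, 3]

    def test_nearby_peaks_average(self):
        reps = [_pl("A", "1", [(9676.0, 10.0)]), _pl("A", "2", [(9678.0, 20.0)]),
                _pl("A", "3", [(9680.0, 30.0)])]
        merged = maldi.merge_replicates(reps, mz_tol=5.0)
        assert merged.mz.tolist() == [9678.0]
        assert merged.intensity.tolist() == [20.0]

    def test_singleton_peaks_kept_but_flagged(self):
        reps = [_pl("A", "1", [(5000.0, 10.0), (9678.0, 50.0)]),
                _pl("A", "2", [(9678.0, 50.0)])]
        merged = maldi.merge_replicates(reps)
        assert merged.support.tolist() == [1, 2]

    def test_empty_and_mixed_strains_rejected(self):
        with pytest.raises(NotComputable):
            maldi.merge_replicates([])
        with pytest.raises(NotComputable):
            maldi.merge_replicates([_pl("A", "1", [(5000, 1)]),
                                    _pl("B", "1", [(5000, 1)])])


class TestFilterAndTop:
    def test_low_mass_cut(self):
        pl = _pl("A", "1", [(2050.0, 9.0), (9678.0, 50.0)])
        kept = maldi.filter_noise(pl)
        assert kept.mz.tolist() == [9678.0]

    def test_empty_list_passes_through(self):
        pl = PeakList("A", "1", np.empty(0), np.empty(0))
        assert len(maldi.filter_noise(pl)) == 0

    def test_top_fifteen_selection_and_normalization(self, rng):
        mz = 3000 + 100 * np.arange(20.0)
        inten = 1000 + 10 * rng.permutation(20).astype(float)
        fp = maldi.top_peaks(_pl("A", "1", list(zip(mz, inten))), n=15)
        assert len(fp.mz) == 15
        assert fp.rel_intensity.max() == 1.0
        assert not fp.short

    def test_tie_at_cutoff_keeps_lower_mz(self):
        peaks = [(3000.0 + i, 100.0) for i in range(3)]
        fp = maldi.top_peaks(_pl("A", "1", peaks), n=2)
        assert fp.mz.tolist() == [3000.0, 3001.0]
        assert not fp.short  # enough peaks were available


class TestBinning:
    def _fps(self, spec):
        return [
            maldi.Fingerprint(s, np.array(mzs, float), np.ones(len(mzs)))
            for s, mzs in spec
        ]

    def test_within_tolerance_shares_a_bin(self):
        bm = maldi.bin_peaks(self._fps([("A", [9671.0]), ("B", [9684.0])]), tol=14)
        assert bm.matrix.shape == (2, 1)
        assert bm.matrix.all()

    def test_beyond_tolerance_splits(self):
        bm = maldi.bin_peaks(self._fps([("A", [9671.0]), ("B", [9690.0])]), tol=14)
        assert bm.matrix.shape == (2, 2)

    def test_every_peak_lands_in_exactly_one_bin(self, rng):
        spec = [(f"s{i}", sorted(rng.uniform(2200, 13800, size=8))) for i in range(6)]
        bm = maldi.bin_peaks(self._fps(spec), tol=14)
        # conservation: per-strain peak count equals per-strain bin memberships
        # only when no two of a strain's peaks share a bin; totals always match
        assert bm.matrix.sum() <= 6 * 8
        assert len(bm.centers) == bm.matrix.shape[1]

    def test_binning_order_invariance(self):
        fps = self._fps([("A", [5000.0, 9678.0]), ("B", [9680.0])])
        bm1 = maldi.bin_peaks(fps, tol=14)
        bm2 = maldi.bin_peaks(fps[::-1], tol=14)
        assert np.allclose(sorted(bm1.centers), sorted(bm2.centers))


class TestWard:
    def test_identical_rows_merge_at_height_zero(self):
        bm = maldi.BinMatrix(("A", "B", "C"), np.array([1.0, 2.0]),
                             np.array([[1, 0], [1, 0], [0, 1]], dtype=np.uint8),
                             np.zeros(2, bool), 14.0)
        dend = maldi.ward_cluster(bm)
        assert dend.linkage[0, 2] == 0.0  # first merge joins the identical pair
        assert np.all(np.diff(dend.linkage[:, 2]) >= 0)  # monotone heights

    def test_disjoint_peak_sets_cut_cleanly(self):
        rows = np.array([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]],
                        dtype=np.uint8)
        bm = maldi.BinMatrix(("A", "B", "C", "D"), np.arange(4.0), rows,
                             np.zeros(4, bool), 14.0)
        part = maldi.ward_cluster(bm).cut(2)
        assert part["A"] == part["B"] != part["C"] == part["D"]


class TestEndToEnd:
    def test_pipeline_strain_order_invariance(self):
        cfg = two_pop_config(13)
        _, truth = sd.simulate_sequences(cfg)
        peaks = sd.simulate_spectra(cfg, truth)
        _, _, dend1 = maldi.fingerprint_pipeline(peaks)
        _, _, dend2 = maldi.fingerprint_pipeline(peaks[::-1])
        assert dend1.cut(2) == dend2.cut(2)

    def test_universal_peak_bin_covers_all_strains(self, default_dataset):
        cfg, _, truth, peaks = default_dataset
        _, bm, _ = maldi.fingerprint_pipeline(peaks)
        col = int(np.argmin(np.abs(bm.centers - 9678.0)))
        assert abs(bm.centers[col] - 9678.0) < 14.0
        assert bm.matrix[:, col].all()

    def test_two_regions_cluster_perfectly(self, default_dataset):
        cfg, _, truth, peaks = default_dataset
        _, bm, dend = maldi.fingerprint_pipeline(peaks)
        regions = {s: truth.region_of[s] for s in bm.strains}
        assert phylo.concordance(dend.cut(2), regions, k=2) == 1.0
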