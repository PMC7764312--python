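import numpy as np
import pytest

from sauseg.io_schema import LabelSchema, LabelVolume, SchemaEntry
from sauseg.metrics import (PairedVolumes, ScanSeries, StructureMask, assd,
                            boundary, cv_intra_session, cv_total, dice,
                            evaluate_report, volume_cc)


def mask(arr, spacing=(1.0, 1.0, 1.0)):
    return StructureMask(np.asarray(arr, dtype=bool), spacing)


def brute_force_boundary(m):
    """Independent 6-connectivity boundary enumeration."""
    data = m.data
    out = []
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            for k in range(data.shape[2]):
                if not data[i, j, k]:
                    continue
                edge = False
                for di, dj, dk in [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
                    ni, nj, nk = i + di, j + dj, k + dk
                    if not (0 <= ni < data.shape[0] and 0 <= nj < data.shape[1]
                            and 0 <= nk < data.shape[2]):
                        edge = True
                        break
                    if not data[ni, nj, nk]:
                        edge = True
                        break
                if edge:
                    out.append((i, j, k))
    return np.array(out)


def brute_force_assd(a, b):
    """All-pairs Euclidean distances between boundary voxel centers."""
    spacing = np.asarray(a.spacing)
    pa = brute_force_boundary(a) * spacing
    pb = brute_force_boundary(b) * spacing
    d_ab = np.array([np.sqrt(((pb - p) ** 2).sum(axis=1)).min() for p in pa])
    d_ba = np.array([np.sqrt(((pa - p) ** 2).sum(axis=1)).min() for p in pb])
    return (d_ab.sum() + d_ba.sum()) / (len(pa) + len(pb))


class TestDice:
    def test_identical_masks(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        a[2:5, 2:5, 2:5] = True
        assert dice(mask(a), mask(a)) == 1.0

    def test_disjoint(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros((8, 8, 8), dtype=bool)
        a[0, 0, 0] = True
        b[7, 7, 7] = True
        assert dice(mask(a), mask(b)) == 0.0

    def test_half_overlap(self):
        # |a| = |b| = 8, 4 shared -> 2*4/16 = 0.5
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros((8, 8, 8), dtype=bool)
        a[0, 0, :8] = True
        b[0, 0, 4:8] = True
        b[0, 1, :4] = True
        assert dice(mask(a), mask(b)) == 0.5

    def test_both_empty_is_one(self):
        z = np.zeros((4, 4, 4), dtype=bool)
        assert dice(mask(z), mask(z)) == 1.0

    def test_symmetric(self, rng):
        a = mask(rng.random((8, 8, 8)) > 0.5)
        b = mask(rng.random((8, 8, 8)) > 0.5)
        assert dice(a, b) == dice(b, a)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            dice(mask(np.zeros((4, 4, 4))), mask(np.zeros((5, 5, 5))))


class TestBoundary:
    def test_single_voxel(self):
        a = np.zeros((5, 5, 5), dtype=bool)
        a[2, 2, 2] = True
        pts = boundary(mask(a))
        np.testing.assert_array_equal(pts, [[2, 2, 2]])

    def test_cube_3_has_26_boundary_voxels(self):
        a = np.zeros((7, 7, 7), dtype=bool)
        a[2:5, 2:5, 2:5] = True
        assert len(boundary(mask(a))) == 26

    def test_boundary_subset_of_mask(self, rng):
        a = rng.random((8, 8, 8)) > 0.4
        if not a.any():
            a[0, 0, 0] = True
        for i, j, k in boundary(mask(a)):
            assert a[i, j, k]

    def test_empty_mask_error(self):
        with pytest.raises(ValueError):
            boundary(mask(np.zeros((4, 4, 4))))

    def test_matches_enumeration_oracle(self, rng):
        a = mask(rng.random((10, 10, 10)) > 0.5)
        got = {tuple(p) for p in boundary(a)}
        want = {tuple(p) for p in brute_force_boundary(a)}
        assert got == want


class TestASSD:
    def test_identical_masks_zero(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        a[2:6, 2:6, 2:6] = True
        assert assd(mask(a), mask(a)) == 0.0

    def test_two_single_voxels_three_apart(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros((8, 8, 8), dtype=bool)
        a[2, 2, 2] = True
        b[5, 2, 2] = True
        assert assd(mask(a), mask(b)) == pytest.approx(3.0, abs=1e-12)

    def test_spacing_in_mm(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        b = np.zeros((8, 8, 8), dtype=bool)
        a[2, 2, 2] = True
        b[4, 2, 2] = True
        assert assd(mask(a, (1.5, 1.0, 1.0)), mask(b, (1.5, 1.0, 1.0))) == \
            pytest.approx(3.0, abs=1e-12)

    def test_symmetric(self, rng):
        a = mask(rng.random((8, 8, 8)) > 0.6)
        b = mask(rng.random((8, 8, 8)) > 0.6)
        assert assd(a, b) == pytest.approx(assd(b, a), abs=1e-12)

    def test_empty_mask_error(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = a.copy()
        b[1, 1, 1] = True
        with pytest.raises(ValueError):
            assd(mask(a), mask(b))

    def test_matches_brute_force_on_50_random_pairs(self):
        rng = np.random.default_rng(42)
        for trial in range(50):
            shape = tuple(rng.integers(5, 17, size=3))
            a = rng.random(shape) > rng.uniform(0.4, 0.8)
            b = rng.random(shape) > rng.uniform(0.4, 0.8)
            if not a.any():
                a[0, 0, 0] = True
            if not b.any():
                b[tuple(s - 1 for s in shape)] = True
            sp = tuple(rng.choice([1.0, 1.0, 1.3]) for _ in range(3))
            ma, mb = mask(a, sp), mask(b, sp)
            assert assd(ma, mb) == pytest.approx(brute_force_assd(ma, mb),
                                                 abs=1e-9)


class TestVolumeCC:
    def test_isotropic(self):
        a = np.zeros((10, 10, 10), dtype=bool)
        a.reshape(-1)[:1000] = True
        assert volume_cc(mask(a)) == pytest.approx(1.0)

    def test_empty(self):
        assert volume_cc(mask(np.zeros((4, 4, 4)))) == 0.0

    def test_anisotropic(self):
        a = np.ones((10, 10, 10), dtype=bool)
        assert volume_cc(mask(a, (1.0, 1.0, 1.2))) == pytest.approx(1.2)


class TestCVIntraSession:
    def test_identical_pairs_zero(self):
        assert cv_intra_session(PairedVolumes([(5.0, 5.0), (7.0, 7.0)])) == 0.0

    def test_hand_computed_single_pair(self):
        # (100, 102): sigma = 1, mu = 101 -> 0.9901%
        got = cv_intra_session(PairedVolumes([(100.0, 102.0)]))
        assert got == pytest.approx(0.9901, abs=1e-4)

    def test_hand_computed_two_pairs(self):
        # mean of 0.9901% and 1.0101% = 1.0001%
        got = cv_intra_session(PairedVolumes([(100.0, 102.0), (200.0, 196.0)]))
        assert got == pytest.approx(1.0001, abs=1e-4)

    def test_scale_invariant(self):
        pv = PairedVolumes([(100.0, 102.0), (50.0, 51.0)])
        scaled = PairedVolumes([(300.0, 306.0), (150.0, 153.0)])
        assert cv_intra_session(pv) == pytest.approx(cv_intra_session(scaled))

    def test_zero_mean_error(self):
        with pytest.raises(ValueError):
            cv_intra_session(PairedVolumes([(0.0, 0.0)]))


class TestCVTotal:
    def test_constant_series_zero(self):
        assert cv_total(ScanSeries([4.0, 4.0, 4.0])) == 0.0

    def test_hand_computed_three_scans(self):
        # (10, 12, 14): sigma = sqrt(8/3) = 1.63299, CVt = 13.608%
        assert cv_total(ScanSeries([10.0, 12.0, 14.0])) == \
            pytest.approx(13.608, abs=1e-3)

    def test_hand_computed_two_scans(self):
        # (1, 3): sigma = 1, mu = 2 -> 50%
        assert cv_total(ScanSeries([1.0, 3.0])) == pytest.approx(50.0, abs=1e-9)

    def test_scale_invariant(self):
        assert cv_total(ScanSeries([10.0, 12.0, 14.0])) == \
            pytest.approx(cv_total(ScanSeries([30.0, 36.0, 42.0])))

    def test_minimum_length(self):
        with pytest.raises(ValueError):
            ScanSeries([1.0])


class TestEvaluateReport:
    @pytest.fixture
    def schema(self):
        return LabelSchema([SchemaEntry(0, "background"), SchemaEntry(1, "a"),
                            SchemaEntry(2, "b")])

    def test_perfect_prediction(self, schema, rng):
        data = rng.integers(0, 3, size=(8, 8, 8)).astype(np.int32)
        lv = LabelVolume(data, schema)
        table = evaluate_report(lv, lv)
        rows = table[table.label > 0]
        assert (rows.dice == 1.0).all()
        assert (rows.assd_mm == 0.0).all()

    def test_summary_is_unweighted_mean(self, schema, rng):
        pred = LabelVolume(rng.integers(0, 3, (8, 8, 8)).astype(np.int32), schema)
        truth = LabelVolume(rng.integers(0, 3, (8, 8, 8)).astype(np.int32), schema)
        table = evaluate_report(pred, truth)
        rows = table[table.label > 0]
        summary = table[table.label == -1].iloc[0]
        assert summary.dice == pytest.approx(rows.dice.mean())

    def test_rows_match_independent_recomputation(self, schema, rng):
        pred = LabelVolume(rng.integers(0, 3, (10, 10, 10)).astype(np.int32), schema)
        truth = LabelVolume(rng.integers(0, 3, (10, 10, 10)).astype(np.int32), schema)
        table = evaluate_report(pred, truth)
        for lid in (1, 2):
            row = table[table.label == lid].iloc[0]
            mp = StructureMask.from_labels(pred, lid)
            mt = StructureMask.from_labels(truth, lid)
            assert row.dice == pytest.approx(dice(mp, mt))
            assert row.assd_mm == pytest.approx(assd(mp, mt))
            assert row.volume_truth_cc == pytest.approx(volume_cc(mt))

    def test_absent_structure_flagged(self, schema):
        pred = LabelVolume(np.zeros((4, 4, 4), dtype=np.int32), schema)
        tdata = np.zeros((4, 4, 4), dtype=np.int32)
        tdata[1, 1, 1] = 1
        truth = LabelVolume(tdata, schema)
        table = evaluate_report(pred, truth)
        row1 = table[table.label == 1].iloc[0]
        assert row1.dice == 0.0 and row1.flag == "absent_in_one"
        row2 = table[table.label == 2].iloc[0]
        assert row2.dice == 1.0 and np.isnan(row2.assd_mm)

    def test_grid_mismatch(self, schema):
        a = LabelVolume(np.zeros((4, 4, 4), dtype=np.int32), schema)
        b = LabelVolume(np.zeros((5, 5, 5), dtype=np.int32), schema)
        with pytest.raises(ValueError):
            evaluate_report(a, b)

    def test_relabel_invariance(self, schema, rng):
        """Dice/ASSD depend only on the masks, not on which id names them."""
        data_a = (rng.random((8, 8, 8)) > 0.5).astype(np.int32)
        data_b = (rng.random((8, 8, 8)) > 0.5).astype(np.int32)
        lv_a1 = LabelVolume(data_a, schema)
        lv_b1 = LabelVolume(data_b, schema)
        lv_a2 = LabelVolume(data_a * 2, schema)
        lv_b2 = LabelVolume(data_b * 2, schema)
        d1 = dice(StructureMask.from_labels(lv_a1, 1),
                  StructureMask.from_labels(lv_b1, 1))
        d2 = dice(StructureMask.from_labels(lv_a2, 2),
                  StructureMask.from_labels(lv_b2, 2))
        assert d1 == d2
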