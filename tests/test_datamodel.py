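"""Cohort data model, TSV round trips, z-scoring and site encoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stfingerprint as sf
from stfingerprint.datamodel import CohortValidationError, encode_site_name


def _cohort(matrices, sites=None, labels=None, scores=None):
    sites = sites or ["A"] * len(matrices)
    labels = labels if labels is not None else [0] * len(matrices)
    subjects = [
        sf.SubjectRecord(f"s{i}", m, labels[i], sites[i],
                         symptom_scores=scores[i] if scores else {})
        for i, m in enumerate(matrices)]
    nc = matrices[0].shape[0]
    return sf.Cohort(subjects, [f"r{j}" for j in range(nc)],
                     sorted(set(sites)))


class TestCohortInvariants:
    def test_shape_bookkeeping(self):
        rng = np.random.default_rng(0)
        c = _cohort([rng.normal(size=(4, 10)) for _ in range(3)])
        assert c.n_regions == 4 and len(c) == 3

    def test_inconsistent_region_count_rejected(self):
        rng = np.random.default_rng(0)
        mats = [rng.normal(size=(4, 10)), rng.normal(size=(5, 10)),
                rng.normal(size=(4, 10))]
        with pytest.raises(CohortValidationError, match="s1"):
            _cohort(mats)

    def test_duplicate_ids_rejected(self):
        rng = np.random.default_rng(0)
        subs = [sf.SubjectRecord("same", rng.normal(size=(2, 12)), 0, "A")
                for _ in range(2)]
        with pytest.raises(CohortValidationError, match="duplicate"):
            sf.Cohort(subs, ["r0", "r1"], ["A"])

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(CohortValidationError, match="timepoints"):
            sf.SubjectRecord("s", np.zeros((3, 4)), 0, "A")


class TestRoundTrip:
    def test_save_load_bit_exact(self, tmp_path):
        rng = np.random.default_rng(42)
        scores = [{"rrb": 3.25, "social": -0.125}, {}, {"rrb": 0.7071067811865476}]
        c = _cohort([rng.normal(size=(4, 10)) * 10 ** rng.integers(-3, 4)
                     for _ in range(3)],
                    sites=["A", "B", "A"], labels=[0, 1, 0], scores=scores)
        c.subjects[0].mean_fd = 0.12345678901234567
        manifest = sf.save_cohort(c, tmp_path)
        back = sf.load_cohort(manifest)
        assert [s.subject_id for s in back] == [s.subject_id for s in c]
        for a, b in zip(c, back):
            np.testing.assert_array_equal(a.timeseries, b.timeseries)
            assert a.symptom_scores == b.symptom_scores
            assert a.mean_fd == b.mean_fd
            assert (a.class_label, a.site) == (b.class_label, b.site)
        assert back.region_names == c.region_names

    def test_generator_output_round_trips(self, tmp_path):
        cfg = sf.SynthConfig(n_class0=6, n_class1=3, n_regions=5,
                             planted_regions=(0,), nt_range=(16, 20),
                             n_sites=2, seed=5)
        c = sf.generate_cohort(cfg)
        back = sf.load_cohort(sf.save_cohort(c, tmp_path))
        for a, b in zip(c, back):
            np.testing.assert_array_equal(a.timeseries, b.timeseries)

    def test_missing_file_names_subject(self, tmp_path):
        rng = np.random.default_rng(0)
        c = _cohort([rng.normal(size=(2, 10))])
        manifest = sf.save_cohort(c, tmp_path)
        (tmp_path / "timeseries" / "s0.tsv").unlink()
        with pytest.raises(FileNotFoundError, match="s0"):
            sf.load_cohort(manifest)

    def test_non_numeric_cell_names_file(self, tmp_path):
        rng = np.random.default_rng(0)
        c = _cohort([rng.normal(size=(2, 10))])
        manifest = sf.save_cohort(c, tmp_path)
        p = tmp_path / "timeseries" / "s0.tsv"
        p.write_text(p.read_text().replace(
            p.read_text().split("\t")[1], "oops", 1))
        with pytest.raises(CohortValidationError, match="s0.tsv"):
            sf.load_cohort(manifest)


class TestZScore:
    def test_row_moments(self):
        c = _cohort([np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])[:, :].repeat(3, axis=1)])
        z = sf.zscore_normalize(c)
        ts = z.subjects[0].timeseries
        assert abs(ts[0].mean()) < 1e-12 and abs(ts[0].std() - 1) < 1e-12
        np.testing.assert_array_equal(ts[1], 0.0)  # constant row -> zeros

    def test_large_matrix_moments(self):
        rng = np.random.default_rng(3)
        c = _cohort([rng.normal(2.0, 7.0, size=(246, 180))])
        ts = sf.zscore_normalize(c).subjects[0].timeseries
        assert np.abs(ts.mean(axis=1)).max() < 1e-10
        assert np.abs(ts.std(axis=1) - 1).max() < 1e-10

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        c = _cohort([rng.normal(size=(6, 40))])
        once = sf.zscore_normalize(c)
        twice = sf.zscore_normalize(once)
        np.testing.assert_allclose(twice.subjects[0].timeseries,
                                   once.subjects[0].timeseries, atol=1e-8)

    def test_non_finite_rejected(self):
        m = np.zeros((2, 10))
        m[0, 0] = np.nan
        with pytest.raises(CohortValidationError, match="non-finite"):
            sf.zscore_normalize(_cohort([m]))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_moments_property(self, seed):
        rng = np.random.default_rng(seed)
        ts = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 10),
                        size=(3, 24))
        z = sf.zscore_normalize(_cohort([ts])).subjects[0].timeseries
        assert np.abs(z.mean(axis=1)).max() < 1e-10
        assert np.abs(z.std(axis=1) - 1).max() < 1e-8


class TestSiteEncoding:
    def test_one_hot_rows(self):
        c = _cohort([np.zeros((2, 10))] * 3, sites=["A", "B", "A"])
        enc = sf.encode_sites(c, ["A", "B"])
        np.testing.assert_array_equal(
            enc.matrix, [[1, 0], [0, 1], [1, 0]])

    def test_unseen_site_all_zero(self):
        c = _cohort([np.zeros((2, 10))], sites=["C"])
        enc = sf.encode_sites(c, ["A", "B"])
        np.testing.assert_array_equal(enc.matrix, [[0, 0]])
        np.testing.assert_array_equal(encode_site_name("C", ["A", "B"]),
                                      [0, 0])

    def test_duplicate_vocabulary_rejected(self):
        c = _cohort([np.zeros((2, 10))])
        with pytest.raises(CohortValidationError, match="duplicate"):
            sf.encode_sites(c, ["A", "A"])

    def test_multisite_count_cross_check(self):
        rng = np.random.default_rng(9)
        vocab = [f"site{i:02d}" for i in range(20)]
        sites = [vocab[i] for i in rng.integers(0, 20, size=120)]
        c = _cohort([np.zeros((2, 10))] * 120, sites=sites)
        enc = sf.encode_sites(c, vocab)
        np.testing.assert_array_equal(enc.matrix.sum(axis=1), 1)
        for j, name in enumerate(vocab):
            assert enc.matrix[:, j].sum() == sites.count(name)
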