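import numpy as np
import pandas as pd
import pytest

from megcoh import SubjectRecording
from megcoh.coherence import (
    CoherenceMatrix,
    CohortCoherence,
    WelchParams,
    broadband_coherence,
    cohort_coherence,
    connectivity_stats,
    degree_of_connectivity,
    epoch_signal,
    hemispheric_group_tests,
    ms_coherence,
    pair_deltas,
    pairwise_matrix,
    partition_rois,
)
from megcoh.synth import DEFAULT_ROI_LABELS, canonical_pairs

from .oracles import coherence_oracle


def _recording(n_seconds, fs=200.0, seed=0, n_roi=10):
    rng = np.random.default_rng(seed)
    return SubjectRecording(
        subject_id="s",
        class_label="HC",
        fs=fs,
        data=rng.standard_normal((n_roi, int(fs * n_seconds))),
        roi_labels=DEFAULT_ROI_LABELS[:n_roi],
    )


class TestEpoching:
    @pytest.mark.parametrize(
        "duration,epoch_len,expected",
        [(180.0, 1.0, 180), (10.0, 10.0, 1), (5.5, 1.0, 5), (25.0, 10.0, 2)],
    )
    def test_epoch_counts(self, duration, epoch_len, expected):
        rec = _recording(duration)
        epochs = epoch_signal(rec, epoch_len)
        assert len(epochs) == expected
        assert all(e.shape == (10, int(200 * epoch_len)) for e in epochs)

    def test_trailing_samples_dropped(self):
        epochs = epoch_signal(_recording(5.5), 1.0)
        assert sum(e.shape[1] for e in epochs) == 1000  # 100 of 1100 dropped

    def test_epoch_longer_than_recording(self):
        with pytest.raises(ValueError):
            epoch_signal(_recording(5.0), 10.0)


class TestMsCoherence:
    def test_self_coherence_is_one(self, rng):
        x = rng.standard_normal(200)
        spec = ms_coherence(x, x, 200.0)
        assert spec.defined
        assert np.allclose(spec.values, 1.0, atol=1e-9)

    def test_matches_brute_force_periodogram_oracle(self, rng):
        """Welch-averaged MS-COH equals the direct evaluation of
        |Pxy|^2/(Pxx Pyy) on the same segment layout to 1e-10."""
        est = WelchParams()
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.standard_normal(200)
            y = 0.5 * x + r.standard_normal(200)
            spec = ms_coherence(x, y, 200.0, est)
            freqs, expected = coherence_oracle(x, y, 200.0, 100, 50)
            assert np.array_equal(freqs, spec.freqs)
            assert np.max(np.abs(spec.values - expected)) < 1e-10

    def test_independent_noise_bias_floor(self):
        """For independent inputs the estimator mean approaches 1/L with L
        averaged segments (Monte-Carlo oracle)."""
        est = WelchParams(seg_seconds=1.0, overlap=0.0)
        n_segments = 10
        rng = np.random.default_rng(99)
        means = []
        for _ in range(300):
            x = rng.standard_normal(200 * n_segments)
            y = rng.standard_normal(200 * n_segments)
            spec = ms_coherence(x, y, 200.0, est)
            means.append(spec.values[1:-1].mean())
        assert np.mean(means) == pytest.approx(1.0 / n_segments, rel=0.2)

    def test_delay_invariance_at_shared_tone(self):
        """A shared sinusoid stays highly coherent regardless of a pure delay."""
        rng = np.random.default_rng(5)
        fs, n, f0 = 200.0, 2000, 40.0
        t = np.arange(n) / fs
        tone = np.sin(2 * np.pi * f0 * t)
        x = tone + 0.3 * rng.standard_normal(n)
        highs = []
        for delay in (0, 7):
            y = np.roll(tone, delay) + 0.3 * rng.standard_normal(n)
            spec = ms_coherence(x, y, fs)
            k = np.argmin(np.abs(spec.freqs - f0))
            highs.append(spec.values[k])
        assert min(highs) > 0.8
        assert abs(highs[0] - highs[1]) < 0.1

    def test_zero_variance_flagged_not_nan_propagated(self):
        x = np.zeros(200)
        y = np.random.default_rng(0).standard_normal(200)
        spec = ms_coherence(x, y, 200.0)
        assert not spec.defined
        assert np.isnan(broadband_coherence(spec))  # flagged, no exception

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            ms_coherence(np.ones(80), np.ones(80), 200.0)


class TestBroadband:
    def test_constant_spectrum(self):
        from megcoh.coherence import CoherenceSpectrum

        spec = CoherenceSpectrum(freqs=np.arange(0, 101, 2.0), values=np.full(51, 0.6))
        assert broadband_coherence(spec, (0.5, 80.0)) == pytest.approx(0.6)

    def test_single_bin_band(self):
        from megcoh.coherence import CoherenceSpectrum

        vals = np.linspace(0, 1, 51)
        spec = CoherenceSpectrum(freqs=np.arange(0, 101, 2.0), values=vals)
        assert broadband_coherence(spec, (39.9, 40.1)) == pytest.approx(vals[20])

    def test_linear_ramp_band_mean(self):
        from megcoh.coherence import CoherenceSpectrum

        freqs = np.arange(0, 101, 2.0)
        vals = freqs / 100.0
        spec = CoherenceSpectrum(freqs=freqs, values=vals)
        mask = (freqs >= 0.5) & (freqs <= 80.0)
        assert broadband_coherence(spec, (0.5, 80.0)) == pytest.approx(
            vals[mask].mean()
        )

    def test_empty_band_rejected(self):
        from megcoh.coherence import CoherenceSpectrum

        spec = CoherenceSpectrum(freqs=np.arange(0, 101, 2.0), values=np.zeros(51))
        with pytest.raises(ValueError):
            broadband_coherence(spec, (0.6, 1.2))


class TestPairwiseMatrix:
    def test_identical_rows_give_all_ones(self, rng):
        row = rng.standard_normal(200)
        mat = pairwise_matrix(np.tile(row, (10, 1)), 200.0, roi_labels=DEFAULT_ROI_LABELS)
        assert np.allclose(mat.matrix, 1.0, atol=1e-9)

    def test_symmetric_unit_diagonal_in_range(self, rng):
        epoch = rng.standard_normal((10, 200))
        mat = pairwise_matrix(epoch, 200.0, roi_labels=DEFAULT_ROI_LABELS)
        assert np.array_equal(mat.matrix, mat.matrix.T)
        assert np.allclose(np.diag(mat.matrix), 1.0)
        off = mat.matrix[~np.eye(10, dtype=bool)]
        assert np.all((off >= 0.0) & (off <= 1.0))

    def test_independent_rows_near_bias_floor(self, rng):
        # three 50%-overlapping Hann segments -> sizeable but bounded floor
        vals = []
        for _ in range(30):
            epoch = rng.standard_normal((10, 200))
            mat = pairwise_matrix(epoch, 200.0, roi_labels=DEFAULT_ROI_LABELS)
            vals.append(mat.matrix[np.triu_indices(10, 1)].mean())
        assert 0.2 < np.mean(vals) < 0.65

    def test_matches_single_pair_estimator(self, rng):
        epoch = rng.standard_normal((10, 200))
        mat = pairwise_matrix(epoch, 200.0, band=(0.5, 80.0), roi_labels=DEFAULT_ROI_LABELS)
        spec = ms_coherence(epoch[2], epoch[7], 200.0)
        expected = broadband_coherence(spec, (0.5, 80.0))
        assert mat.matrix[2, 7] == pytest.approx(expected, abs=1e-12)


class TestDegree:
    def _mat(self, m):
        return CoherenceMatrix(epoch_index=0, matrix=m, roi_labels=DEFAULT_ROI_LABELS)

    def test_all_ones_gives_nine(self):
        assert degree_of_connectivity(self._mat(np.ones((10, 10))), "LF") == 9.0

    def test_identity_gives_zero(self):
        assert degree_of_connectivity(self._mat(np.eye(10)), "RO") == 0.0

    def test_constant_row(self):
        m = np.full((10, 10), 0.3)
        np.fill_diagonal(m, 1.0)
        assert degree_of_connectivity(self._mat(m), "LT") == pytest.approx(2.7)

    def test_unknown_roi(self):
        with pytest.raises(KeyError):
            degree_of_connectivity(self._mat(np.eye(10)), "XX")


class TestCohortStats:
    def test_epoch_counts_and_stat_ordering(self, small_cohort):
        coh = cohort_coherence(small_cohort, epoch_len=1.0)
        assert coh.n_pair_evaluations == 6 * 20 * 45  # subjects x epochs x pairs
        table = connectivity_stats(coh)
        assert set(table["n_epochs"]) == {3 * 20}
        assert (table["min"] <= table["mean"]).all()
        assert (table["mean"] <= table["max"]).all()
        assert (table["sd"] >= 0).all()
        deg = coh.degree_series("LF", "HC")
        assert deg.shape == (60,)
        assert np.all((deg >= 0) & (deg <= 9))

    def test_single_epoch_degenerate_stats(self, small_cohort):
        sub = type(small_cohort)(
            subjects=[s for s in small_cohort.subjects],
            roi_labels=small_cohort.roi_labels,
        )
        coh = cohort_coherence(sub, epoch_len=20.0)  # one epoch per subject
        # restrict to a single subject per class for the degenerate case
        one = {k: v[:1] for k, v in coh.matrices.items()}
        coh_one = CohortCoherence(
            roi_labels=coh.roi_labels,
            matrices=one,
            subject_ids={k: v[:1] for k, v in coh.subject_ids.items()},
            band=coh.band,
            n_pair_evaluations=90,
        )
        table = connectivity_stats(coh_one)
        assert (table["mean"] == table["max"]).all()
        assert (table["mean"] == table["min"]).all()
        assert (table["sd"] == 0).all()


def _stats_frame(means):
    return pd.DataFrame(
        {"mean": [means[r] for r in DEFAULT_ROI_LABELS]}, index=DEFAULT_ROI_LABELS
    )


def _delta_frame(positive_pairs, magnitude=0.05):
    rows = []
    for a, b in canonical_pairs(DEFAULT_ROI_LABELS):
        d = magnitude if (a, b) in positive_pairs else -0.01
        rows.append({"pair": f"{a}-{b}", "roi_a": a, "roi_b": b, "delta": d})
    return pd.DataFrame(rows)


class TestPartition:
    def test_balance_demotes_lowest_degree_delta(self):
        """Three positive pairs touch six ROIs; the lowest-delta member (LO)
        is demoted so both groups hold five ROIs."""
        hc = _stats_frame({r: 3.0 for r in DEFAULT_ROI_LABELS})
        mci_means = {r: 2.95 for r in DEFAULT_ROI_LABELS}
        for r in ("LF", "LT", "RT", "RC", "LP"):
            mci_means[r] = 3.1
        mci_means["LO"] = 3.02  # positive but smallest among candidates
        deltas = _delta_frame({("LF", "LT"), ("RT", "RC"), ("LP", "LO")})
        part = partition_rois(hc, _stats_frame(mci_means), deltas, balance=True)
        assert part.hyper == frozenset({"LF", "LT", "RT", "RC", "LP"})
        assert part.hypo == frozenset({"RF", "LC", "RP", "LO", "RO"})

    def test_partition_is_disjoint_and_exhaustive(self):
        deltas = _delta_frame({("LF", "RF")})
        hc = _stats_frame({r: 3.0 for r in DEFAULT_ROI_LABELS})
        mci = _stats_frame({r: 3.0 + 0.01 * i for i, r in enumerate(DEFAULT_ROI_LABELS)})
        part = partition_rois(hc, mci, deltas, balance=True)
        assert part.hyper | part.hypo == frozenset(DEFAULT_ROI_LABELS)
        assert not part.hyper & part.hypo
        assert len(part.hyper) == 5

    def test_all_negative_deltas(self):
        deltas = _delta_frame(set())
        hc = _stats_frame({r: 3.0 for r in DEFAULT_ROI_LABELS})
        mci = _stats_frame(
            {r: 3.0 + 0.02 * i for i, r in enumerate(DEFAULT_ROI_LABELS)}
        )
        no_balance = partition_rois(hc, mci, deltas, balance=False)
        assert no_balance.hyper == frozenset()
        balanced = partition_rois(hc, mci, deltas, balance=True)
        # the five largest degree-delta ROIs get promoted
        expected = set(DEFAULT_ROI_LABELS[-5:])
        assert balanced.hyper == frozenset(expected)

    def test_roi_mismatch_rejected(self):
        hc = _stats_frame({r: 3.0 for r in DEFAULT_ROI_LABELS})
        mci = hc.drop(index="LF")
        with pytest.raises(ValueError):
            partition_rois(hc, mci, _delta_frame(set()))


class TestHemisphericTests:
    def test_pair_group_counts(self, small_cohort):
        coh = cohort_coherence(small_cohort, epoch_len=1.0)
        table, fractions = hemispheric_group_tests(coh)
        per_class = table[table["class"] == "HC"]
        assert len(per_class) == 45
        assert (per_class["group"] == "inter").sum() == 25
        assert (per_class["group"] == "intra").sum() == 20
        assert set(fractions) == {(c, g) for c in ("HC", "MCI") for g in ("inter", "intra")}
        assert all(0.0 <= v <= 1.0 for v in fractions.values())

    def test_two_roi_labelling(self):
        rng = np.random.default_rng(0)
        mats = rng.uniform(0.2, 0.8, size=(2, 30, 2, 2))
        mats = (mats + mats.transpose(0, 1, 3, 2)) / 2
        coh = CohortCoherence(
            roi_labels=("LA", "RB"),
            matrices={"HC": mats, "MCI": mats + 0.01},
            subject_ids={"HC": ["a", "b"], "MCI": ["c", "d"]},
            band=(0.5, 80.0),
            n_pair_evaluations=0,
        )
        table, _ = hemispheric_group_tests(coh)
        hc = table[table["class"] == "HC"]
        assert list(hc["group"]) == ["inter"]

    def test_identical_series_not_significant(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.3, 0.5, size=(2, 50))
        mats = np.zeros((2, 50, 2, 2))
        mats[:, :, 0, 1] = base
        mats[:, :, 1, 0] = base
        mats[:, :, 0, 0] = mats[:, :, 1, 1] = 1.0
        coh = CohortCoherence(
            roi_labels=("LA", "RB"),
            matrices={"HC": mats, "MCI": mats},
            subject_ids={"HC": ["a", "b"], "MCI": ["c", "d"]},
            band=(0.5, 80.0),
            n_pair_evaluations=0,
        )
        table, _ = hemispheric_group_tests(coh)
        # both ROIs share the identical degree series -> t = 0, p = 1
        assert np.allclose(table["p"], 1.0)
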