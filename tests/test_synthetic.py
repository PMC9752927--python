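import math

import numpy as np
import pytest

from plinet.connectivity import band_pli
from plinet.montage import FRONTOTEMPORAL
from plinet.preprocess import BandSpec, make_epochs
from plinet.synthetic import (
    SeverityLink,
    SimChannelModel,
    SimCohortSpec,
    SimCouplingSpec,
    frontotemporal_oscillator,
    simulate_cohort,
    simulate_recording,
)

QUICK = SimChannelModel()


def _theta_pli(rec, epoch_s=10.0):
    total = (rec.n_samples // int(epoch_s * rec.fs)) * epoch_s
    ep = make_epochs(rec, epoch_s, total, bands=[BandSpec("theta", 4, 7)],
                     broadband=None)
    return band_pli(ep["theta"])


class TestSimulateRecording:
    def test_shape_and_units(self):
        rec = simulate_recording(QUICK, [], duration_s=10, fs=500, seed=0)
        assert rec.data.shape == (25, 5000)
        assert rec.fs == 500.0

    def test_seeded_determinism(self):
        a = simulate_recording(QUICK, [frontotemporal_oscillator("L", 0.2)],
                               duration_s=5, fs=500, seed=42)
        b = simulate_recording(QUICK, [frontotemporal_oscillator("L", 0.2)],
                               duration_s=5, fs=500, seed=42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_variance_budget(self):
        rec = simulate_recording(QUICK, [], duration_s=30, fs=500, seed=1)
        target = QUICK.variance
        ratio = rec.data.var(axis=1) / target
        assert np.all(np.abs(ratio - 1) < 0.10)

    def test_variance_budget_with_coupling(self):
        spec = SimCouplingSpec(node_set_a=("T7",), node_set_b=("T9",),
                               band="theta", phase_lag=math.pi / 4, strength=0.5)
        rec = simulate_recording(QUICK, [spec], duration_s=30, fs=500, seed=1)
        i = rec.labels.index("T7")
        # additive injection: variance ratio 1 + f/(1-f) on coupled channels
        expected = QUICK.variance * (1 + 0.5 / 0.5)
        assert abs(rec.data[i].var() / expected - 1) < 0.10

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown electrode"):
            SimCouplingSpec(node_set_a=("Nope",), node_set_b=("T9",))

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            simulate_recording(QUICK, [], duration_s=5, fs=80, seed=0)

    def test_uncoupled_channels_have_low_pli(self):
        rec = simulate_recording(QUICK, [], duration_s=60, fs=500, seed=1)
        cm = _theta_pli(rec)
        vals = cm.pli[np.triu_indices(25, 1)]
        # Monte-Carlo chance level of the 10-s-epoch scheme at 60 s
        assert vals.mean() < 0.15
        assert vals.max() < 0.35

    def test_strong_coupling_gives_high_pli(self):
        spec = SimCouplingSpec(node_set_a=FRONTOTEMPORAL[:8],
                               node_set_b=FRONTOTEMPORAL[8:],
                               band="theta", phase_lag=math.pi / 4, strength=0.9)
        rec = simulate_recording(QUICK, [spec], duration_s=60, fs=500, seed=1)
        cm = _theta_pli(rec)
        ia = [rec.labels.index(x) for x in FRONTOTEMPORAL[:8]]
        ib = [rec.labels.index(x) for x in FRONTOTEMPORAL[8:]]
        cross = cm.pli[np.ix_(ia, ib)]
        assert cross.mean() > 0.8

    def test_coupling_monotonicity(self):
        """PLI of the coupled pair is non-decreasing on a strength grid."""
        plis = []
        for s in (0.0, 0.2, 0.4, 0.6, 0.8):
            spec = SimCouplingSpec(node_set_a=("T7",), node_set_b=("F7",),
                                   band="theta", phase_lag=math.pi / 4, strength=s)
            rec = simulate_recording(QUICK, [spec], duration_s=20, fs=500, seed=3)
            cm = _theta_pli(rec)
            plis.append(cm.pli[rec.labels.index("T7"), rec.labels.index("F7")])
        assert all(b >= a - 1e-9 for a, b in zip(plis, plis[1:]))
        assert plis[-1] > plis[0]


class TestSeverityLink:
    def test_zero_slope_degenerates_to_intercept(self):
        link = SeverityLink(intercept=0.2, slope=0.0, noise_sd=0.0)
        rng = np.random.default_rng(0)
        assert link(10.0, rng) == pytest.approx(0.2)
        assert link(1000.0, rng) == pytest.approx(0.2)

    def test_log_link_monotone(self):
        link = SeverityLink(noise_sd=0.0)
        rng = np.random.default_rng(0)
        vals = [link(s, rng) for s in (5, 40, 400, 4000)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestSimulateCohort:
    def test_bookkeeping_controls(self):
        spec = SimCohortSpec(n_patients=0, n_controls=3, duration_s=5, seed=1)
        out = simulate_cohort(spec)
        assert len(out) == 3
        for _, record in out:
            assert record.group == "control"
            assert math.isnan(record.va2)

    def test_patient_records_consistent(self):
        spec = SimCohortSpec(n_patients=5, n_controls=0, duration_s=5, seed=2)
        out = simulate_cohort(spec)
        for _, record in out:
            assert record.group in {"L-TLE", "R-TLE", "B-TLE"}
            assert record.va2 > 0
            assert record.age_of_onset <= record.age
            assert record.seizure_freq_class in {1, 2, 3, 4}

    def test_byte_reproducible(self):
        spec = SimCohortSpec(n_patients=2, n_controls=1, duration_s=5, seed=7)
        a = simulate_cohort(spec)
        b = simulate_cohort(spec)
        for (ra, sa), (rb, sb) in zip(a, b):
            np.testing.assert_array_equal(ra.data, rb.data)
            assert sa == sb

    def test_severity_distribution_shape(self):
        spec = SimCohortSpec(n_patients=150, n_controls=0, duration_s=1.0, seed=5)
        # short recordings: only the clinical records matter here
        sev = np.array([rec.va2 for _, rec in simulate_cohort(spec)])
        assert 25 < np.median(sev) < 60  # target median 40
        assert np.mean(sev) > np.median(sev) * 1.5  # right-skewed

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="cohort sizes"):
            simulate_cohort(SimCohortSpec(n_patients=0, n_controls=0))
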