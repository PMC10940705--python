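import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calscreen import (
    QCConfig,
    TraceTemplate,
    WellTrace,
    detect_injection_failure,
    detect_interference,
    di_from_arrays,
    difference_index,
    generate_trace,
    profile_trace,
)
from calscreen.errors import QCError
from calscreen.qc import control_pre_median_summary, has_injection_drop
from calscreen.synthetic import NO_EFFECT, PlantedEffect


def brute_force_di(a, b, q=95.0):
    """Independent oracle: explicit sort and explicit interpolation."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    rng = max(a.max(), b.max()) - min(a.min(), b.min())
    if rng == 0:
        return 0.0
    r = sorted(abs(x - y) / rng for x, y in zip(a, b))
    rank = q / 100.0 * (len(r) - 1)
    lo = int(np.floor(rank))
    hi = int(np.ceil(rank))
    return r[lo] + (rank - lo) * (r[hi] - r[lo])


def _trace(values, plate="P", well="A1"):
    values = np.asarray(values, float)
    return WellTrace(plate, well, np.arange(values.size) * 2.0, values)


class TestDiFormula:
    def test_worked_example_sixteen_percent(self):
        # |A-B| = [0,0,0,0,2], combined range 10, r=[0,0,0,0,0.2],
        # 95th percentile at rank 3.8 -> 0.16
        di = di_from_arrays([0, 2, 4, 6, 8], [0, 2, 4, 6, 10])
        assert di == pytest.approx(0.16, abs=1e-12)

    def test_identical_traces_zero(self):
        a = np.linspace(0, 100, 50)
        assert di_from_arrays(a, a) == 0.0

    def test_doubled_trace_inconsistent(self):
        a = np.linspace(0, 100, 50)
        di = di_from_arrays(a, 2 * a)
        assert di == pytest.approx(brute_force_di(a, 2 * a), abs=1e-12)
        assert di > 0.30

    def test_equal_constants_defined_as_zero(self):
        assert di_from_arrays(np.full(20, 5.0), np.full(20, 5.0)) == 0.0

    def test_oracle_equivalence_on_random_pairs(self):
        rng = np.random.default_rng(12345)
        worst = 0.0
        for _ in range(1000):
            n = rng.integers(10, 200)
            a = rng.normal(100, 30, n)
            b = rng.normal(100, 30, n)
            worst = max(worst, abs(di_from_arrays(a, b) - brute_force_di(a, b)))
        assert worst <= 1e-12

    @given(
        data=st.lists(
            st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)),
            min_size=10,
            max_size=60,
        ),
        shift=st.floats(-1e3, 1e3),
        scale=st.floats(0.01, 100),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetry_bounds_and_invariance(self, data, shift, scale):
        a = np.array([d[0] for d in data])
        b = np.array([d[1] for d in data])
        di = di_from_arrays(a, b)
        assert 0.0 <= di <= 1.0
        assert di_from_arrays(b, a) == di
        assert di_from_arrays(a + shift, b + shift) == pytest.approx(di, abs=1e-9)
        assert di_from_arrays(a * scale, b * scale) == pytest.approx(di, abs=1e-9)


class TestDifferenceIndex:
    def test_post_injection_alignment_and_verdict(self):
        rng = np.random.default_rng(0)
        base = np.concatenate([np.full(30, 100.0), np.linspace(100, 500, 120)])
        a = _trace(base + rng.normal(0, 4, base.size))
        b = _trace(base + rng.normal(0, 4, base.size), well="A1")
        out = difference_index(
            a, b, injection_index_a=30, injection_index_b=30, compound_id="X", agonist="CRP"
        )
        assert out.consistent and out.di < 0.30
        assert out.n_timepoints == 120

    def test_threshold_monotonicity(self):
        a = _trace(np.linspace(0, 100, 40))
        b = _trace(np.linspace(0, 140, 40))
        lo = difference_index(a, b, QCConfig(di_threshold=0.1, align_from_injection=False))
        hi = difference_index(a, b, QCConfig(di_threshold=0.9, align_from_injection=False))
        assert hi.consistent >= lo.consistent  # raising the threshold never loses pairs

    def test_short_alignment_rejected(self):
        a = _trace(np.arange(12.0))
        with pytest.raises(QCError, match="aligned"):
            difference_index(a, a, injection_index_a=8, injection_index_b=8)

    def test_mismatched_grids_interpolated_to_coarser(self):
        t_fine = np.arange(0.0, 100.0, 1.0)
        t_coarse = np.arange(0.0, 100.0, 2.0)
        a = WellTrace("P", "A1", t_fine, np.interp(t_fine, [0, 99], [0, 99]))
        b = WellTrace("P", "A1", t_coarse, np.interp(t_coarse, [0, 99], [0, 99]))
        out = difference_index(a, b, QCConfig(align_from_injection=False))
        assert out.di == pytest.approx(0.0, abs=1e-12)
        assert out.n_timepoints == t_coarse.size


class TestInterference:
    def _controls(self, n=16, level=100.0, spread=1.0, seed=0):
        rng = np.random.default_rng(seed)
        traces = {}
        for i in range(n):
            f = np.full(60, level) + rng.normal(0, spread, 60)
            f[30:] += 300.0
            traces[f"C{i}"] = _trace(f, well=f"C{i}")
        return traces

    def test_autofluorescent_flagged(self):
        traces = self._controls()
        summary = control_pre_median_summary(traces, list(traces), 30)
        bright = _trace(np.full(60, 500.0))
        flags = detect_interference(bright, 30, summary)
        assert flags.interference == "autofluorescent"

    def test_quencher_flagged(self):
        traces = self._controls()
        summary = control_pre_median_summary(traces, list(traces), 30)
        dim = _trace(np.full(60, 10.0))
        assert detect_interference(dim, 30, summary).interference == "quencher"

    def test_within_band_not_flagged(self):
        traces = self._controls()
        summary = control_pre_median_summary(traces, list(traces), 30)
        normal = _trace(np.full(60, 100.5))
        assert detect_interference(normal, 30, summary).interference == "none"

    def test_zero_mad_floor_warns(self):
        summary = (100.0, 0.0)
        with pytest.warns(UserWarning, match="MAD"):
            flags = detect_interference(_trace(np.full(60, 100.0)), 30, summary)
        assert flags.interference == "none"

    def test_too_few_controls_rejected(self):
        traces = self._controls(n=4)
        with pytest.raises(QCError, match=">= 8"):
            control_pre_median_summary(traces, list(traces), 30)


class TestInjectionFailure:
    def _params(self, trace, agonist="thrombin"):
        return profile_trace(trace, agonist, 30)

    def test_failure_well_flagged(self):
        tpl = TraceTemplate(agonist="thrombin")
        trace = generate_trace(
            tpl, PlantedEffect("X", "injection_failure"), 60.0, 2.0, 5, well_id="F1"
        )
        params = self._params(trace)
        assert detect_injection_failure(trace, 30, params, (400.0, 5.0))

    def test_strong_inhibitor_with_artifact_not_flagged(self):
        tpl = TraceTemplate(agonist="thrombin")
        trace = generate_trace(tpl, PlantedEffect("X", "inhibitor", 0.05), 60.0, 2.0, 5)
        params = self._params(trace)
        # response is 5 % of control (boundary) but the drop artifact is intact
        assert has_injection_drop(trace, 30)
        assert not detect_injection_failure(trace, 30, params, (400.0, 5.0))

    def test_normal_control_well_not_flagged(self):
        tpl = TraceTemplate(agonist="thrombin")
        trace = generate_trace(tpl, NO_EFFECT, 60.0, 2.0, 5)
        params = self._params(trace)
        assert not detect_injection_failure(trace, 30, params, (400.0, 5.0))
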