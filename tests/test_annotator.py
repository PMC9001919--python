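import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermotrace import (
    AnnotatorConfig,
    SimulationConfig,
    annotate,
    classify,
    detect_setpoints,
    label_sections,
    simulate_trace,
)

from _reference import reference_setpoints
from conftest import MICRO_TEMPS, make_trace, random_walk_trace


class TestLabelSections:
    def test_strict_inequality_at_boundary(self):
        tr = make_trace([18.0, 19.0, 18.0])
        mask, bouts = label_sections(tr)
        assert mask.tolist() == [False, True, False]
        assert bouts == ((1, 2),)

    def test_all_equal_threshold_gives_no_bouts(self):
        mask, bouts = label_sections(make_trace([18.0] * 8))
        assert not mask.any()
        assert bouts == ()

    def test_micro_trace_single_bout(self, micro_trace):
        _, bouts = label_sections(micro_trace)
        assert bouts == ((1, 15),)

    def test_short_runs_suppressed_one_sided(self):
        tr = make_trace([19.0, 17.0, 19.0, 19.0, 19.0, 17.0])
        cfg = AnnotatorConfig(min_section_samples=2)
        mask, bouts = label_sections(tr, cfg)
        # the lone sample at 0 is relabelled; the short *non*-thermo run at 1 is not
        assert mask.tolist() == [False, False, True, True, True, False]
        assert bouts == ((2, 5),)

    def test_threshold_override(self):
        tr = make_trace([18.0, 19.0, 18.0], ta_ref=18.0)
        mask, _ = label_sections(tr, AnnotatorConfig(section_threshold=20.0))
        assert not mask.any()


class TestDetectSetpoints:
    def test_worked_micro_trace(self, micro_trace, default_cfg):
        events, n_changes = detect_setpoints(micro_trace, (1, 15), default_cfg)
        assert [(e.kind, e.index, e.temp) for e in events] == [
            ("upper", 5, 30.0),
            ("lower", 8, 27.5),
            ("upper", 11, 31.0),
        ]
        assert n_changes == 3

    def test_monotone_ramp_no_events(self, default_cfg):
        temps = np.linspace(18.0, 31.0, 40)
        tr = make_trace(temps)
        events, n = detect_setpoints(tr, (1, 40), default_cfg)
        assert events == [] and n == 0

    def test_triangle_below_hysteresis_no_events(self, default_cfg):
        up = np.linspace(25 - 0.95, 25 + 0.95, 10)
        temps = np.concatenate([np.tile(np.concatenate([up, up[::-1]]), 5)])
        tr = make_trace(temps)
        events, n = detect_setpoints(tr, (0, len(temps)), default_cfg)
        assert events == [] and n == 0

    def test_first_occurrence_tie_breaking(self, default_cfg):
        # plateau at the maximum: event lands on its first sample
        temps = [20.0, 25.0, 30.0, 30.0, 30.0, 27.0, 25.0]
        tr = make_trace(temps)
        events, _ = detect_setpoints(tr, (0, 7), default_cfg)
        assert [(e.kind, e.index) for e in events] == [("upper", 2)]

    def test_initial_direction_not_counted(self, default_cfg):
        # falls first: initial determination of cooling is not an event
        temps = [30.0, 28.0, 25.0, 24.0, 26.5, 28.0]
        tr = make_trace(temps)
        events, n = detect_setpoints(tr, (0, 6), default_cfg)
        assert [(e.kind, e.index, e.temp) for e in events] == [("lower", 3, 24.0)]
        assert n == 1

    def test_unconfirmed_terminal_extremum_dropped(self, default_cfg):
        temps = [20.0, 25.0, 30.0, 27.0, 24.0, 26.0, 27.5]  # trailing rise of 3.5
        tr = make_trace(temps)
        events, _ = detect_setpoints(tr, (0, 7), default_cfg)
        assert [e.kind for e in events] == ["upper", "lower"]
        temps2 = temps[:5] + [25.0, 25.9]  # trailing rise < hysteresis
        events2, _ = detect_setpoints(make_trace(temps2), (0, 7), default_cfg)
        assert [e.kind for e in events2] == ["upper"]

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bruteforce_reference(self, seed, default_cfg):
        rng = np.random.default_rng(seed)
        tr = random_walk_trace(rng)
        events, _ = detect_setpoints(tr, (0, tr.n), default_cfg)
        assert [(e.kind, e.index, e.temp) for e in events] == reference_setpoints(
            tr.temp, default_cfg.hysteresis
        )

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        temps=st.lists(
            st.integers(-20, 20).map(lambda k: 25.0 + 0.5 * k), min_size=2, max_size=60
        ),
        h=st.sampled_from([0.5, 1.0, 2.0, 3.5]),
    )
    def test_reference_equivalence_property(self, temps, h):
        tr = make_trace(temps)
        cfg = AnnotatorConfig(hysteresis=h)
        events, _ = detect_setpoints(tr, (0, tr.n), cfg)
        assert [(e.kind, e.index, e.temp) for e in events] == reference_setpoints(temps, h)


class TestClassify:
    @pytest.mark.parametrize("total,expected", [(3, True), (2, False), (0, False), (4, True)])
    def test_strictly_more_than_two(self, total, expected):
        assert classify(total) is expected


class TestAnnotate:
    def test_micro_trace_full_pipeline(self, micro_trace):
        at = annotate(micro_trace)
        assert at.n_shuttles == 3
        assert at.is_thermoregulator
        assert at.bouts == ((1, 15),)

    def test_flat_trace(self):
        at = annotate(make_trace([18.0] * 20))
        assert at.n_bouts == 0 and at.n_shuttles == 0
        assert not at.is_thermoregulator

    def test_simulated_non_thermoregulator(self):
        cfg = SimulationConfig(mode="non_thermoregulator", noise_sd=0.0, seed=1)
        trace, _ = simulate_trace(cfg)
        at = annotate(trace)
        assert at.n_shuttles <= 1
        assert not at.is_thermoregulator

    def test_idempotence(self, micro_trace):
        once = annotate(micro_trace)
        twice = annotate(once.trace)
        assert once == twice

    def test_detector_resets_at_bout_boundaries(self, default_cfg):
        # bout 1 ends warming at 30; bout 2 starts at 22: without a reset the
        # drop would be read as a reversal and yield an upper event at 30.
        temps = [18.0, 24.0, 30.0, 17.0, 17.0, 22.0, 23.0, 23.5, 18.0]
        at = annotate(make_trace(temps))
        assert at.bouts == ((1, 3), (5, 8))
        assert at.events == ()

    def test_direction_changes_only_inside_sections(self):
        # exit ramp to ambient after the bout must not create a lower event
        temps = [18.0, 25.0, 31.0, 27.0, 22.0, 19.0, 18.0, 17.8, 17.9, 18.0]
        at = annotate(make_trace(temps))
        assert [e.kind for e in at.events] == ["upper"]


class TestAnnotationProperties:
    @pytest.mark.parametrize("seed", range(30))
    def test_alternation_and_separation_within_bouts(self, seed):
        rng = np.random.default_rng(1000 + seed)
        tr = random_walk_trace(rng, n=300)
        at = annotate(tr)
        h = 2.0
        for s, e in at.bouts:
            evs = [ev for ev in at.events if s <= ev.index < e]
            for a, b in zip(evs, evs[1:]):
                assert a.kind != b.kind
                assert abs(a.temp - b.temp) >= h - 1e-12
            ups = [ev.temp for ev in evs if ev.kind == "upper"]
            los = [ev.temp for ev in evs if ev.kind == "lower"]
            if ups and los:
                assert np.mean(ups) - np.mean(los) >= h - 1e-12

    def test_upper_is_running_max_lower_is_running_min(self):
        rng = np.random.default_rng(99)
        tr = random_walk_trace(rng, n=400)
        at = annotate(tr)
        for ev in at.events:
            assert ev.temp == tr.temp[ev.index]

    def test_quantization_robustness_sigma_zero(self):
        cfg = SimulationConfig(noise_sd=0.0, seed=3, p_exit=0.0)
        q_trace, _ = simulate_trace(cfg)
        # rebuild the unquantized latent series with an effectively-zero step
        u_cfg = SimulationConfig(noise_sd=0.0, seed=3, p_exit=0.0, resolution=1e-12)
        u_trace, _ = simulate_trace(u_cfg)
        at_q = annotate(q_trace)
        at_u = annotate(u_trace)
        assert [e.kind for e in at_q.events] == [e.kind for e in at_u.events]
        for a, b in zip(at_q.events, at_u.events):
            assert abs(a.temp - b.temp) <= cfg.resolution
            assert abs(a.index - b.index) <= 25  # plateau from quantization
        assert at_q.is_thermoregulator == at_u.is_thermoregulator
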