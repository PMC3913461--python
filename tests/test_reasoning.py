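"""Per-shock segmentation and review-variable derivation rules."""

import pandas as pd
import pytest

import roreview as rv
from roreview.core import Event
from roreview.reasoning import (
    CODE_NO,
    CODE_UNKNOWN,
    CODE_YES,
    MODE_ADVISORY,
    MODE_MANUAL,
    ReviewConfig,
    checkpoint_rhythm_code,
    stacked_run_sizes,
)
from roreview.timecodes import ClockTriplet, NO_CPR_88, UNKNOWN_99


def make_episode(therapy_events, rhythm_events, span_end, shock_times, **kw):
    therapy = rv.build_therapy_sequence(therapy_events, 0.0, span_end)
    response = rv.build_response_sequence(rhythm_events, span_end)
    shocks = tuple(rv.ShockRecord(t, 200.0, 80.0) for t in shock_times)
    return rv.Episode(therapy=therapy, response=response, shocks=shocks, **kw)


def two_shock_episode():
    ev = [
        Event("d1", 50.0), Event("d2", 55.0),
        Event("c1", 60.0), Event("c2", 120.0),
        Event("d1", 130.0), Event("d2", 135.0),
        Event("c1", 140.0), Event("c2", 290.0),
    ]
    rhythm = [Event("vf", 10.0), Event("pe", 180.0)]
    return make_episode(ev, rhythm, 300.0, [50.0, 130.0])


class TestSegmentation:
    def test_two_shock_windows(self):
        ctxs = rv.segment_shocks(two_shock_episode())
        assert len(ctxs) == 2
        first, second = ctxs
        assert first.is_first and first.pre_start == 0.0  # BOE
        assert first.post_end == 130.0
        assert second.pre_start == 50.0
        assert second.is_last and second.post_end == 300.0  # EOE

    def test_single_shock_spans_episode(self, narrative_episode):
        (ctx,) = rv.segment_shocks(narrative_episode)
        assert ctx.pre_window == (0.0, 198.0)
        assert ctx.post_window == (198.0, 343.0)

    def test_zero_shocks_yields_empty(self, eq4_therapy, eq4_response):
        ep = rv.Episode(
            therapy=rv.build_therapy_sequence([], 0.0, 100.0),
            response=rv.build_response_sequence([Event("vf", 1.0)], 100.0),
        )
        assert rv.segment_shocks(ep) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_windows_tile_the_episode(self, seed):
        ep = rv.generate_episode(seed=seed).episode()
        ctxs = rv.segment_shocks(ep)
        assert ctxs[0].pre_start == ep.span_start
        assert ctxs[-1].post_end == ep.span_end
        for a, b in zip(ctxs, ctxs[1:]):
            assert a.post_end == b.shock_time
            assert b.pre_start == a.shock_time


class TestTimeVariables:
    def test_first_and_last_compression_on_tracing(self, eq4_episode):
        (ctx,) = rv.segment_shocks(eq4_episode)
        tv = rv.derive_time_variables(ctx, eq4_episode)
        assert tv.fc_elapsed == 805.2
        assert tv.lc_elapsed == 887.2
        # absolute conversions against the 14:30:00 power-on
        assert tv.fctm == ClockTriplet(14, 43, 25)  # 805.2 s later
        assert tv.ecgtm == ClockTriplet(14, 30, 0)

    def test_vf_onset_in_walkthrough(self, narrative_episode):
        (ctx,) = rv.segment_shocks(narrative_episode)
        tv = rv.derive_time_variables(ctx, narrative_episode)
        assert tv.vfonset_elapsed == 283.0

    def test_no_compressions_codes_no_cpr(self):
        ep = make_episode(
            [Event("d1", 50.0), Event("d2", 55.0)],
            [Event("vf", 10.0), Event("as", 60.0)],
            200.0,
            [50.0],
        )
        (ctx,) = rv.segment_shocks(ep)
        tv = rv.derive_time_variables(ctx, ep)
        assert tv.fctm == NO_CPR_88 and tv.lctm == NO_CPR_88

    def test_persistent_vf_codes_no_onset(self):
        ep = make_episode(
            [Event("d1", 50.0), Event("d2", 55.0)],
            [Event("vf", 10.0)],
            300.0,
            [50.0],
        )
        (ctx,) = rv.segment_shocks(ep)
        tv = rv.derive_time_variables(ctx, ep)
        assert tv.vfonsettm == UNKNOWN_99
        assert tv.vfonset_elapsed is None

    def test_vf_recurrence_after_break_is_an_onset(self):
        ep = make_episode(
            [Event("d1", 50.0), Event("d2", 55.0)],
            [Event("vf", 10.0), Event("as", 58.0), Event("vf", 100.0)],
            300.0,
            [50.0],
        )
        (ctx,) = rv.segment_shocks(ep)
        assert rv.derive_time_variables(ctx, ep).vfonset_elapsed == 100.0

    def test_rosc_time_is_first_pulse_transition(self):
        ep = make_episode(
            [Event("d1", 50.0), Event("d2", 55.0)],
            [Event("vf", 10.0), Event("pr", 120.0)],
            300.0,
            [50.0],
        )
        (ctx,) = rv.segment_shocks(ep)
        assert rv.derive_time_variables(ctx, ep).rsc_elapsed == 120.0

    def test_unknown_power_on_propagates(self):
        ep = make_episode(
            [Event("c1", 10.0), Event("c2", 40.0), Event("d1", 50.0), Event("d2", 55.0)],
            [Event("vf", 5.0), Event("as", 60.0)],
            200.0,
            [50.0],
            power_on=None,
        )
        (ctx,) = rv.segment_shocks(ep)
        tv = rv.derive_time_variables(ctx, ep)
        assert tv.ecgtm == UNKNOWN_99 and tv.shktm == UNKNOWN_99
        assert tv.fctm == UNKNOWN_99  # a compression exists but no clock
        assert tv.fc_elapsed == 10.0

    def test_ongoing_at_start_flag(self):
        ep = make_episode(
            [Event("c1", 0.0), Event("c2", 40.0), Event("d1", 50.0), Event("d2", 55.0)],
            [Event("vf", 5.0), Event("as", 60.0)],
            200.0,
            [50.0],
        )
        (ctx,) = rv.segment_shocks(ep)
        assert rv.derive_time_variables(ctx, ep).fc_ongoing_at_start


class TestResponseVariables:
    def test_walkthrough_checkpoints(self, narrative_episode):
        """Shock at 198 s: asystole at +10 (208 s), organized at +60 (258 s)."""
        (ctx,) = rv.segment_shocks(narrative_episode)
        rvars = rv.derive_response_variables(ctx, narrative_episode)
        assert rvars.init_rhy == 2  # VF from 46 s
        assert rvars.rhyb4 == 2
        assert rvars.r10 == 1  # asystole
        assert rvars.r30 == 1
        assert rvars.r60 == 4  # organized
        assert rvars.r120 == 2  # VF recurred at 283
        assert rvars.vfpr == CODE_YES
        assert rvars.orgpr == CODE_YES
        assert rvars.rosc == CODE_NO

    def test_constant_domain_constant_codes(self):
        ep = make_episode(
            [Event("d1", 50.0), Event("d2", 55.0)],
            [Event("as", 5.0)],
            300.0,
            [50.0],
        )
        (ctx,) = rv.segment_shocks(ep)
        rvars = rv.derive_response_variables(ctx, ep)
        assert rvars.rhyb4 == rvars.r10 == rvars.r30 == rvars.r60 == rvars.r120 == 1

    def test_unknown_preshock_boundary_is_not_persistent_vf(self):
        # VF, then unknown just before the 10 s check: rhyb4 stays VF but
        # the unknown rhythm at +10 blocks the persistent-VF coding
        ep = make_episode(
            [Event("d1", 50.0), Event("d2", 55.0)],
            [Event("vf", 10.0), Event("un", 56.0), Event("vf", 90.0)],
            300.0,
            [50.0],
        )
        (ctx,) = rv.segment_shocks(ep)
        tv = rv.derive_time_variables(ctx, ep)
        assert tv.vfonset_elapsed == 90.0  # not coded persistent

    def test_un_at_boundary_makes_rhyb4_unknown(self):
        ep = make_episode(
            [Event("d1", 50.0), Event("d2", 55.0)],
            [Event("vf", 10.0), Event("un", 45.0), Event("as", 60.0)],
            300.0,
            [50.0],
        )
        (ctx,) = rv.segment_shocks(ep)
        assert rv.derive_response_variables(ctx, ep).rhyb4 == CODE_UNKNOWN

    def test_recording_end_before_checkpoint_is_unknown(self):
        # recording ends 111 s after the shock: r120 unknowable
        ep = make_episode(
            [Event("d1", 50.0), Event("d2", 55.0)],
            [Event("vf", 10.0), Event("as", 60.0)],
            161.0,
            [50.0],
        )
        (ctx,) = rv.segment_shocks(ep)
        rvars = rv.derive_response_variables(ctx, ep)
        assert rvars.r60 == 1
        assert rvars.r120 == CODE_UNKNOWN

    def test_vf_transition_in_window_overrides(self):
        # VF onset at 63 s = 13 s post-shock: within ±5 s of the 10 s check
        ep = make_episode(
            [Event("d1", 50.0), Event("d2", 55.0)],
            [Event("vf", 10.0), Event("as", 52.0), Event("vf", 63.0)],
            300.0,
            [50.0],
        )
        (ctx,) = rv.segment_shocks(ep)
        assert rv.derive_response_variables(ctx, ep).r10 == 2

    def test_unknown_falls_back_to_last_known_within_window(self):
        # PE until 107 s, unknown after; the 60 s check (110 s) still reads PE
        ep = make_episode(
            [Event("d1", 50.0), Event("d2", 55.0)],
            [Event("pe", 10.0), Event("un", 107.0)],
            300.0,
            [50.0],
        )
        (ctx,) = rv.segment_shocks(ep)
        rvars = rv.derive_response_variables(ctx, ep)
        assert rvars.r60 == 4
        assert rvars.r120 == CODE_UNKNOWN  # PE too far from the 120 s check

    def test_shock_end_offset_shifts_checkpoints(self):
        # transition to AS at 62.5: the 10 s check reads VF with offset 0
        # (q=60, transition at 62.5 outside half-width 2) but AS with offset 3
        ep = make_episode(
            [Event("d1", 50.0), Event("d2", 55.0)],
            [Event("vf", 10.0), Event("as", 62.5), Event("pe", 200.0)],
            300.0,
            [50.0],
        )
        (ctx,) = rv.segment_shocks(ep)
        r0 = rv.derive_response_variables(ctx, ep, ReviewConfig(window_halfwidth_s=2.0))
        r3 = rv.derive_response_variables(
            ctx, ep, ReviewConfig(shock_end_offset_s=3.0, window_halfwidth_s=2.0)
        )
        assert r0.r10 == 2 and r3.r10 == 1

    def test_unknown_coverage_blocks_a_no_answer(self):
        ep = make_episode(
            [Event("d1", 50.0), Event("d2", 55.0)],
            [Event("as", 10.0), Event("un", 100.0)],
            300.0,
            [50.0],
        )
        (ctx,) = rv.segment_shocks(ep)
        rvars = rv.derive_response_variables(ctx, ep)
        assert rvars.vfpr == CODE_UNKNOWN  # VF could hide in the unknown span
        assert rvars.rosc == CODE_NO  # rosc follows the representation only

    @pytest.mark.parametrize("seed", range(8))
    def test_preshock_rhythm_consistent_with_previous_post_window(self, seed):
        """rhyb4 of shock k+1 equals the rhythm at the end of shock k's window."""
        ep = rv.generate_episode(seed=seed).episode()
        ctxs = rv.segment_shocks(ep)
        for a, b in zip(ctxs, ctxs[1:]):
            if a.post_response.is_empty:
                continue
            last_label = a.post_response.intervals[-1].label
            expected = rv.reasoning.RHYTHM_CODE[last_label]
            got = rv.derive_response_variables(b, ep).rhyb4
            assert got == expected


class TestDeviceVariables:
    def test_stacked_run_decomposition(self):
        # three shocks, no compressions between 1-2, compressions before 3
        ev = [
            Event("d1", 50.0), Event("d2", 55.0),
            Event("d1", 60.0), Event("d2", 65.0),
            Event("c1", 70.0), Event("c2", 120.0),
            Event("d1", 130.0), Event("d2", 135.0),
        ]
        ep = make_episode(ev, [Event("vf", 5.0)], 200.0, [50.0, 60.0, 130.0])
        assert stacked_run_sizes(ep) == [2, 2, 1]

    def test_mode_from_latest_switch(self):
        ep = make_episode(
            [Event("d1", 100.0), Event("d2", 105.0)],
            [Event("vf", 5.0)],
            200.0,
            [100.0],
            mode_switches=(rv.ModeSwitch(5.0, "advisory"),),
        )
        (ctx,) = rv.segment_shocks(ep)
        assert rv.derive_device_variables(ctx, ep).mode == MODE_ADVISORY

        ep2 = make_episode(
            [Event("d1", 100.0), Event("d2", 105.0)],
            [Event("vf", 5.0)],
            200.0,
            [100.0],
            mode_switches=(rv.ModeSwitch(5.0, "advisory"), rv.ModeSwitch(50.0, "manual")),
        )
        (ctx2,) = rv.segment_shocks(ep2)
        assert rv.derive_device_variables(ctx2, ep2).mode == MODE_MANUAL

    def test_cpr_and_counters(self):
        ep = two_shock_episode()
        c1, c2 = rv.segment_shocks(ep)
        d1 = rv.derive_device_variables(c1, ep)
        d2 = rv.derive_device_variables(c2, ep)
        assert (d1.shkn, d2.shkn) == (1, 2)
        assert d1.ssrecord == d2.ssrecord == 2
        assert d1.cpr == CODE_NO  # no compressions before the first shock
        assert d2.cpr == CODE_YES

    def test_manual_fc_lc_unknown_reads_as_cpr_present(self):
        ep = two_shock_episode()
        c1, _ = rv.segment_shocks(ep)
        assert rv.derive_device_variables(c1, ep, manual_fc_lc_unknown=True).cpr == CODE_YES

    def test_missing_log_attributes_use_sentinel(self):
        therapy = rv.build_therapy_sequence(
            [Event("d1", 50.0), Event("d2", 55.0)], 0.0, 100.0
        )
        ep = rv.Episode(
            therapy=therapy,
            response=rv.build_response_sequence([Event("vf", 5.0)], 100.0),
            shocks=(rv.ShockRecord(50.0),),
        )
        (ctx,) = rv.segment_shocks(ep)
        dv = rv.derive_device_variables(ctx, ep)
        assert dv.imp == 999 and dv.enrgy == 999


def test_derivation_is_deterministic():
    ep = rv.generate_episode(seed=33).episode()
    pd.testing.assert_frame_equal(rv.derive_database(ep), rv.derive_database(ep))
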