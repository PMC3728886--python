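"""Screening orchestrator: barrier rule, TST conversion, pipeline, analyses."""

import math

import numpy as np
import pytest
from conftest import make_context
from hypothesis import given, settings
from hypothesis import strategies as st

import barrierscreen as bs
from barrierscreen import engine as eng
from barrierscreen import screening as scr
from barrierscreen.errors import ConfigurationError


def _profile(energies, statuses=None, x1=None):
    n = len(energies)
    statuses = statuses or [eng.CONVERGED] * n
    energies = [e if st_ == eng.CONVERGED else None
                for e, st_ in zip(energies, statuses)]
    return scr.ReactionProfile(
        label="T", pathway_id=5,
        x1_targets=x1 or list(np.linspace(3.0, 1.5, n)),
        energies=energies, statuses=statuses,
    )


def oracle_barrier(energies, statuses):
    """Independent two-pass restatement of the barrier rule, used as a test
    oracle: find the first global maximum among converged frames, demand a
    fully converged prefix, interior maximum, and a positive drop."""
    conv = [(i, e) for i, (e, st_) in enumerate(zip(energies, statuses))
            if st_ == eng.CONVERGED]
    if len(conv) < 2:
        return None, scr.INCOMPLETE
    emax = max(e for _, e in conv)
    imax = min(i for i, e in conv if e == emax)
    if any(st_ != eng.CONVERGED for st_ in statuses[:imax]):
        return None, scr.INCOMPLETE
    if imax == len(energies) - 1:
        return None, scr.LAST_FRAME_MAX
    if imax == 0:
        return None, scr.NO_PRE_MAX
    barrier = emax - min(energies[:imax])
    if barrier <= 0:
        return None, scr.NONPOSITIVE
    return barrier, None


class TestExtractBarrier:
    def test_simple_hill(self):
        res = scr.extract_barrier(_profile([0.0, 5.0, 12.0, 8.0, 1.0]))
        assert res.valid
        assert res.barrier == pytest.approx(12.0)
        assert res.argmax == 2 and res.argmin == 0

    def test_minimum_taken_before_maximum_only(self):
        # later dip below the pre-max minimum must not enlarge the barrier
        res = scr.extract_barrier(_profile([2.0, 10.0, -5.0]))
        assert res.valid
        assert res.barrier == pytest.approx(8.0)

    def test_last_frame_maximum_rejected(self):
        res = scr.extract_barrier(_profile([0.0, 3.0, 7.0, 12.0]))
        assert not res.valid
        assert res.rejection_reason == scr.LAST_FRAME_MAX

    def test_first_frame_maximum_rejected(self):
        res = scr.extract_barrier(_profile([12.0, 3.0, 1.0, 0.0]))
        assert not res.valid
        assert res.rejection_reason == scr.NO_PRE_MAX

    def test_unconverged_prefix_rejected(self):
        statuses = [eng.CONVERGED, eng.NOT_CONVERGED, eng.CONVERGED, eng.CONVERGED]
        res = scr.extract_barrier(_profile([0.0, 5.0, 12.0, 1.0], statuses))
        assert not res.valid
        assert res.rejection_reason == scr.INCOMPLETE

    def test_unconverged_after_max_tolerated(self):
        statuses = [eng.CONVERGED, eng.CONVERGED, eng.CONVERGED, eng.NOT_CONVERGED]
        res = scr.extract_barrier(_profile([0.0, 12.0, 5.0, 99.0], statuses))
        assert res.valid
        assert res.barrier == pytest.approx(12.0)

    def test_flat_profile_rejected_nonpositive(self):
        res = scr.extract_barrier(_profile([4.0, 4.0, 4.0, 4.0]))
        assert not res.valid
        # argmax of a constant profile is frame 0
        assert res.rejection_reason == scr.NO_PRE_MAX

    def test_incomplete_takes_precedence_over_last_frame_max(self):
        statuses = [eng.NOT_CONVERGED, eng.CONVERGED, eng.CONVERGED, eng.CONVERGED]
        res = scr.extract_barrier(_profile([0.0, 1.0, 2.0, 12.0], statuses))
        assert res.rejection_reason == scr.INCOMPLETE

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=2,
                    max_size=12),
           st.lists(st.booleans(), min_size=2, max_size=12))
    def test_matches_independent_oracle(self, energies, conv_flags):
        n = len(energies)
        flags = (conv_flags * n)[:n]
        statuses = [eng.CONVERGED if f else eng.NOT_CONVERGED for f in flags]
        p = _profile(energies, statuses)
        res = scr.extract_barrier(p)
        oracle_b, oracle_reason = oracle_barrier(
            [e for e in energies], statuses)
        if oracle_b is None:
            assert not res.valid
            assert res.rejection_reason == oracle_reason
        else:
            assert res.valid
            assert res.barrier == pytest.approx(oracle_b)


class TestEyring:
    def test_known_rate_to_free_energy(self):
        # k = 9.6 1/s at 313.15 K corresponds to ~17.0 kcal/mol
        dg = scr.eyring_dg(9.6, 313.15)
        assert round(dg, 1) == 17.0

    def test_round_trip(self):
        for k_cat in (0.01, 1.0, 9.6, 1e4):
            dg = scr.eyring_dg(k_cat, 298.15)
            assert scr.eyring_k(dg, 298.15) == pytest.approx(k_cat, rel=1e-10)

    def test_slower_rate_means_higher_barrier(self):
        assert scr.eyring_dg(0.1, 313.15) > scr.eyring_dg(10.0, 313.15)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            scr.eyring_dg(0.0, 313.15)
        with pytest.raises(ValueError):
            scr.eyring_dg(1.0, -5.0)
        with pytest.raises(ValueError):
            scr.eyring_k(10.0, 0.0)

    def test_dimensional_oracle(self):
        # independent recomputation from the definition with CODATA values
        k_cat, T = 9.6, 313.15
        prefactor = 1.380649e-23 * T / 6.62607015e-34
        expected = 1.98720425864e-3 * T * math.log(prefactor / k_cat)
        assert scr.eyring_dg(k_cat, T) == pytest.approx(expected, rel=1e-12)


class TestWildType:
    def test_wild_type_barrier_recovered_exactly(self, toy):
        ctx, settings_ = make_context(toy, bs.GroundTruth(wt_barrier=18.5))
        wt = scr.run_wild_type(ctx, settings_)
        assert wt.valid
        assert wt.barrier == pytest.approx(18.5, abs=1e-6)

    def test_constrained_run_matches_unconstrained(self, toy):
        gt = bs.GroundTruth(wt_barrier=18.5)
        ctx_u, set_u = make_context(toy, gt)
        ctx_c, set_c = make_context(toy, gt, layer_radius=6.0)
        wu = scr.run_wild_type(ctx_u, set_u)
        wc = scr.run_wild_type(ctx_c, set_c)
        assert wu.barrier == pytest.approx(wc.barrier, abs=1e-6)

    def test_recovery_improves_with_frame_count(self, toy):
        gt = bs.GroundTruth(wt_barrier=18.5)
        errors = []
        for n in (4, 10, 50):
            ctx, settings_ = make_context(toy, gt, n_intermediate=n)
            wt = scr.run_wild_type(ctx, settings_)
            errors.append(abs(wt.barrier - 18.5))
        assert errors[0] > 1.0           # coarse ladder under-samples
        assert errors[1] < 0.1
        assert errors[2] < 0.1
        assert errors[0] > errors[1] >= errors[2] - 1e-12


def _toy_screen(toy, barriers, **gt_kw):
    gt = bs.GroundTruth(wt_barrier=18.5, mutant_barriers=barriers, **gt_kw)
    ctx, settings_ = make_context(toy, gt)
    positions = bs.detect_active_site(toy.ge, 4.0)
    specs = [s for s in bs.enumerate_single_mutants(positions, {1})
             if s.label in barriers]
    wt = scr.run_wild_type(ctx, settings_)
    records, report = scr.screen(specs, wt, ctx, settings_)
    return wt, records, report


class TestScreen:
    def test_programmed_barriers_recovered(self, toy):
        barriers = {"A10W": 6.9, "A10F": 15.5, "A11C": 22.0}
        wt, records, report = _toy_screen(toy, barriers)
        assert report["n_computed"] == 3
        for rec in records:
            assert rec.valid
            assert rec.barrier == pytest.approx(barriers[rec.label], abs=1e-6)
            assert rec.delta_vs_wt == pytest.approx(barriers[rec.label] - 18.5, abs=1e-6)

    def test_lewis_failure_discarded_with_reason(self, toy):
        barriers = {"A10W": 6.9, "A10F": 15.5}
        wt, records, report = _toy_screen(
            toy, barriers, lewis_failure_labels=frozenset({"A10F"}))
        by_label = {r.label: r for r in records}
        assert by_label["A10F"].status == scr.STATUS_LEWIS
        assert math.isnan(by_label["A10F"].barrier)
        assert by_label["A10W"].valid
        assert report["by_reason"][scr.STATUS_LEWIS] == ["A10F"]

    def test_charge_mismatch_discarded(self, toy):
        barriers = {"A10W": 6.9, "A10K": 12.0}
        wt, records, report = _toy_screen(
            toy, barriers, charge_mismatch_labels=frozenset({"A10K"}))
        by_label = {r.label: r for r in records}
        assert by_label["A10K"].status == scr.STATUS_CHARGE
        assert by_label["A10W"].valid

    def test_steric_clash_discarded(self, toy_clash):
        barriers = {"A11W": 9.0, "A10W": 6.9}
        wt, records, report = _toy_screen(toy_clash, barriers)
        by_label = {r.label: r for r in records}
        assert by_label["A11W"].status == "DISCARDED_MODELING"
        assert by_label["A10W"].valid

    def test_discarded_mutants_retained_in_report(self, toy):
        barriers = {"A10W": 6.9, "A10F": 15.5}
        wt, records, report = _toy_screen(
            toy, barriers, lewis_failure_labels=frozenset({"A10F"}))
        assert report["n_requested"] == 2
        assert report["n_computed"] == 1
        assert report["n_discarded"] == 1
        assert len(records) == 2  # nothing silently dropped

    def test_invalid_wild_type_aborts(self, toy):
        ctx, settings_ = make_context(toy, bs.GroundTruth())
        bad_wt = scr.MutantRecord(spec=None, label="WT", status=scr.STATUS_LEWIS)
        with pytest.raises(ConfigurationError):
            scr.screen([], bad_wt, ctx, settings_)

    def test_constrained_screen_recovers_barriers(self, toy):
        barriers = {"A10W": 6.9, "A11C": 22.0}
        gt = bs.GroundTruth(wt_barrier=18.5, mutant_barriers=barriers)
        ctx, settings_ = make_context(toy, gt, layer_radius=6.0)
        positions = bs.detect_active_site(toy.ge, 4.0)
        specs = [s for s in bs.enumerate_single_mutants(positions, {1})
                 if s.label in barriers]
        wt = scr.run_wild_type(ctx, settings_)
        records, _ = scr.screen(specs, wt, ctx, settings_)
        for rec in records:
            assert rec.barrier == pytest.approx(barriers[rec.label], abs=1e-6)


class TestRank:
    def _records(self):
        recs = []
        for label, b in (("A10W", 6.9), ("A10F", 15.5), ("A11C", 22.0), ("A11Y", 6.9)):
            r = scr.MutantRecord(spec=None, label=label)
            r.barrier_result = scr.BarrierResult(b, 5, 0, True)
            recs.append(r)
        bad = scr.MutantRecord(spec=None, label="A12P", status=scr.STATUS_LEWIS)
        recs.append(bad)
        return recs

    def test_ascending_with_label_tiebreak(self):
        df = scr.rank(self._records())
        assert list(df["label"]) == ["A10W", "A11Y", "A10F", "A11C"]

    def test_invalid_records_excluded(self):
        df = scr.rank(self._records())
        assert "A12P" not in set(df["label"])

    def test_top_n(self):
        df = scr.rank(self._records(), top_n=2)
        assert len(df) == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            scr.rank([])


class TestAdditivity:
    def _rec(self, label, barrier):
        r = scr.MutantRecord(spec=None, label=label)
        r.barrier_result = scr.BarrierResult(barrier, 5, 0, True)
        return r

    def test_exactly_additive_doubles_have_zero_residual(self):
        wt = self._rec("WT", 18.5)
        singles = [self._rec("A10W", 10.0), self._rec("A11F", 15.0)]
        doubles = [self._rec("A10W-A11F", 10.0 + 15.0 - 18.5)]
        df, summary = scr.additivity_analysis(singles, doubles, wt)
        assert summary["n_analysed"] == 1
        assert df["residual"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_residual_sign_and_magnitude(self):
        wt = self._rec("WT", 18.5)
        singles = [self._rec("A10W", 10.0), self._rec("A11F", 15.0)]
        doubles = [self._rec("A10W-A11F", 9.0)]
        df, summary = scr.additivity_analysis(singles, doubles, wt)
        # expected = 10 + 15 - 18.5 = 6.5; observed 9.0 -> residual +2.5
        assert df["residual"].iloc[0] == pytest.approx(2.5)
        assert summary["mean_residual"] == pytest.approx(2.5)

    def test_missing_single_excluded_not_crashed(self):
        wt = self._rec("WT", 18.5)
        singles = [self._rec("A10W", 10.0)]
        doubles = [self._rec("A10W-A11F", 7.0)]
        df, summary = scr.additivity_analysis(singles, doubles, wt)
        assert summary["n_analysed"] == 0
        assert summary["n_excluded"] == 1

    def test_display_cap_restricts_means(self):
        wt = self._rec("WT", 18.5)
        singles = [self._rec("A10W", 10.0), self._rec("A11F", 99.0)]
        df, summary = scr.additivity_analysis(singles, [], wt, display_cap=30.0)
        assert summary["mean_single_barrier"] == pytest.approx(10.0)

    def test_end_to_end_additive_screen(self, toy):
        # doubles not explicitly programmed fall back to additive offsets,
        # so the whole analysis closes to zero residual
        barriers = {"A10W": 10.0, "A11F": 15.0}
        gt = bs.GroundTruth(wt_barrier=18.5, mutant_barriers=barriers)
        ctx, settings_ = make_context(toy, gt)
        wt = scr.run_wild_type(ctx, settings_)
        positions = bs.detect_active_site(toy.ge, 4.0)
        singles = [s for s in bs.enumerate_single_mutants(positions, {1})
                   if s.label in barriers]
        srecs, _ = scr.screen(singles, wt, ctx, settings_)
        best = bs.best_per_position(srecs)
        doubles = bs.enumerate_double_mutants(best)
        drecs, _ = scr.screen(doubles, wt, ctx, settings_)
        df, summary = scr.additivity_analysis(srecs, drecs, wt)
        assert summary["n_analysed"] == 1
        assert abs(summary["max_abs_residual"]) < 1e-6


def _agree_records(counts, wt_raw=18.5, wt_reo=18.5):
    """Synthesize records realizing given quadrant counts."""
    recs = []
    i = 0
    deltas = {0: (1.0, 1.0), 1: (-1.0, 1.0), 2: (-1.0, -1.0), 3: (1.0, -1.0)}
    for q, n in enumerate(counts):
        for _ in range(n):
            r = scr.MutantRecord(spec=None, label=f"M{i}")
            dr, do = deltas[q]
            r.barrier_result = scr.BarrierResult(wt_raw + dr, 5, 0, True)
            r.reortho_barrier = wt_reo + do
            recs.append(r)
            i += 1
    return recs


class TestReorthoAgreement:
    def test_quadrant_classification_and_percentage(self):
        counts = (90, 14, 45, 20)
        recs = _agree_records(counts)
        res = scr.reortho_agreement(recs, 18.5, 18.5)
        assert res.quadrant_counts == counts
        assert res.n_total == 169
        assert res.agreement_pct == 80

    def test_equal_counts_as_higher(self):
        r = scr.MutantRecord(spec=None, label="M0")
        r.barrier_result = scr.BarrierResult(18.5, 5, 0, True)
        r.reortho_barrier = 18.5
        res = scr.reortho_agreement([r], 18.5, 18.5)
        assert res.quadrant_counts == (1, 0, 0, 0)

    def test_cap_excludes_large_barriers(self):
        recs = _agree_records((2, 0, 0, 0))
        big = scr.MutantRecord(spec=None, label="BIG")
        big.barrier_result = scr.BarrierResult(40.0, 5, 0, True)
        big.reortho_barrier = 20.0
        res = scr.reortho_agreement(recs + [big], 18.5, 18.5, cap=34.0)
        assert res.n_total == 2

    def test_records_without_reortho_skipped(self):
        recs = _agree_records((1, 0, 0, 0))
        plain = scr.MutantRecord(spec=None, label="P")
        plain.barrier_result = scr.BarrierResult(10.0, 5, 0, True)
        res = scr.reortho_agreement(recs + [plain], 18.5, 18.5)
        assert res.n_total == 1

    def test_counts_helper_matches(self):
        assert scr.agreement_from_counts((90, 14, 45, 20)) == 80
        assert scr.agreement_from_counts((0, 0, 0, 0)) == 0
        assert scr.agreement_from_counts((1, 0, 1, 0)) == 100

    def test_noisy_end_to_end_agreement(self, toy):
        # reorthogonalized energies carry seeded scatter; both variants of a
        # strongly shifted mutant still land on the same side of wild type
        barriers = {"A10W": 5.0, "A11C": 30.0}
        gt = bs.GroundTruth(wt_barrier=18.5, mutant_barriers=barriers)
        ctx, settings_ = make_context(toy, gt, reortho_sd=0.2, seed=11)
        settings_.engine_config = eng.EngineConfig(reorthogonalize=True)
        wt = scr.run_wild_type(ctx, settings_)
        assert wt.reortho_barrier is not None
        positions = bs.detect_active_site(toy.ge, 4.0)
        specs = [s for s in bs.enumerate_single_mutants(positions, {1})
                 if s.label in barriers]
        records, _ = scr.screen(specs, wt, ctx, settings_)
        res = scr.reortho_agreement(records, wt.barrier, wt.reortho_barrier)
        assert res.n_total == 2
        assert res.agreement_pct == 100


class TestRecordsToFrame:
    def test_columns_and_rows(self, toy):
        barriers = {"A10W": 6.9}
        wt, records, _ = _toy_screen(toy, barriers)
        df = scr.records_to_frame(records)
        assert set(df.columns) >= {"label", "barrier", "delta_vs_wt", "status"}
        assert len(df) == 1
        assert df["barrier"].iloc[0] == pytest.approx(6.9, abs=1e-6)
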