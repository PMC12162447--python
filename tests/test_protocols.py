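"""Protocol simulators: structure, determinism, and law conformity."""

import numpy as np
import pytest
from scipy import stats

from iotalearn.events import (
    conditional_rate,
    contextual_rate_iti,
    state_windows,
    write_events,
)
from iotalearn.info import retrospective_association, prospective_association
from iotalearn.protocols import (
    ProtocolConfig,
    gen_delay,
    gen_trace,
    gen_truly_random,
    gen_vi,
    run_virtual_subject,
)


def measured_iota(record, cs_label="cs:A", reinf="reinf:food"):
    cond = conditional_rate(record, reinf, state_windows(record, cs_label))
    ctx = conditional_rate(record, reinf, None)
    return cond.rate / ctx.rate


class TestDelay:
    def test_fixed_iti_informativeness_is_cycle_over_cs(self):
        cfg = ProtocolConfig(
            kind="delay", cs_seconds=5.0, iti_mean_seconds=1195.0,
            iti_distribution="fixed", n_trials=10, seed=1,
        )
        assert measured_iota(gen_delay(cfg)) == pytest.approx(240.0)

    def test_exponential_iti_informativeness_near_analytic(self):
        cfg = ProtocolConfig(
            kind="delay", cs_seconds=5.0, iti_mean_seconds=1195.0,
            iti_distribution="exponential", n_trials=200, seed=2,
        )
        assert measured_iota(gen_delay(cfg)) == pytest.approx(240.0, rel=0.15)

    def test_no_reinforcement_when_p_zero(self):
        cfg = ProtocolConfig(kind="delay", p_reinforce=0.0, n_trials=5, seed=3)
        rec = gen_delay(cfg)
        assert rec.times_of("reinf:food") == []

    def test_determinism(self):
        cfg = ProtocolConfig(kind="delay", n_trials=8, seed=11)
        assert write_events(gen_delay(cfg)) == write_events(gen_delay(cfg))

    def test_reinforcement_co_timed_with_cs_offset(self):
        cfg = ProtocolConfig(kind="delay", n_trials=4, iti_distribution="fixed", seed=0)
        rec = gen_delay(cfg)
        assert rec.times_of("reinf:food") == rec.times_of("cs_off:A")


class TestTrace:
    def _iota_gap(self, rec, gap_s):
        n_r = len(rec.times_of("reinf:food"))
        iti = contextual_rate_iti(rec, "reinf:food", ["cs:A", "gap:A"])
        return (1.0 / gap_s) / iti.rate

    def test_gap_informativeness_burke_regime(self):
        # gap 1 s, ITI mean ~600 s: iota ~ 600
        cfg = ProtocolConfig(
            kind="trace", cs_seconds=2.0, gap_seconds=1.0,
            iti_mean_seconds=600.0, iti_distribution="fixed", n_trials=50, seed=4,
        )
        rec = gen_trace(cfg)
        assert self._iota_gap(rec, 1.0) == pytest.approx(600.0, rel=0.02)

    def test_partial_reinforcement_raises_gap_informativeness(self):
        common = dict(
            kind="trace", cs_seconds=2.0, gap_seconds=5.0,
            iti_mean_seconds=300.0, iti_distribution="fixed", n_trials=400,
        )
        full = gen_trace(ProtocolConfig(**common, p_reinforce=1.0, seed=6))
        part = gen_trace(ProtocolConfig(**common, p_reinforce=0.5, seed=6))
        ratio = self._iota_gap(part, 5.0) / self._iota_gap(full, 5.0)
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_gap_state_only_on_reinforced_trials(self):
        cfg = ProtocolConfig(
            kind="trace", gap_seconds=3.0, p_reinforce=0.5, n_trials=100, seed=7,
        )
        rec = gen_trace(cfg)
        n_gaps = len(state_windows(rec, "gap:A").intervals)
        assert n_gaps == len(rec.times_of("reinf:food")) < 100

    def test_zero_gap_rejected(self):
        with pytest.raises(ValueError):
            ProtocolConfig(kind="trace", gap_seconds=0.0)


@pytest.fixture(scope="module")
def random_control_record():
    cfg = ProtocolConfig(
        kind="truly_random", cs_seconds=120.0, iti_mean_seconds=1080.0,
        n_trials=250, poisson_rate_per_second=0.25 / 60.0, seed=8,
    )
    return gen_truly_random(cfg)


@pytest.fixture(scope="module")
def vi_session_record():
    cfg = ProtocolConfig(
        kind="vi_single", vi_seconds=60.0, response_rate_per_second=1.0,
        session_seconds=40_000.0, seed=9,
    )
    return gen_vi(cfg)


class TestTrulyRandom:
    def test_cs_and_context_rates_equal(self, random_control_record):
        # ~125 shocks expected during CS time: sampling sd ~9% of the rate
        record = random_control_record
        cs = conditional_rate(record, "reinf:food", state_windows(record, "cs:A"))
        ctx = conditional_rate(record, "reinf:food", None)
        assert cs.rate == pytest.approx(ctx.rate, rel=0.25)
        assert ctx.rate == pytest.approx(0.25 / 60.0, rel=0.1)

    def test_counts_are_poisson_dispersed(self, random_control_record):
        # variance ~ mean for counts in consecutive 2-min bins
        record = random_control_record
        times = np.array(record.times_of("reinf:food"))
        bins = np.arange(0.0, record.t_end, 120.0)
        counts, _ = np.histogram(times, bins)
        assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.35)


class TestVI:
    def test_obtained_rate_matches_programmed(self, vi_session_record):
        n = len(vi_session_record.times_of("reinf:food"))
        assert n == pytest.approx(40_000 / 60.0, rel=0.1)

    def test_retrospective_contingency_is_one(self, vi_session_record):
        # every reinforcement co-timed with the triggering response
        a = retrospective_association(vi_session_record, "response:press", "reinf:food")
        assert a.maximal

    def test_prospective_association_near_zero_with_dense_responding(self, vi_session_record):
        a = prospective_association(vi_session_record, "response:press", "reinf:food", base=2)
        assert abs(a.value) < 0.6


class TestVirtualSubject:
    def test_high_informativeness_one_or_two_shot(self):
        cfg = ProtocolConfig(
            kind="delay", cs_seconds=5.0, iti_mean_seconds=1195.0,
            iti_distribution="fixed", n_trials=10, seed=10,
        )
        rec, log = run_virtual_subject(cfg, k_learn=100.0)
        assert log.acquisition_trial is not None and log.acquisition_trial <= 2
        assert len(rec.times_of("response:cr")) > 0

    def test_low_informativeness_needs_many_reinforcements(self):
        cfg = ProtocolConfig(
            kind="delay", cs_seconds=5.0, iti_mean_seconds=5.0,
            iti_distribution="fixed", n_trials=60, seed=10,
        )
        # iota = 2, k = 50: trade-off needs > 50 reinforcements
        rec, log = run_virtual_subject(cfg, k_learn=50.0)
        assert log.acquisition_trial is None or log.acquisition_trial > 50

    def test_extinction_stops_responding(self):
        cfg = ProtocolConfig(
            kind="delay", cs_seconds=5.0, iti_mean_seconds=595.0,
            iti_distribution="fixed", n_trials=25, seed=12,
        )
        rec, log = run_virtual_subject(cfg, k_learn=100.0, n_extinction_trials=40)
        assert log.acquisition_trial is not None
        assert log.extinction_trial is not None
        assert log.extinction_trial > 25  # during the extinction phase
        # no conditioned responses after the stop decision
        resp = rec.times_of("response:cr")
        cs_off = rec.times_of("cs_off:A")
        assert resp and max(resp) <= cs_off[log.extinction_trial - 1]


class TestLawConformity:
    def test_exponential_itis_pass_goodness_of_fit(self):
        cfg = ProtocolConfig(
            kind="delay", cs_seconds=1.0, iti_mean_seconds=50.0,
            iti_distribution="exponential", n_trials=1500, seed=14,
        )
        rec = gen_delay(cfg)
        cs_on = np.array(rec.times_of("cs_on:A"))
        cs_off = np.array(rec.times_of("cs_off:A"))
        itis = np.concatenate([[cs_on[0]], cs_on[1:] - cs_off[:-1]])
        # truncation at 10x the mean clips ~<0.005% of draws
        p = stats.kstest(itis, "expon", args=(0, itis.mean())).pvalue
        assert p > 0.01

    def test_every_generator_output_feeds_every_analysis(self):
        """Pipeline closure: rate queries and state windows work on all
        generator outputs without adapters."""
        records = [
            gen_delay(ProtocolConfig(kind="delay", n_trials=5, seed=1)),
            gen_trace(ProtocolConfig(kind="trace", gap_seconds=2.0, n_trials=5, seed=1)),
            gen_truly_random(
                ProtocolConfig(
                    kind="truly_random", poisson_rate_per_second=0.01,
                    n_trials=5, seed=1,
                )
            ),
            gen_vi(
                ProtocolConfig(
                    kind="vi_single", response_rate_per_second=0.5,
                    session_seconds=2000.0, seed=1,
                )
            ),
        ]
        for rec in records:
            ctx = conditional_rate(rec, "reinf:food", None)
            assert ctx.duration > 0
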