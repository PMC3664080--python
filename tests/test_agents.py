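"""Pseudo-agent decision logic, consult protocol and claim contention."""

import pytest

from edsim.agents import (
    ActionChoice,
    AgentState,
    EpisodeSpec,
    ProviderAgent,
    ProviderTeam,
    physician_next_action,
)
from edsim.distributions import DistributionSpec, RandomStreams
from edsim.kernel import Environment, SimulationError

C = DistributionSpec.constant


@pytest.mark.parametrize("high, consult, low, expected", [
    (2, True, 5, ActionChoice.TREAT_HIGH),   # higher priority before anything else
    (1, False, 0, ActionChoice.TREAT_HIGH),
    (0, True, 5, ActionChoice.ANSWER_CONSULT),
    (0, False, 3, ActionChoice.TREAT_LOW),
    (0, False, 0, ActionChoice.GO_IDLE),
])
def test_physician_decision_hierarchy(high, consult, low, expected):
    assert physician_next_action(high, consult, low) is expected


def test_negative_queue_lengths_rejected():
    with pytest.raises(ValueError):
        physician_next_action(-1, False, 0)


def test_assessing_reachable_only_for_delegate():
    env = Environment()
    phys = ProviderAgent(env, "physician")
    with pytest.raises(SimulationError):
        phys.set_state(AgentState.ASSESSING)


class _P:
    """Minimal patient stub for team-level tests."""

    def __init__(self, pid, acuity, arrival=0.0):
        self.id = pid
        self.acuity = acuity
        self.arrival = arrival
        self.provider = None
        self.provider_start = None
        self.provider_done = None
        self.provider_time = None
        self.provider_queued = None
        self.provider_reply = None


def _team(env, enabled=True, tie_break="delegate_first", preempt=False, consult=5.0):
    if enabled:
        spec = EpisodeSpec(
            physician_high=[(AgentState.TREATING, C(20.0))],
            physician_low=[(AgentState.TREATING, C(10.0))],
            delegate_pre=[(AgentState.ASSESSING, C(20.0))],
            delegate_post=[(AgentState.TREATING, C(5.0))],
            consult=C(consult),
            consult_preempts_low=preempt,
        )
    else:
        spec = EpisodeSpec(
            physician_high=[(AgentState.TREATING, C(20.0))],
            physician_low=[(AgentState.TREATING, C(10.0))],
            delegate_pre=[(AgentState.TREATING, C(20.0))],
            delegate_post=[],
            consult=None,
        )
    team = ProviderTeam(env, spec, RandomStreams(0), tie_break=tie_break)
    team.start()
    return team


def _drive(env, team, patients):
    for t, p in patients:
        def feeder(t=t, p=p):
            yield env.timeout(t - env.now if t > env.now else 0.0)
            team.add_patient(p)
        env.process(feeder())


class TestDelegateEpisode:
    def test_enabled_stage_minutes_sum_excluding_consult_wait(self):
        # assess 20 + consult 5 + implement 5 = 30 busy minutes per patient
        env = Environment()
        team = _team(env, enabled=True)
        p = _P(1, "low")
        _drive(env, team, [(0.0, p)])
        env.run(until=100.0)
        assert p.provider == "delegate"
        assert p.provider_time == pytest.approx(30.0)
        assert team.delegate.busy_time(0.0, 100.0) == pytest.approx(30.0)

    def test_disabled_episode_is_twenty_minutes(self):
        env = Environment()
        team = _team(env, enabled=False)
        p = _P(1, "low")
        _drive(env, team, [(0.0, p)])
        env.run(until=100.0)
        assert p.provider_time == pytest.approx(20.0)
        assert p.provider_done == pytest.approx(20.0)

    def test_high_acuity_patient_to_delegate_is_hard_error(self):
        env = Environment()
        team = _team(env, enabled=True)
        p = _P(1, "high")
        def inject():  # bypass acuity routing on purpose, after agents boot
            yield env.timeout(1.0)
            team.low_queue.append(p)
            team.patient_waiting.send(sort_key=team._wake_key)  # delegate first
        env.process(inject())
        with pytest.raises(SimulationError, match="low-acuity"):
            env.run(until=10.0)

    def test_consult_interval_identical_for_both_agents(self):
        env = Environment()
        team = _team(env, enabled=True)
        _drive(env, team, [(0.0, _P(1, "low"))])
        env.run(until=100.0)
        team.close_logs()
        phys_c = [(a, b) for s, a, b in team.physician.intervals if s is AgentState.CONSULTING]
        dele_c = [(a, b) for s, a, b in team.delegate.intervals if s is AgentState.CONSULTING]
        assert phys_c == dele_c == [(20.0, 25.0)]

    def test_consult_waits_for_high_acuity_treatment(self):
        # physician busy with a high-acuity patient when the request is
        # raised: the consult starts only after that treatment ends
        env = Environment()
        team = _team(env, enabled=True)
        _drive(env, team, [(0.0, _P(1, "low")), (15.0, _P(2, "high"))])
        env.run(until=200.0)
        team.close_logs()
        phys_c = [(a, b) for s, a, b in team.physician.intervals if s is AgentState.CONSULTING]
        assert phys_c == [(35.0, 40.0)]  # high treatment 15..35, then consult
        assert team.delegate.state_time(AgentState.AWAITING_CONSULT) == pytest.approx(15.0)

    def test_consult_symmetry_over_a_run(self):
        import numpy as np
        env = Environment()
        team = _team(env, enabled=True)
        rng = np.random.default_rng(3)
        t, pats = 0.0, []
        for i in range(40):
            t += rng.exponential(12.0)
            pats.append((t, _P(i, "high" if rng.random() < 0.2 else "low")))
        _drive(env, team, pats)
        env.run(until=3000.0)
        team.close_logs()
        assert team.physician.state_time(AgentState.CONSULTING) == pytest.approx(
            team.delegate.state_time(AgentState.CONSULTING))

    def test_preemption_pauses_low_treatment_for_consult(self):
        env = Environment()
        team = _team(env, enabled=True, preempt=True)
        # delegate takes p1 at t=0 (assess until 20); physician takes p2 at
        # t=10 (low, 10 min). At t=20 the consult request preempts it.
        _drive(env, team, [(0.0, _P(1, "low")), (10.0, _P(2, "low"))])
        env.run(until=100.0)
        team.close_logs()
        phys_c = [(a, b) for s, a, b in team.physician.intervals if s is AgentState.CONSULTING]
        assert phys_c == [(20.0, 25.0)]
        p2_treat = [(a, b) for s, a, b in team.physician.intervals if s is AgentState.TREATING]
        assert p2_treat == [(10.0, 20.0)]  # second segment resumes below
        assert team.delegate.state_time(AgentState.AWAITING_CONSULT) == 0.0


class TestClaiming:
    def test_high_acuity_goes_to_physician_even_if_both_idle(self):
        env = Environment()
        team = _team(env, enabled=False)
        p = _P(1, "high")
        _drive(env, team, [(0.0, p)])
        env.run(until=50.0)
        assert p.provider == "physician"

    def test_low_acuity_claimed_by_only_idle_agent(self):
        env = Environment()
        team = _team(env, enabled=False, tie_break="physician_first")
        p1, p2 = _P(1, "high"), _P(2, "low")
        _drive(env, team, [(0.0, p1), (1.0, p2)])
        env.run(until=50.0)
        assert p1.provider == "physician" and p2.provider == "delegate"

    @pytest.mark.parametrize("tie_break, winner", [
        ("delegate_first", "delegate"),
        ("physician_first", "physician"),
    ])
    def test_both_idle_tie_break(self, tie_break, winner):
        env = Environment()
        team = _team(env, enabled=False, tie_break=tie_break)
        p = _P(1, "low")
        _drive(env, team, [(5.0, p)])
        env.run(until=50.0)
        assert p.provider == winner

    def test_idle_longest_claims_first(self):
        env = Environment()
        team = _team(env, enabled=False, tie_break="idle_longest")
        p1, p2, p3 = _P(1, "low"), _P(2, "low"), _P(3, "low")
        # p1 -> delegate-or-physician; loser of that claim has been idle
        # longer when p3 arrives after both are free again
        _drive(env, team, [(0.0, p1), (0.0, p2), (60.0, p3)])
        env.run(until=200.0)
        assert {p1.provider, p2.provider} == {"physician", "delegate"}
        # physician finished p at t=10/20, delegate at 20: physician idled longest
        assert p3.provider == "physician"

    def test_one_patient_two_waiters_exactly_one_claims(self):
        # exhaustive check of the contention protocol on a 1-patient scenario
        for tie_break in ("idle_longest", "delegate_first", "physician_first", "random"):
            env = Environment()
            team = _team(env, enabled=False, tie_break=tie_break)
            p = _P(1, "low")
            _drive(env, team, [(3.0, p)])
            env.run(until=60.0)
            team.close_logs()
            assert p.provider in ("physician", "delegate")
            total_busy = (team.physician.busy_time(0, 60) + team.delegate.busy_time(0, 60))
            expected = 10.0 if p.provider == "physician" else 20.0
            assert total_busy == pytest.approx(expected)  # the other agent re-held

    def test_unknown_tie_break_rejected(self):
        env = Environment()
        spec = EpisodeSpec([], [], [], [], None)
        with pytest.raises(ValueError):
            ProviderTeam(env, spec, RandomStreams(0), tie_break="coin_toss")


def test_agent_activity_log_contiguous_and_non_overlapping():
    env = Environment()
    team = _team(env, enabled=True)
    import numpy as np
    rng = np.random.default_rng(11)
    t, pats = 0.0, []
    for i in range(60):
        t += rng.exponential(10.0)
        pats.append((t, _P(i, "high" if rng.random() < 0.2 else "low")))
    _drive(env, team, pats)
    env.run(until=4000.0)
    team.close_logs()
    for agent in (team.physician, team.delegate):
        iv = agent.intervals
        assert all(b > a for _s, a, b in iv)
        assert all(iv[i][2] == iv[i + 1][1] for i in range(len(iv) - 1))  # contiguous
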