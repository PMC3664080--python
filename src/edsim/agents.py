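"""Physician and delegate modeled as interacting pseudo-agents.

A pseudo-agent is a simulation *entity* with embedded hierarchical decision
logic, not a passive capacitated resource.  Two provider agents are modeled:

* the **physician**, who treats high-acuity patients before anything else,
  then answers a pending consult from the delegate, then treats a
  low-acuity patient, and otherwise goes idle;
* the **delegate** (resident / physician assistant / nurse practitioner),
  who only treats low-acuity patients and — when interaction is enabled —
  must review the treatment plan with the physician (a consult occupying
  both providers for the same interval) before proceeding to treatment.

Idle agents are held on broadcast signal channels: ``patient_waiting`` is
sent to both agents when a patient joins a queue, ``consult_request`` is
sent by the delegate to the physician.  When several idle agents could
claim the same low-acuity patient, a configurable tie-break decides who
does (``idle_longest`` by default).
"""

from __future__ import annotations

from collections import deque
from collections.abc import Callable, Generator, Sequence
from dataclasses import dataclass
from enum import Enum
from typing import Any

from .distributions import DistributionSpec, RandomStreams
from .kernel import Environment, Event, SignalChannel, SimulationError

__all__ = [
    "ActionChoice",
    "AgentState",
    "EpisodeSpec",
    "ProviderAgent",
    "ProviderTeam",
    "Stage",
    "physician_next_action",
]

TIE_BREAKS = ("idle_longest", "delegate_first", "physician_first", "random")


class AgentState(str, Enum):
    IDLE = "idle"
    ASSESSING = "assessing"          # delegate only: developing the treatment plan
    CONSULTING = "consulting"
    TREATING = "treating"
    AWAITING_CONSULT = "awaiting_consult"  # delegate holding for the physician; idle-type

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: states that count toward utilization (patient-related activity)
BUSY_STATES = frozenset({AgentState.ASSESSING, AgentState.CONSULTING, AgentState.TREATING})


class ActionChoice(Enum):
    TREAT_HIGH = "treat_high"
    ANSWER_CONSULT = "answer_consult"
    TREAT_LOW = "treat_low"
    GO_IDLE = "go_idle"


def physician_next_action(
    high_queue_len: int, consult_pending: bool, low_queue_len: int
) -> ActionChoice:
    """The physician's decision hierarchy at a decision epoch.

    High-acuity patients come before anything else; next the physician
    attends to a delegate waiting for guidance; next a low-acuity patient;
    otherwise the physician goes idle.
    """
    if high_queue_len < 0 or low_queue_len < 0:
        raise ValueError("queue lengths must be non-negative")
    if high_queue_len > 0:
        return ActionChoice.TREAT_HIGH
    if consult_pending:
        return ActionChoice.ANSWER_CONSULT
    if low_queue_len > 0:
        return ActionChoice.TREAT_LOW
    return ActionChoice.GO_IDLE


class ProviderAgent:
    """One provider pseudo-agent: role, state machine and activity log."""

    __slots__ = ("role", "state", "intervals", "_state_since", "idle_since", "env")

    def __init__(self, env: Environment, role: str) -> None:
        if role not in ("physician", "delegate"):
            raise ValueError(f"unknown provider role {role!r}")
        self.env = env
        self.role = role
        self.state = AgentState.IDLE
        self.intervals: list[tuple[AgentState, float, float]] = []
        self._state_since = env.now
        self.idle_since = env.now

    def set_state(self, new: AgentState) -> None:
        if new is AgentState.ASSESSING and self.role != "delegate":
            raise SimulationError("only the delegate assesses patients (treatment-plan work-up)")
        now = self.env.now
        if now > self._state_since:
            self.intervals.append((self.state, self._state_since, now))
        self.state = new
        self._state_since = now
        if new is AgentState.IDLE:
            self.idle_since = now

    def close_log(self) -> None:
        """Flush the open interval at the end of a run."""
        now = self.env.now
        if now > self._state_since:
            self.intervals.append((self.state, self._state_since, now))
            self._state_since = now

    def busy_time(self, start: float = 0.0, end: float | None = None) -> float:
        """Patient-related activity time within [start, end] (consults included)."""
        self.close_log()
        end = self.env.now if end is None else end
        total = 0.0
        for state, a, b in self.intervals:
            if state in BUSY_STATES:
                total += max(0.0, min(b, end) - max(a, start))
        return total

    def state_time(self, state: AgentState, start: float = 0.0, end: float | None = None) -> float:
        self.close_log()
        end = self.env.now if end is None else end
        return sum(
            max(0.0, min(b, end) - max(a, start)) for s, a, b in self.intervals if s is state
        )


Stage = tuple[AgentState, DistributionSpec]


@dataclass
class EpisodeSpec:
    """Stage structure of a provider episode, per patient class.

    ``consult`` of ``None`` disables the interaction: the delegate then runs
    ``delegate_pre`` followed by ``delegate_post_no_consult``.  With
    interaction on, the order is pre-stages, consult request + joint consult,
    then ``delegate_post`` (treatment and plan implementation).
    """

    physician_high: Sequence[Stage]
    physician_low: Sequence[Stage]
    delegate_pre: Sequence[Stage]
    delegate_post: Sequence[Stage]
    consult: DistributionSpec | None = None
    delegate_post_no_consult: Sequence[Stage] | None = None
    #: optional variant: a consult request pauses an in-progress low-acuity
    #: treatment (the physician answers at once unless a high-acuity patient
    #: is queued); high-acuity work is never interrupted.  Off by default:
    #: the physician answers pending consults at its next decision epoch.
    consult_preempts_low: bool = False

    def delegate_stages_after_pre(self) -> Sequence[Stage]:
        if self.consult is not None:
            return self.delegate_post
        if self.delegate_post_no_consult is not None:
            return self.delegate_post_no_consult
        return self.delegate_post


class ProviderTeam:
    """The physician/delegate pair, their queues, signals and protocol.

    Patients are handed over with :meth:`add_patient`; the team wakes idle
    agents through the ``patient_waiting`` channel, runs the provider
    episode, stamps ``provider_start`` / ``provider_done`` /
    ``provider_time`` / ``provider`` on the patient and fires the patient's
    ``provider_reply`` event (if present) so a flow process can continue.
    """

    def __init__(
        self,
        env: Environment,
        episode: EpisodeSpec,
        streams: RandomStreams,
        tie_break: str = "idle_longest",
        on_done: Callable[[Any], None] | None = None,
    ) -> None:
        if tie_break not in TIE_BREAKS:
            raise ValueError(f"tie_break must be one of {TIE_BREAKS}, got {tie_break!r}")
        self.env = env
        self.episode = episode
        self.streams = streams
        self.tie_break = tie_break
        self.on_done = on_done
        self.physician = ProviderAgent(env, "physician")
        self.delegate = ProviderAgent(env, "delegate")
        self.high_queue: deque[Any] = deque()
        self.low_queue: deque[Any] = deque()
        self.patient_waiting = SignalChannel(env, "patient_waiting")
        self.consult_request = SignalChannel(env, "consult_request")
        self.consult_pending: ProviderAgent | None = None
        self._consult_reply: Event | None = None
        self._tb_rng = streams.get("tie_break")
        self._started = False

    # -- dispatch order --------------------------------------------------
    def _wake_key(self, agent: Any) -> tuple:
        """Sort key ordering simultaneous wake-ups (first key claims first)."""
        if not isinstance(agent, ProviderAgent):
            return (2, 0.0)
        if self.tie_break == "idle_longest":
            return (0, agent.idle_since)
        if self.tie_break == "delegate_first":
            return (0, 0.0 if agent.role == "delegate" else 1.0)
        if self.tie_break == "physician_first":
            return (0, 0.0 if agent.role == "physician" else 1.0)
        return (0, self._tb_rng.random())

    def start(self) -> None:
        if self._started:
            raise SimulationError("provider team already started")
        self._started = True
        self.env.process(self._physician_proc())
        self.env.process(self._delegate_proc())

    # -- patient intake --------------------------------------------------
    def add_patient(self, patient: Any) -> None:
        """Queue a patient by acuity and alert both agents."""
        patient.provider_queued = self.env.now
        if patient.acuity == "high":
            self.high_queue.append(patient)
        else:
            self.low_queue.append(patient)
        self.patient_waiting.send(sort_key=self._wake_key)

    # -- physician -------------------------------------------------------
    def _physician_proc(self) -> Generator[Event, Any, None]:
        env = self.env
        phys = self.physician
        while True:
            choice = physician_next_action(
                len(self.high_queue), self.consult_pending is not None, len(self.low_queue)
            )
            if choice is ActionChoice.TREAT_HIGH:
                yield from self._serve(phys, self.high_queue.popleft(), self.episode.physician_high)
            elif choice is ActionChoice.ANSWER_CONSULT:
                yield from self._answer_consult()
            elif choice is ActionChoice.TREAT_LOW:
                yield from self._serve(
                    phys,
                    self.low_queue.popleft(),
                    self.episode.physician_low,
                    interruptible=self.episode.consult is not None
                    and self.episode.consult_preempts_low,
                )
            else:
                phys.set_state(AgentState.IDLE)
                wake = env.event()
                self.patient_waiting.attach(wake, phys)
                self.consult_request.attach(wake, phys)
                yield wake

    def _answer_consult(self) -> Generator[Event, Any, None]:
        if self.consult_pending is None or self._consult_reply is None:
            raise SimulationError("consult invoked with no pending request")
        if self.episode.consult is None:
            raise SimulationError("consult requested but interaction is disabled")
        self.consult_pending = None
        reply, self._consult_reply = self._consult_reply, None
        duration = self.episode.consult.sample(self.streams.get("consult"))
        self.physician.set_state(AgentState.CONSULTING)
        reply.trigger(duration)
        yield self.env.timeout(duration)
        # the delegate logs the identical CONSULTING interval on its side

    # -- delegate --------------------------------------------------------
    def _delegate_proc(self) -> Generator[Event, Any, None]:
        env = self.env
        dele = self.delegate
        while True:
            if self.low_queue:
                yield from self._delegate_episode(self.low_queue.popleft())
            else:
                dele.set_state(AgentState.IDLE)
                yield self.patient_waiting.hold(dele)

    def _delegate_episode(self, patient: Any) -> Generator[Event, Any, None]:
        if patient.acuity != "low":
            raise SimulationError("the delegate only treats low-acuity patients")
        dele = self.delegate
        patient.provider = dele.role
        patient.provider_start = self.env.now
        busy = 0.0
        for state, dist in self.episode.delegate_pre:
            dur = dist.sample(self.streams.get(f"delegate_{state.value}"))
            dele.set_state(state)
            busy += dur
            yield self.env.timeout(dur)
        if self.episode.consult is not None:
            if self.consult_pending is not None:
                raise SimulationError("a consult request is already pending (single delegate)")
            self.consult_pending = dele
            reply = self._consult_reply = self.env.event()
            dele.set_state(AgentState.AWAITING_CONSULT)
            self.consult_request.send(sort_key=self._wake_key)
            duration = yield reply  # physician answers with the joint duration
            dele.set_state(AgentState.CONSULTING)
            busy += duration
            yield self.env.timeout(duration)
        for state, dist in self.episode.delegate_stages_after_pre():
            dur = dist.sample(self.streams.get(f"delegate_{state.value}"))
            dele.set_state(state)
            busy += dur
            yield self.env.timeout(dur)
        self._finish(dele, patient, busy)

    # -- shared ----------------------------------------------------------
    def _serve(
        self,
        agent: ProviderAgent,
        patient: Any,
        stages: Sequence[Stage],
        interruptible: bool = False,
    ) -> Generator[Event, Any, None]:
        patient.provider = agent.role
        patient.provider_start = self.env.now
        busy = 0.0
        for state, dist in stages:
            dur = dist.sample(self.streams.get(f"{agent.role}_{state.value}_{patient.acuity}"))
            busy += dur
            if not interruptible:
                agent.set_state(state)
                yield self.env.timeout(dur)
                continue
            remaining = dur
            while remaining > 1e-9:
                agent.set_state(state)
                if self.consult_pending is not None and not self.high_queue:
                    # a request raised while the physician was consulting or
                    # serving a high-acuity patient is answered first
                    yield from self._answer_consult()
                    agent.set_state(state)
                seg_start = self.env.now
                timer = self.env.timeout(remaining)
                wake = self.env.event()
                self.consult_request.attach(wake, agent)
                yield self.env.any_of([timer, wake])
                remaining -= self.env.now - seg_start
                if remaining <= 1e-9:
                    break
                if self.consult_pending is not None and not self.high_queue:
                    yield from self._answer_consult()
                # otherwise: spurious wake (request already handled or a
                # high-acuity patient is queued) — resume the treatment
        self._finish(agent, patient, busy)

    def _finish(self, agent: ProviderAgent, patient: Any, busy: float) -> None:
        patient.provider_done = self.env.now
        patient.provider_time = busy
        if self.on_done is not None:
            self.on_done(patient)
        reply = getattr(patient, "provider_reply", None)
        if reply is not None:
            reply.trigger(patient)

    def close_logs(self) -> None:
        self.physician.close_log()
        self.delegate.close_log()
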