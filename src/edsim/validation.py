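"""The bare validation model for the pseudo-agent building blocks.

A deliberately simple system — no beds, nurses or routing — so any
difference between run modes reflects the provider-dispatch programming
rather than system feedback.  Patients arrive with exponential
inter-arrival times (mean 12 min, i.e. about 5/h; 20% high acuity), queue
for treatment and are discharged when treatment completes.  Treatment times
are fixed constants: 20 min for high acuity, 10 min for low acuity, plus
10 min whenever the delegate does the treating.  With interaction enabled
the delegate also spends 5 min consulting with the physician (occupying
both) and 5 further minutes implementing the plan.

Three run modes:

* ``conventional``    — providers as passive resources under a greedy
  work-conserving dispatcher (the traditional construction);
* ``pseudo_disabled`` — providers as pseudo-agents, consults switched off;
* ``pseudo_enabled``  — pseudo-agents with the consult protocol.

Under common random numbers the first two must produce identical patient
trajectories; enabling interaction raises both utilizations and the
low-acuity time to disposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Generator

import numpy as np
import pandas as pd

from .agents import AgentState, EpisodeSpec, ProviderTeam
from .distributions import DistributionSpec, RandomStreams
from .kernel import Environment, Event
from .stats import BatchCI, replication_ci

__all__ = [
    "MODES",
    "ValidationConfig",
    "ValidationPatient",
    "ValidationResult",
    "run_replication",
    "run_validation",
    "time_to_disposition",
]

MODES = ("conventional", "pseudo_disabled", "pseudo_enabled")

#: result strata: (provider, acuity)
STRATA = (("physician", "high"), ("physician", "low"), ("delegate", "low"))


@dataclass
class ValidationConfig:
    interarrival_mean: float = 12.0   # minutes; about 5 patients/hour
    p_high: float = 0.20
    treat_high: float = 20.0          # minutes, fixed
    treat_low: float = 10.0
    delegate_extra: float = 10.0      # surcharge when the delegate treats
    consult: float = 5.0              # joint physician+delegate interval
    implement: float = 5.0            # delegate implements the plan
    warmup_hours: float = 24.0
    record_hours: float = 24.0
    replications: int = 500
    mode: str = "conventional"
    tie_break: str = "delegate_first"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0.0 <= self.p_high <= 1.0:
            raise ValueError("p_high must be in [0, 1]")
        for name in ("interarrival_mean", "treat_high", "treat_low", "delegate_extra",
                     "consult", "implement"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ValidationPatient:
    id: int
    arrival: float
    acuity: str
    provider: str | None = None
    provider_start: float | None = None
    provider_done: float | None = None
    provider_time: float | None = None
    provider_queued: float | None = None
    provider_reply: Any = None

    def trajectory(self) -> tuple:
        """The tuple compared bit-for-bit across run modes."""
        return (self.id, self.arrival, self.acuity, self.provider,
                self.provider_start, self.provider_done)


@dataclass
class ReplicationOutput:
    utilization_physician: float
    utilization_delegate: float
    ttd: dict[tuple[str, str], float]          # stratum -> mean minutes (nan if empty)
    n_disposed: dict[tuple[str, str], int]
    arrivals: int
    completed: int
    in_system: int
    p_low_physician: float                      # share of low-acuity treated by physician
    trajectories: list[tuple]


@dataclass
class ValidationResult:
    mode: str
    replications: int
    utilization_physician: BatchCI
    utilization_delegate: BatchCI
    ttd_physician_high: BatchCI
    ttd_physician_low: BatchCI
    ttd_delegate_low: BatchCI
    p_low_physician: float
    per_replication: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, ci, unit in [
            ("Utilization: physician", self.utilization_physician, "fraction"),
            ("Utilization: delegate", self.utilization_delegate, "fraction"),
            ("Time to disposition: physician (high acuity)", self.ttd_physician_high, "minutes"),
            ("Time to disposition: physician (low acuity)", self.ttd_physician_low, "minutes"),
            ("Time to disposition: delegate (low acuity)", self.ttd_delegate_low, "minutes"),
        ]:
            rows.append({
                "measure": label, "mode": self.mode, "mean": ci.mean,
                "ci_lo": ci.lo, "ci_hi": ci.hi, "unit": unit,
            })
        return pd.DataFrame(rows)


def time_to_disposition(patients: list[ValidationPatient], start: float, end: float):
    """Mean arrival-to-exit minutes by (provider, acuity) stratum.

    Only patients disposed inside [start, end] contribute; patients with an
    incomplete timestamp trail are excluded and counted separately.
    """
    sums: dict[tuple[str, str], float] = {s: 0.0 for s in STRATA}
    counts: dict[tuple[str, str], int] = {s: 0 for s in STRATA}
    excluded = 0
    for p in patients:
        if p.provider_done is None or p.provider is None:
            excluded += 1
            continue
        if not (start <= p.provider_done <= end):
            continue
        key = (p.provider, p.acuity)
        sums[key] += p.provider_done - p.arrival
        counts[key] += 1
    means = {s: (sums[s] / counts[s] if counts[s] else float("nan")) for s in STRATA}
    return means, counts, excluded


# ---------------------------------------------------------------------------
# conventional construction: providers as passive resources under a dispatcher
# ---------------------------------------------------------------------------

class _ConventionalModel:
    """Greedy work-conserving dispatcher over two passive provider resources.

    High-acuity patients are served by the physician only, with priority;
    low-acuity patients go to any free provider (the physician only when no
    high-acuity patient waits), with the same idle-ordering tie-break as the
    pseudo-agent team so the two constructions are trajectory-equivalent.
    """

    def __init__(self, env: Environment, cfg: ValidationConfig) -> None:
        self.env = env
        self.cfg = cfg
        self.high_queue: list[ValidationPatient] = []
        self.low_queue: list[ValidationPatient] = []
        self.idle: dict[str, float] = {"physician": 0.0, "delegate": 0.0}  # role -> idle_since
        self.busy_intervals: dict[str, list[tuple[AgentState, float, float]]] = {
            "physician": [], "delegate": []
        }
        self.completed: list[ValidationPatient] = []

    def add_patient(self, p: ValidationPatient) -> None:
        (self.high_queue if p.acuity == "high" else self.low_queue).append(p)
        self.dispatch()

    def _service_minutes(self, role: str, acuity: str) -> float:
        cfg = self.cfg
        if acuity == "high":
            return cfg.treat_high
        return cfg.treat_low + (cfg.delegate_extra if role == "delegate" else 0.0)

    def _pick_idle_for_low(self) -> str | None:
        eligible = [r for r in ("physician", "delegate") if r in self.idle]
        if "physician" in eligible and self.high_queue:
            eligible.remove("physician")
        if not eligible:
            return None
        if self.cfg.tie_break == "delegate_first":
            order = {"delegate": 0.0, "physician": 1.0}
            return min(eligible, key=lambda r: order[r])
        if self.cfg.tie_break == "physician_first":
            order = {"physician": 0.0, "delegate": 1.0}
            return min(eligible, key=lambda r: order[r])
        # idle_longest: smaller idle_since first; physician wins exact ties,
        # matching the agent processes' channel registration order.
        return min(eligible, key=lambda r: (self.idle[r], r != "physician"))

    def dispatch(self) -> None:
        while self.high_queue and "physician" in self.idle:
            self._start("physician", self.high_queue.pop(0))
        while self.low_queue:
            role = self._pick_idle_for_low()
            if role is None:
                break
            self._start(role, self.low_queue.pop(0))

    def _start(self, role: str, p: ValidationPatient) -> None:
        del self.idle[role]
        dur = self._service_minutes(role, p.acuity)
        p.provider = role
        p.provider_start = self.env.now
        p.provider_time = dur
        self.busy_intervals[role].append((AgentState.TREATING, self.env.now, self.env.now + dur))
        self.env.process(self._complete(role, p, dur))

    def _complete(self, role: str, p: ValidationPatient, dur: float) -> Generator[Event, Any, None]:
        yield self.env.timeout(dur)
        p.provider_done = self.env.now
        self.completed.append(p)
        self.idle[role] = self.env.now
        self.dispatch()


# ---------------------------------------------------------------------------
# replication driver
# ---------------------------------------------------------------------------

def _episode_spec(cfg: ValidationConfig, enabled: bool) -> EpisodeSpec:
    c = DistributionSpec.constant
    assess = cfg.treat_low + cfg.delegate_extra  # delegate develops the plan
    if enabled:
        return EpisodeSpec(
            physician_high=[(AgentState.TREATING, c(cfg.treat_high))],
            physician_low=[(AgentState.TREATING, c(cfg.treat_low))],
            delegate_pre=[(AgentState.ASSESSING, c(assess))],
            delegate_post=[(AgentState.TREATING, c(cfg.implement))],
            consult=c(cfg.consult),
        )
    return EpisodeSpec(
        physician_high=[(AgentState.TREATING, c(cfg.treat_high))],
        physician_low=[(AgentState.TREATING, c(cfg.treat_low))],
        delegate_pre=[(AgentState.TREATING, c(assess))],
        delegate_post=[],
        consult=None,
    )


def run_replication(cfg: ValidationConfig, streams: RandomStreams) -> ReplicationOutput:
    """One independent replication: warm-up plus recording day."""
    env = Environment()
    horizon = (cfg.warmup_hours + cfg.record_hours) * 60.0
    w_start = cfg.warmup_hours * 60.0
    patients: list[ValidationPatient] = []

    if cfg.mode == "conventional":
        model = _ConventionalModel(env, cfg)
        sink = model.add_patient
    else:
        team = ProviderTeam(
            env,
            _episode_spec(cfg, enabled=(cfg.mode == "pseudo_enabled")),
            streams,
            tie_break=cfg.tie_break,
        )
        team.start()
        sink = team.add_patient

    def arrivals() -> Generator[Event, Any, None]:
        rng_arr = streams.get("arrival")
        rng_ac = streams.get("acuity")
        i = 0
        while True:
            yield env.timeout(rng_arr.exponential(cfg.interarrival_mean))
            i += 1
            p = ValidationPatient(
                id=i, arrival=env.now,
                acuity="high" if rng_ac.random() < cfg.p_high else "low",
            )
            patients.append(p)
            sink(p)

    env.process(arrivals())
    env.run(until=horizon)

    if cfg.mode == "conventional":
        logs = model.busy_intervals
        busy = {
            role: sum(min(b, horizon) - max(a, w_start)
                      for _s, a, b in iv if min(b, horizon) > max(a, w_start))
            for role, iv in logs.items()
        }
    else:
        team.close_logs()
        busy = {
            "physician": team.physician.busy_time(w_start, horizon),
            "delegate": team.delegate.busy_time(w_start, horizon),
        }

    record = cfg.record_hours * 60.0
    ttd, counts, _excl = time_to_disposition(patients, w_start, horizon)
    done = [p for p in patients if p.provider_done is not None]
    n_low_done = sum(1 for p in done if p.acuity == "low")
    n_low_phys = sum(1 for p in done if p.acuity == "low" and p.provider == "physician")
    return ReplicationOutput(
        utilization_physician=busy["physician"] / record,
        utilization_delegate=busy["delegate"] / record,
        ttd=ttd,
        n_disposed=counts,
        arrivals=len(patients),
        completed=len(done),
        in_system=len(patients) - len(done),
        p_low_physician=(n_low_phys / n_low_done) if n_low_done else float("nan"),
        trajectories=[p.trajectory() for p in patients],
    )


def run_validation(cfg: ValidationConfig) -> ValidationResult:
    """Run ``cfg.replications`` independent replications and aggregate.

    Replication r uses the substream family ``(seed, r)``; the three run
    modes therefore share arrival and acuity streams replication-by-
    replication (common random numbers).
    """
    if cfg.replications < 2:
        raise ValueError("confidence intervals require at least 2 replications")
    base = RandomStreams(cfg.seed)
    reps = [run_replication(cfg, base.child(r)) for r in range(cfg.replications)]

    frame = pd.DataFrame({
        "utilization_physician": [r.utilization_physician for r in reps],
        "utilization_delegate": [r.utilization_delegate for r in reps],
        "ttd_physician_high": [r.ttd[("physician", "high")] for r in reps],
        "ttd_physician_low": [r.ttd[("physician", "low")] for r in reps],
        "ttd_delegate_low": [r.ttd[("delegate", "low")] for r in reps],
        "arrivals": [r.arrivals for r in reps],
        "completed": [r.completed for r in reps],
        "p_low_physician": [r.p_low_physician for r in reps],
    })
    return ValidationResult(
        mode=cfg.mode,
        replications=cfg.replications,
        utilization_physician=replication_ci(frame["utilization_physician"]),
        utilization_delegate=replication_ci(frame["utilization_delegate"]),
        ttd_physician_high=replication_ci(frame["ttd_physician_high"]),
        ttd_physician_low=replication_ci(frame["ttd_physician_low"]),
        ttd_delegate_low=replication_ci(frame["ttd_delegate_low"]),
        p_low_physician=float(np.nanmean(frame["p_low_physician"])),
        per_replication=frame,
    )
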