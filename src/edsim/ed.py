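"""Hospital emergency-department patient-flow model.

Patients arrive (walk-in or ambulance) on an hourly/daily schedule scaled to
roughly 50,000 patients a year, are triaged (CTAS 1-5), registered, admitted
to one of the beds once the charge nurse and a bed are both available (with
a leave-without-being-seen risk that grows with the wait), assessed by a
bedside nurse, then treated by the physician or delegate pseudo-agents.
Orders (blood work, radiology) depend on the CTAS level; the patient keeps
the bed during radiology and releases it at departure (admission or a
nurse-assisted discharge).

Run protocol: one long replication with a warm-up (default 40 days) removed
and a 420-day recording window analyzed by batch means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Generator, Iterator

import numpy as np
import pandas as pd

from .agents import AgentState, EpisodeSpec, ProviderTeam
from .distributions import DistributionSpec, RandomStreams
from .kernel import Environment, Event, Resource
from .stats import BatchCI, batch_means, utilization

__all__ = [
    "EDConfig",
    "EDPatient",
    "EDResult",
    "arrival_times",
    "assign_ctas",
    "lwbs_probability",
    "order_tests",
    "run_ed",
]

MINUTES_PER_DAY = 1440.0
HOURS_PER_YEAR = 8766.0  # 365.25 days

#: default weekday/hour arrival shape: a synthetic two-peak diurnal curve
#: (overnight trough ~04:00, peaks late morning and early evening) used in
#: place of the unpublished hospital schedule; scaled to the annual volume.
DEFAULT_HOURLY_WEIGHTS: tuple[float, ...] = (
    0.55, 0.45, 0.40, 0.35, 0.33, 0.35, 0.45, 0.65,
    0.90, 1.15, 1.35, 1.45, 1.40, 1.30, 1.25, 1.20,
    1.20, 1.25, 1.35, 1.40, 1.30, 1.10, 0.90, 0.70,
)
#: mild weekday effect, Monday-first (Mondays busiest, weekend quietest)
DEFAULT_DAY_WEIGHTS: tuple[float, ...] = (1.08, 1.02, 1.00, 0.99, 0.98, 0.95, 0.98)

CTAS_LEVELS = (1, 2, 3, 4, 5)
DEFAULT_CTAS_PROBS = (0.01, 0.16, 0.56, 0.25, 0.02)
DEFAULT_RADIOLOGY_PROBS = {1: 0.82, 2: 0.07, 3: 0.48, 4: 0.28, 5: 0.18}
DEFAULT_BLOOD_PROBS = {1: 0.85, 2: 0.73, 3: 0.51, 4: 0.19, 5: 0.01}
#: leave-without-being-seen probability by waiting-time band (minutes)
DEFAULT_LWBS_BANDS: tuple[tuple[float, float], ...] = (
    (30.0, 0.01), (60.0, 0.02), (120.0, 0.10),
    (180.0, 0.20), (300.0, 0.30), (math.inf, 0.40),
)


def _default_services() -> dict[str, DistributionSpec]:
    D = DistributionSpec
    return {
        "triage": D.poisson(10.0),
        "registration": D.lognormal(2.0, cv=0.5),
        "nurse_assessment": D.beta_scaled(10.0),
        "draw_blood": D.triangular(4.0),
        "discharge": D.triangular(10.0),
        "physician_high": D.triangular(9.0),
        "physician_low": D.triangular(4.0),
        "delegate_workup": D.triangular(10.5),
        "delegate_treat": D.triangular(4.0),
        "delegate_implement": D.triangular(5.5),
        "consult": D.triangular(4.5),
        "radiology": D.beta_scaled(9.0),
    }


def _default_schedule() -> tuple[int, ...]:
    """1 unit overnight (00-08), 2 during the day (08-24)."""
    return tuple(1 if h < 8 else 2 for h in range(24))


@dataclass
class EDConfig:
    annual_volume: float = 50_000.0
    walk_in_fraction: float = 0.80
    walk_in_multiplier: float = 1.0   # sensitivity lever: 0.5 halves walk-ins only
    hourly_weights: tuple[float, ...] = DEFAULT_HOURLY_WEIGHTS
    day_weights: tuple[float, ...] = DEFAULT_DAY_WEIGHTS

    triage_nurses: int | tuple[int, ...] = field(default_factory=_default_schedule)
    registrars: int | tuple[int, ...] = field(default_factory=_default_schedule)
    bedside_nurses: int = 2
    charge_nurses: int = 1
    beds: int = 5
    radiology_units: int = 1

    ctas_probs: tuple[float, ...] = DEFAULT_CTAS_PROBS
    radiology_probs: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_RADIOLOGY_PROBS))
    blood_probs: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_BLOOD_PROBS))
    lwbs_bands: tuple[tuple[float, float], ...] = DEFAULT_LWBS_BANDS
    lwbs_mode: str = "hazard"         # "hazard" (band-boundary draws) or "single_draw"
    admit_prob: float = 0.15
    transfer_minutes: float = 2.0     # charge-nurse hold while placing the patient

    services: dict[str, DistributionSpec] = field(default_factory=_default_services)
    interaction: bool = True
    tie_break: str = "delegate_first"
    consult_preempts_low: bool = False

    warmup_days: float = 40.0
    record_days: float = 420.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.ctas_probs) - 1.0) > 1e-9:
            raise ValueError("ctas_probs must sum to 1")
        probs = (*self.ctas_probs, self.admit_prob, self.walk_in_fraction,
                 *self.radiology_probs.values(), *self.blood_probs.values(),
                 *(p for _b, p in self.lwbs_bands))
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        bands = [p for _b, p in self.lwbs_bands]
        if any(nxt < prv for prv, nxt in zip(bands, bands[1:])):
            raise ValueError("lwbs band probabilities must be non-decreasing in wait")
        if self.record_days <= 0:
            raise ValueError("recording horizon must be positive")
        if self.lwbs_mode not in ("hazard", "single_draw"):
            raise ValueError("lwbs_mode must be 'hazard' or 'single_draw'")

    @property
    def hourly_rate_base(self) -> float:
        """Arrivals per hour before hourly/daily weighting."""
        return self.annual_volume / HOURS_PER_YEAR

    def rate_at(self, t_min: float) -> float:
        """Arrival rate (per hour) at absolute simulation time ``t_min``."""
        hour = int(t_min // 60.0) % 24
        day = int(t_min // MINUTES_PER_DAY) % 7
        hw = self.hourly_weights[hour] * 24.0 / sum(self.hourly_weights)
        dw = self.day_weights[day] * 7.0 / sum(self.day_weights)
        base = self.hourly_rate_base * hw * dw
        # halving walk-ins leaves the ambulance share untouched
        return base * (self.walk_in_fraction * self.walk_in_multiplier
                       + (1.0 - self.walk_in_fraction))


@dataclass
class EDPatient:
    id: int
    arrival: float
    arrival_mode: str
    ctas: int
    needs_blood: bool
    needs_radiology: bool
    disposition: str | None = None     # admitted | discharged | lwbs
    triage_done: float | None = None
    registered: float | None = None
    bed_assigned: float | None = None
    nurse_assessed: float | None = None
    provider_queued: float | None = None
    provider_start: float | None = None
    provider_done: float | None = None
    provider_time: float | None = None
    provider: str | None = None
    departure: float | None = None
    provider_reply: Any = None

    @property
    def acuity(self) -> str:
        return "high" if self.ctas <= 2 else "low"


def assign_ctas(rng: np.random.Generator, probs: tuple[float, ...] = DEFAULT_CTAS_PROBS) -> int:
    """Categorical CTAS draw, level 1 (resuscitation) to 5 (non-urgent)."""
    return int(rng.choice(CTAS_LEVELS, p=probs))


def order_tests(
    ctas: int,
    rng: np.random.Generator,
    blood_probs: dict[int, float] | None = None,
    radiology_probs: dict[int, float] | None = None,
) -> tuple[bool, bool]:
    """Independent Bernoulli draws for (blood work, radiology) given CTAS."""
    if ctas not in CTAS_LEVELS:
        raise ValueError(f"CTAS level must be 1..5, got {ctas}")
    bp = (blood_probs or DEFAULT_BLOOD_PROBS)[ctas]
    rp = (radiology_probs or DEFAULT_RADIOLOGY_PROBS)[ctas]
    return bool(rng.random() < bp), bool(rng.random() < rp)


def lwbs_probability(
    wait_so_far: float, bands: tuple[tuple[float, float], ...] = DEFAULT_LWBS_BANDS
) -> float:
    """Probability of leaving without being seen, by waiting-time band."""
    if wait_so_far < 0:
        raise ValueError("waiting time cannot be negative")
    for bound, p in bands:
        if wait_so_far < bound:
            return p
    return bands[-1][1]


def arrival_times(cfg: EDConfig, rng: np.random.Generator, horizon_min: float) -> Iterator[float]:
    """Nonhomogeneous arrival process with piecewise-constant hourly rates.

    Within each hour inter-arrivals are exponential at that hour's rate; the
    draw is restarted at each hour boundary, which is exact for a
    piecewise-constant-rate Poisson process by memorylessness.
    """
    t = 0.0
    while True:
        rate = cfg.rate_at(t)  # per hour
        if rate <= 0.0:
            t = math.floor(t / 60.0) * 60.0 + 60.0
            if t >= horizon_min:
                return
            continue
        gap = rng.exponential(60.0 / rate)
        boundary = math.floor(t / 60.0) * 60.0 + 60.0
        if t + gap > boundary:
            t = boundary
        else:
            t += gap
            if t >= horizon_min:
                return
            yield t
        if t >= horizon_min:
            return


def _episode_spec(cfg: EDConfig) -> EpisodeSpec:
    s = cfg.services
    return EpisodeSpec(
        physician_high=[(AgentState.TREATING, s["physician_high"])],
        physician_low=[(AgentState.TREATING, s["physician_low"])],
        delegate_pre=[(AgentState.ASSESSING, s["delegate_workup"])],
        delegate_post=[(AgentState.TREATING, s["delegate_treat"]),
                       (AgentState.TREATING, s["delegate_implement"])],
        delegate_post_no_consult=[(AgentState.TREATING, s["delegate_treat"])],
        consult=s["consult"] if cfg.interaction else None,
        consult_preempts_low=cfg.consult_preempts_low,
    )


class _EDSimulation:
    """One long ED run; see :func:`run_ed` for the public entry point."""

    def __init__(self, cfg: EDConfig, streams: RandomStreams) -> None:
        self.cfg = cfg
        self.streams = streams
        self.env = Environment()
        env = self.env
        self.triage = Resource(env, "triage_nurse", cfg.triage_nurses)
        self.registrar = Resource(env, "registrar", cfg.registrars)
        self.bedside = Resource(env, "bedside_nurse", cfg.bedside_nurses)
        self.charge = Resource(env, "charge_nurse", cfg.charge_nurses)
        self.beds = Resource(env, "beds", cfg.beds)
        self.radiology = Resource(env, "radiology", cfg.radiology_units)
        self.team = ProviderTeam(
            env, _episode_spec(cfg), streams, tie_break=cfg.tie_break
        )
        self.patients: list[EDPatient] = []
        self.n_active = 0

    # -- arrivals --------------------------------------------------------
    def _arrivals(self, horizon: float) -> Generator[Event, Any, None]:
        cfg, env = self.cfg, self.env
        rng_arr = self.streams.get("arrival")
        rng_mode = self.streams.get("arrival_mode")
        rng_ctas = self.streams.get("ctas")
        rng_blood = self.streams.get("blood")
        rng_rad = self.streams.get("radiology_order")
        i = 0
        for t in arrival_times(cfg, rng_arr, horizon):
            yield env.timeout(t - env.now)
            i += 1
            ctas = assign_ctas(rng_ctas, cfg.ctas_probs)
            blood, rad = (
                rng_blood.random() < cfg.blood_probs[ctas],
                rng_rad.random() < cfg.radiology_probs[ctas],
            )
            # with walk-ins thinned, the ambulance share of the mix rises
            w = cfg.walk_in_fraction * cfg.walk_in_multiplier
            p_walk = w / (w + (1.0 - cfg.walk_in_fraction)) if w >= 0 else 0.0
            mode = "walk_in" if rng_mode.random() < p_walk else "ambulance"
            p = EDPatient(
                id=i, arrival=env.now, arrival_mode=mode, ctas=ctas,
                needs_blood=blood, needs_radiology=rad,
            )
            self.patients.append(p)
            self.n_active += 1
            env.process(self._patient(p))

    # -- patient flow ----------------------------------------------------
    def _seize(self, res: Resource, prio: int) -> Generator[Event, Any, Any]:
        req = res.request(priority=prio)
        yield req
        return req

    def _patient(self, p: EDPatient) -> Generator[Event, Any, None]:
        cfg, env, s = self.cfg, self.env, self.cfg.services
        prio = 0 if p.acuity == "high" else 1

        req = self.triage.request(priority=prio)
        yield req
        yield env.timeout(s["triage"].sample(self.streams.get("svc_triage")))
        self.triage.release(req)
        p.triage_done = env.now

        req = self.registrar.request(priority=prio)
        yield req
        yield env.timeout(s["registration"].sample(self.streams.get("svc_registration")))
        self.registrar.release(req)
        p.registered = env.now

        bed_req = yield from self._wait_for_bed(p, prio)
        if bed_req is None:  # left without being seen
            p.disposition = "lwbs"
            p.departure = env.now
            self.n_active -= 1
            return
        p.bed_assigned = env.now

        creq = self.charge.request(priority=prio)
        yield creq
        yield env.timeout(cfg.transfer_minutes)
        self.charge.release(creq)

        nreq = self.bedside.request(priority=prio)
        yield nreq
        yield env.timeout(s["nurse_assessment"].sample(self.streams.get("svc_assessment")))
        self.bedside.release(nreq)
        p.nurse_assessed = env.now

        p.provider_reply = env.event()
        self.team.add_patient(p)
        yield p.provider_reply

        if p.needs_blood:  # nurse draws at the bed; results never block flow
            nreq = self.bedside.request(priority=prio)
            yield nreq
            yield env.timeout(s["draw_blood"].sample(self.streams.get("svc_blood")))
            self.bedside.release(nreq)

        if p.needs_radiology:  # the bed is kept; the patient returns to it
            rreq = self.radiology.request(priority=prio)
            yield rreq
            yield env.timeout(s["radiology"].sample(self.streams.get("svc_radiology")))
            self.radiology.release(rreq)

        if self.streams.get("admit").random() < cfg.admit_prob:
            p.disposition = "admitted"
        else:
            nreq = self.bedside.request(priority=prio)
            yield nreq
            yield env.timeout(s["discharge"].sample(self.streams.get("svc_discharge")))
            self.bedside.release(nreq)
            p.disposition = "discharged"
        self.beds.release(bed_req)
        p.departure = env.now
        self.n_active -= 1

    def _wait_for_bed(self, p: EDPatient, prio: int):
        """Queue for a bed under the leave-without-being-seen risk.

        In ``hazard`` mode the band probabilities of the inputs table are
        applied incrementally: a first draw on joining a non-empty queue
        (the under-30-minute band) and one at each band boundary crossed
        while still waiting, with the incremental probability
        p(band) - p(previous band).  ``single_draw`` applies one draw with
        the band probability of the realized wait, at bed assignment.
        """
        cfg, env = self.cfg, self.env
        rng = self.streams.get("lwbs")
        req = self.beds.request(priority=prio)
        if req.triggered:
            yield req
            return req
        queued_at = env.now
        if cfg.lwbs_mode == "single_draw":
            yield req
            if rng.random() < lwbs_probability(env.now - queued_at, cfg.lwbs_bands):
                self.beds.release(req)  # immediately hand the bed back
                return None
            return req
        prev_p = 0.0
        boundaries = [b for b, _p in cfg.lwbs_bands if math.isfinite(b)]
        probs = [pp for _b, pp in cfg.lwbs_bands]
        # joining draw: the "< 30 minutes" band
        if rng.random() < probs[0]:
            req.cancel()
            return None
        prev_p = probs[0]
        for bound, band_p in zip(boundaries, probs[1:]):
            timer = env.timeout(max(0.0, bound - (env.now - queued_at)))
            yield env.any_of([req, timer])
            if req.triggered:
                return req
            if rng.random() < (band_p - prev_p):
                req.cancel()
                return None
            prev_p = band_p
        yield req
        return req


def _daily_series(intervals, start: float, end: float) -> np.ndarray:
    """Per-day busy fractions from an activity log, for batch means."""
    n_days = int((end - start) // MINUTES_PER_DAY)
    busy = np.zeros(n_days)
    for _state, a, b in intervals:
        a, b = max(a, start), min(b, end)
        if b <= a:
            continue
        d0, d1 = int((a - start) // MINUTES_PER_DAY), int((b - start) // MINUTES_PER_DAY)
        for d in range(d0, min(d1, n_days - 1) + 1):
            lo = start + d * MINUTES_PER_DAY
            busy[d] += max(0.0, min(b, lo + MINUTES_PER_DAY) - max(a, lo))
    return busy / MINUTES_PER_DAY


@dataclass
class EDResult:
    config: EDConfig
    utilization_physician: float
    utilization_delegate: float
    utilization_physician_ci: BatchCI
    utilization_delegate_ci: BatchCI
    kpis: dict[str, BatchCI]
    resource_utilization: dict[str, float]
    arrivals: int
    admitted: int
    discharged: int
    lwbs_count: int
    in_system: int
    patients: pd.DataFrame

    def kpi_frame(self) -> pd.DataFrame:
        rows = [
            {"measure": "utilization_physician", "mean": self.utilization_physician,
             "ci_lo": self.utilization_physician_ci.lo, "ci_hi": self.utilization_physician_ci.hi},
            {"measure": "utilization_delegate", "mean": self.utilization_delegate,
             "ci_lo": self.utilization_delegate_ci.lo, "ci_hi": self.utilization_delegate_ci.hi},
        ]
        rows += [
            {"measure": name, "mean": ci.mean, "ci_lo": ci.lo, "ci_hi": ci.hi}
            for name, ci in self.kpis.items()
        ]
        return pd.DataFrame(rows)


def _strata_kpis(df: pd.DataFrame) -> dict[str, BatchCI]:
    """Batch-means CIs for the reported time intervals, by stratum."""
    out: dict[str, BatchCI] = {}

    def add(name: str, series: pd.Series) -> None:
        vals = series.dropna().to_numpy()
        if vals.size >= 40:
            out[name] = batch_means(vals)

    seen = df[df.disposition != "lwbs"]
    for acuity in ("high", "low"):
        sub = seen[seen.acuity == acuity]
        add(f"arrival_to_bed_{acuity}", sub.bed_assigned - sub.arrival)
        add(f"total_los_{acuity}", sub.departure - sub.arrival)
    for provider, acuity in (("physician", "high"), ("physician", "low"), ("delegate", "low")):
        sub = seen[(seen.provider == provider) & (seen.acuity == acuity)]
        add(f"wait_for_provider_{provider}_{acuity}", sub.provider_start - sub.provider_queued)
        add(f"time_with_provider_{provider}_{acuity}", sub.provider_time)
        add(f"total_los_{provider}_{acuity}", sub.departure - sub.arrival)
    return out


def run_ed(cfg: EDConfig, seed: int | None = None) -> EDResult:
    """Run the ED model once and report batched-mean KPIs.

    One long replication: ``warmup_days`` are simulated and discarded, then
    ``record_days`` are recorded.  Utilizations are busy fractions of the
    recording window; time KPIs are computed over patients departing inside
    it, with batch-means 95% CIs.
    """
    streams = RandomStreams(cfg.seed if seed is None else seed)
    sim = _EDSimulation(cfg, streams)
    total = (cfg.warmup_days + cfg.record_days) * MINUTES_PER_DAY
    w_start = cfg.warmup_days * MINUTES_PER_DAY
    sim.team.start()
    sim.env.process(sim._arrivals(total))
    sim.env.run(until=total)
    sim.team.close_logs()

    record = cfg.record_days * MINUTES_PER_DAY
    phys, dele = sim.team.physician, sim.team.delegate
    up = phys.busy_time(w_start, total) / record
    ud = dele.busy_time(w_start, total) / record

    from .agents import BUSY_STATES

    phys_daily = _daily_series(
        [iv for iv in phys.intervals if iv[0] in BUSY_STATES], w_start, total)
    dele_daily = _daily_series(
        [iv for iv in dele.intervals if iv[0] in BUSY_STATES], w_start, total)
    up_ci = batch_means(phys_daily) if phys_daily.size >= 40 else BatchCI(up, 0.0, 1, 1)
    ud_ci = batch_means(dele_daily) if dele_daily.size >= 40 else BatchCI(ud, 0.0, 1, 1)

    rows = []
    for p in sim.patients:
        if p.departure is None or not (w_start <= p.departure <= total):
            continue
        rows.append({
            "id": p.id, "arrival": p.arrival, "arrival_mode": p.arrival_mode,
            "ctas": p.ctas, "acuity": p.acuity, "disposition": p.disposition,
            "bed_assigned": p.bed_assigned, "nurse_assessed": p.nurse_assessed,
            "provider_queued": p.provider_queued, "provider_start": p.provider_start,
            "provider_done": p.provider_done, "provider_time": p.provider_time,
            "provider": p.provider, "departure": p.departure,
        })
    df = pd.DataFrame(rows)

    for res in (sim.triage, sim.registrar, sim.bedside, sim.charge, sim.beds, sim.radiology):
        res.finalize()
    res_util = {
        res.name: res.utilization()
        for res in (sim.triage, sim.registrar, sim.bedside, sim.charge, sim.beds, sim.radiology)
    }

    done = [p for p in sim.patients if p.departure is not None]
    return EDResult(
        config=cfg,
        utilization_physician=up,
        utilization_delegate=ud,
        utilization_physician_ci=up_ci,
        utilization_delegate_ci=ud_ci,
        kpis=_strata_kpis(df) if len(df) else {},
        resource_utilization=res_util,
        arrivals=len(sim.patients),
        admitted=sum(1 for p in done if p.disposition == "admitted"),
        discharged=sum(1 for p in done if p.disposition == "discharged"),
        lwbs_count=sum(1 for p in done if p.disposition == "lwbs"),
        in_system=sim.n_active,
        patients=df,
    )
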