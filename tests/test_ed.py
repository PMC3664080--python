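"""Hospital ED model: routing draws, arrivals, flow invariants."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edsim.distributions import DistributionSpec, RandomStreams
from edsim.ed import (
    DEFAULT_LWBS_BANDS,
    EDConfig,
    arrival_times,
    assign_ctas,
    lwbs_probability,
    order_tests,
    run_ed,
)

C = DistributionSpec.constant


@pytest.fixture(scope="module")
def short_run():
    """A 15-day base-case run shared by the flow-invariant tests."""
    return run_ed(EDConfig(warmup_days=3.0, record_days=12.0, seed=21))


class TestLwbsProbability:
    @pytest.mark.parametrize("wait, expected", [
        (0.0, 0.01), (15.0, 0.01), (30.0, 0.02), (45.0, 0.02),
        (90.0, 0.10), (150.0, 0.20), (200.0, 0.30), (299.9, 0.30),
        (300.0, 0.40), (1e6, 0.40),  # the last band is unbounded above
    ])
    def test_band_lookup(self, wait, expected):
        assert lwbs_probability(wait) == expected

    def test_negative_wait_rejected(self):
        with pytest.raises(ValueError):
            lwbs_probability(-1.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=400.0),
           st.floats(min_value=0.0, max_value=400.0))
    def test_monotone_in_wait(self, a, b):
        lo, hi = sorted((a, b))
        assert lwbs_probability(lo) <= lwbs_probability(hi)


class TestRoutingDraws:
    def test_ctas_frequencies_match_masses(self):
        rng = np.random.default_rng(0)
        draws = np.array([assign_ctas(rng) for _ in range(200_000)])
        freq = np.bincount(draws, minlength=6)[1:] / draws.size
        for f, p in zip(freq, (0.01, 0.16, 0.56, 0.25, 0.02)):
            assert f == pytest.approx(p, abs=0.005)
        # P(high acuity) = P(CTAS 1) + P(CTAS 2) = 0.17
        assert (draws <= 2).mean() == pytest.approx(0.17, abs=0.005)

    def test_order_probabilities_by_ctas(self):
        rng = np.random.default_rng(1)
        n = 100_000
        draws1 = np.array([order_tests(1, rng) for _ in range(n)], dtype=float)
        assert draws1[:, 0].mean() == pytest.approx(0.85, abs=0.01)  # blood
        assert draws1[:, 1].mean() == pytest.approx(0.82, abs=0.01)  # radiology
        draws5 = np.array([order_tests(5, rng) for _ in range(n)], dtype=float)
        assert draws5[:, 0].mean() == pytest.approx(0.01, abs=0.005)

    def test_orders_are_independent(self):
        rng = np.random.default_rng(2)
        draws = np.array([order_tests(3, rng) for _ in range(100_000)], dtype=float)
        corr = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
        assert abs(corr) < 0.02

    def test_invalid_ctas_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            order_tests(6, rng)


class TestArrivals:
    def test_flat_weights_annual_count_near_volume(self):
        cfg = EDConfig(hourly_weights=(1.0,) * 24, day_weights=(1.0,) * 7)
        rng = np.random.default_rng(3)
        year = 365.25 * 1440.0
        n = sum(1 for _ in arrival_times(cfg, rng, year))
        sigma = math.sqrt(50_000.0)
        assert abs(n - 50_000) < 3 * sigma

    def test_all_weight_on_one_hour(self):
        cfg = EDConfig(hourly_weights=tuple(1.0 if h == 12 else 0.0 for h in range(24)))
        rng = np.random.default_rng(4)
        times = list(arrival_times(cfg, rng, 7.0 * 1440.0))
        assert times
        assert all(int(t // 60.0) % 24 == 12 for t in times)

    def test_halved_walkins_scale_count(self):
        cfg = EDConfig(hourly_weights=(1.0,) * 24, day_weights=(1.0,) * 7)
        half = replace(cfg, walk_in_multiplier=0.5)
        rng_a, rng_b = np.random.default_rng(5), np.random.default_rng(5)
        horizon = 60.0 * 1440.0
        n_full = sum(1 for _ in arrival_times(cfg, rng_a, horizon))
        n_half = sum(1 for _ in arrival_times(half, rng_b, horizon))
        # walk-ins are 80% of volume: halving them leaves 60% of arrivals
        assert n_half / n_full == pytest.approx(0.6, abs=0.03)

    def test_times_strictly_increasing(self):
        cfg = EDConfig()
        rng = np.random.default_rng(6)
        times = list(arrival_times(cfg, rng, 14.0 * 1440.0))
        assert all(b > a for a, b in zip(times, times[1:]))


class TestConfigValidation:
    def test_ctas_probs_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            EDConfig(ctas_probs=(0.5, 0.2, 0.2, 0.2, 0.2))

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            EDConfig(admit_prob=1.3)

    def test_lwbs_bands_must_be_non_decreasing(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            EDConfig(lwbs_bands=((30.0, 0.4), (60.0, 0.1), (math.inf, 0.5)))


class TestFlow:
    def test_conservation_at_horizon(self, short_run):
        r = short_run
        assert r.arrivals == r.admitted + r.discharged + r.lwbs_count + r.in_system

    def test_timestamps_non_decreasing_in_flow_order(self, short_run):
        df = short_run.patients
        seen = df[df.disposition != "lwbs"]
        for a, b in [("arrival", "bed_assigned"), ("bed_assigned", "nurse_assessed"),
                     ("nurse_assessed", "provider_start"),
                     ("provider_start", "provider_done"), ("provider_done", "departure")]:
            assert (seen[b] >= seen[a] - 1e-9).all()

    def test_lwbs_patients_never_reach_a_bed(self, short_run):
        lwbs = short_run.patients.query("disposition == 'lwbs'")
        assert len(lwbs) > 0
        assert lwbs.bed_assigned.isna().all()

    def test_high_acuity_always_served_by_physician(self, short_run):
        seen = short_run.patients.query("disposition != 'lwbs'")
        assert (seen.loc[seen.acuity == "high", "provider"] == "physician").all()

    def test_low_acuity_waits_longer_for_bed_than_high(self, short_run):
        df = short_run.patients.query("disposition != 'lwbs'")
        waits = df.bed_assigned - df.arrival
        assert waits[df.acuity == "low"].mean() > waits[df.acuity == "high"].mean()

    def test_bed_occupancy_never_exceeds_bed_count(self):
        """One bed per patient from assignment to departure, radiology
        included; reconstructed occupancy must respect the capacity."""
        r = run_ed(EDConfig(warmup_days=0.0, record_days=10.0, seed=22))
        df = r.patients.query("disposition != 'lwbs'")
        events = sorted(
            [(t, +1) for t in df.bed_assigned] + [(t, -1) for t in df.departure]
        )
        occ, peak = 0, 0
        for _t, d in events:
            occ += d
            peak = max(peak, occ)
        assert peak <= r.config.beds

    def test_empty_system_path_sums_stage_services(self):
        """A lone patient with no orders flows through in exactly the sum of
        the deterministic stage times."""
        services = {
            "triage": C(10.0), "registration": C(2.0), "nurse_assessment": C(10.0),
            "draw_blood": C(4.0), "discharge": C(10.0), "physician_high": C(9.0),
            "physician_low": C(4.0), "delegate_workup": C(10.5),
            "delegate_treat": C(4.0), "delegate_implement": C(5.5),
            "consult": C(4.5), "radiology": C(9.0),
        }
        cfg = EDConfig(
            annual_volume=200.0,  # sparse: patients almost never overlap
            hourly_weights=(1.0,) * 24, day_weights=(1.0,) * 7,
            services=services, admit_prob=0.0,
            blood_probs={k: 0.0 for k in range(1, 6)},
            radiology_probs={k: 0.0 for k in range(1, 6)},
            lwbs_bands=((30.0, 0.0), (math.inf, 0.0)),
            interaction=False,  # delegate episode: work-up 10.5 + treatment 4
            warmup_days=0.0, record_days=60.0, seed=23,
        )
        r = run_ed(cfg)
        df = r.patients
        lone = df[(df.acuity == "low") & (df.provider == "delegate")]
        assert len(lone) > 0
        total = lone.departure - lone.arrival
        waits = total - (10.0 + 2.0 + 2.0 + 10.0 + 14.5 + 10.0)
        # at least some patients find an empty system: zero extra wait
        assert (waits.min() == pytest.approx(0.0, abs=1e-6))

    def test_determinism_same_seed_same_result(self):
        a = run_ed(EDConfig(warmup_days=1.0, record_days=4.0, seed=30))
        b = run_ed(EDConfig(warmup_days=1.0, record_days=4.0, seed=30))
        assert a.patients.equals(b.patients)
        assert a.utilization_physician == b.utilization_physician

    def test_interaction_adds_consult_and_implement_to_delegate_time(self, short_run):
        off = run_ed(EDConfig(warmup_days=3.0, record_days=12.0, seed=21, interaction=False))
        d_on = short_run.kpis["time_with_provider_delegate_low"].mean
        d_off = off.kpis["time_with_provider_delegate_low"].mean
        # consult 4.5 + implementation 5.5 minutes
        assert d_on - d_off == pytest.approx(10.0, abs=0.5)


def test_welch_warmup_on_ed_los_series():
    """Moving-average stabilization of daily mean LOS within 40 days."""
    r = run_ed(EDConfig(warmup_days=0.0, record_days=120.0, seed=24))
    df = r.patients.query("disposition != 'lwbs'").copy()
    df["day"] = (df.departure // 1440.0).astype(int)
    daily = df.groupby("day").apply(
        lambda g: (g.departure - g.arrival).mean(), include_groups=False)
    from edsim.stats import welch_warmup
    idx = welch_warmup(daily.to_numpy(), window=7, rel_tol=0.2)
    assert idx is not None and idx <= 40
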