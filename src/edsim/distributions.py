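"""Named parametric service/arrival-time distributions (minutes).

The source tables for the ED model give a mean and a distribution family for
each process time, but no dispersion parameters.  Each family here therefore
has a one-argument "from the mean" constructor with an explicit, overridable
shape convention:

* ``lognormal``   — coefficient of variation 0.5 unless given,
* ``beta``        — scaled to [0, 2*mean] with symmetric shape a = b = 2,
* ``triangular``  — symmetric, (min, mode, max) = (0.5, 1.0, 1.5) * mean,
* ``poisson``     — whole minutes with the stated mean (used literally for
  the triage service time),
* ``exponential`` and ``constant`` need only the mean.

Every spec stores its analytic mean and refuses construction if the supplied
mean disagrees with the family/parameter mean by more than 1e-9; all
families have non-negative support.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Any

import numpy as np

__all__ = ["DistributionSpec", "RandomStreams"]

_FAMILIES = ("constant", "exponential", "poisson", "lognormal", "beta", "triangular")


@dataclass(frozen=True)
class DistributionSpec:
    """A parametric non-negative distribution with a declared mean."""

    family: str
    params: tuple[float, ...]
    mean: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        analytic = self.analytic_mean()
        if not math.isclose(analytic, self.mean, rel_tol=0.0, abs_tol=1e-9):
            raise ValueError(
                f"stated mean {self.mean} does not match analytic mean "
                f"{analytic} of {self.family}{self.params}"
            )
        lo = self.support_min()
        if lo < 0:
            raise ValueError(f"{self.family}{self.params} has negative support (min {lo})")

    # -- constructors ----------------------------------------------------
    @staticmethod
    def constant(value: float) -> "DistributionSpec":
        return DistributionSpec("constant", (float(value),), float(value))

    @staticmethod
    def exponential(mean: float) -> "DistributionSpec":
        if mean <= 0:
            raise ValueError("exponential mean must be positive")
        return DistributionSpec("exponential", (float(mean),), float(mean))

    @staticmethod
    def poisson(mean: float) -> "DistributionSpec":
        if mean <= 0:
            raise ValueError("poisson mean must be positive")
        return DistributionSpec("poisson", (float(mean),), float(mean))

    @staticmethod
    def lognormal(mean: float, cv: float = 0.5) -> "DistributionSpec":
        if mean <= 0 or cv <= 0:
            raise ValueError("lognormal mean and cv must be positive")
        sigma2 = math.log1p(cv * cv)
        mu = math.log(mean) - sigma2 / 2.0
        return DistributionSpec("lognormal", (mu, math.sqrt(sigma2)), float(mean))

    @staticmethod
    def beta_scaled(
        mean: float, a: float = 2.0, b: float | None = None, hi: float | None = None
    ) -> "DistributionSpec":
        """Beta(a, b) rescaled to [0, hi]; default symmetric on [0, 2*mean]."""
        if b is None:
            b = a
        if hi is None:
            hi = mean * (a + b) / a
        if mean <= 0 or a <= 0 or b <= 0 or hi <= 0:
            raise ValueError("beta parameters must be positive")
        return DistributionSpec("beta", (a, b, float(hi)), float(mean))

    @staticmethod
    def triangular(
        mean: float | None = None,
        lo: float | None = None,
        mode: float | None = None,
        hi: float | None = None,
    ) -> "DistributionSpec":
        if lo is None or mode is None or hi is None:
            if mean is None:
                raise ValueError("triangular needs either a mean or (lo, mode, hi)")
            lo, mode, hi = 0.5 * mean, float(mean), 1.5 * mean
        if not (lo <= mode <= hi):
            raise ValueError(f"triangular requires lo <= mode <= hi, got {(lo, mode, hi)}")
        m = (lo + mode + hi) / 3.0
        return DistributionSpec("triangular", (float(lo), float(mode), float(hi)), m)

    @staticmethod
    def from_config(cfg: "DistributionSpec | dict[str, Any] | float") -> "DistributionSpec":
        """Build a spec from a config mapping, e.g. ``{family: triangular, mean: 4.5}``."""
        if isinstance(cfg, DistributionSpec):
            return cfg
        if isinstance(cfg, (int, float)):
            return DistributionSpec.constant(float(cfg))
        cfg = dict(cfg)
        family = cfg.pop("family")
        builders = {
            "constant": lambda: DistributionSpec.constant(cfg["value" if "value" in cfg else "mean"]),
            "exponential": lambda: DistributionSpec.exponential(cfg["mean"]),
            "poisson": lambda: DistributionSpec.poisson(cfg["mean"]),
            "lognormal": lambda: DistributionSpec.lognormal(cfg["mean"], cfg.get("cv", 0.5)),
            "beta": lambda: DistributionSpec.beta_scaled(
                cfg["mean"], cfg.get("a", 2.0), cfg.get("b"), cfg.get("hi")
            ),
            "triangular": lambda: DistributionSpec.triangular(
                cfg.get("mean"), cfg.get("lo"), cfg.get("mode"), cfg.get("hi")
            ),
        }
        if family not in builders:
            raise ValueError(f"unknown distribution family {family!r}")
        return builders[family]()

    # -- analytics -------------------------------------------------------
    def analytic_mean(self) -> float:
        p = self.params
        if self.family == "constant":
            return p[0]
        if self.family in ("exponential", "poisson"):
            return p[0]
        if self.family == "lognormal":
            return math.exp(p[0] + p[1] ** 2 / 2.0)
        if self.family == "beta":
            a, b, hi = p
            return hi * a / (a + b)
        lo, mode, hi = p
        return (lo + mode + hi) / 3.0

    def support_min(self) -> float:
        if self.family == "constant":
            return self.params[0]
        if self.family == "triangular":
            return self.params[0]
        return 0.0

    # -- sampling --------------------------------------------------------
    def sample(self, rng: np.random.Generator) -> float:
        """Draw one non-negative variate (minutes)."""
        p = self.params
        if self.family == "constant":
            return p[0]
        if self.family == "exponential":
            return rng.exponential(p[0])
        if self.family == "poisson":
            return float(rng.poisson(p[0]))
        if self.family == "lognormal":
            return rng.lognormal(p[0], p[1])
        if self.family == "beta":
            return p[2] * rng.beta(p[0], p[1])
        return rng.triangular(p[0], p[1], p[2])

    def sample_n(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.params
        if self.family == "constant":
            return np.full(n, p[0])
        if self.family == "exponential":
            return rng.exponential(p[0], n)
        if self.family == "poisson":
            return rng.poisson(p[0], n).astype(float)
        if self.family == "lognormal":
            return rng.lognormal(p[0], p[1], n)
        if self.family == "beta":
            return p[2] * rng.beta(p[0], p[1], n)
        return rng.triangular(p[0], p[1], p[2], n)

    def to_config(self) -> dict[str, Any]:
        out: dict[str, Any] = {"family": self.family, "mean": self.mean}
        if self.family == "lognormal":
            out["cv"] = math.sqrt(math.expm1(self.params[1] ** 2))
        elif self.family == "beta":
            out.update(a=self.params[0], b=self.params[1], hi=self.params[2])
        elif self.family == "triangular":
            out = {"family": "triangular", "lo": self.params[0], "mode": self.params[1], "hi": self.params[2]}
        return out


class RandomStreams:
    """Named, reproducible substreams of one master seed.

    Each distribution site in a model (arrivals, each service, each routing
    coin) draws from its own named stream, so two model variants fed the same
    master seed consume identical variates site-by-site — the common-random-
    numbers setup used when differencing the with/without-interaction runs.
    """

    def __init__(self, seed: int | tuple[int, ...]) -> None:
        self.seed: tuple[int, ...] = (seed,) if isinstance(seed, int) else tuple(seed)
        self._cache: dict[str, np.random.Generator] = {}

    def get(self, name: str) -> np.random.Generator:
        gen = self._cache.get(name)
        if gen is None:
            tag = zlib.crc32(name.encode("utf-8"))
            seq = np.random.SeedSequence(self.seed + (tag,))
            gen = self._cache[name] = np.random.default_rng(seq)
        return gen

    def child(self, index: int) -> "RandomStreams":
        """An independent stream family, e.g. one per replication."""
        return RandomStreams(self.seed + (int(index),))
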