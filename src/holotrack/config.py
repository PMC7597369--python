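"""Configuration objects for simulation and analysis.

Units are nanometers and seconds everywhere in memory; conversion to pixels
and frames happens only at I/O boundaries (rendering, table emission).
Channels are sampled on an interleaved clock: the PCNA channel at
``t = k * frame_interval`` and the Pol delta channel half a frame later, which
mirrors alternating filter-wheel acquisition where the stated per-channel
frame time already folds in the wheel dead time.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Channel names used throughout the package.
CH_POLD = "pold"
CH_PCNA = "pcna"
CHANNELS = (CH_POLD, CH_PCNA)

#: Arrival order classes (who binds first at a colocalization site).
ARRIVAL_CLASSES = ("pcna_first", "pold_first", "simultaneous")
#: Departure order classes (who leaves first).
DEPARTURE_CLASSES = ("pold_first", "pcna_first", "simultaneous")


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class ExpMixture:
    """Finite mixture of exponential distributions.

    Parameters
    ----------
    weights : tuple of float
        Mixture weights, non-negative, summing to 1.
    taus : tuple of float
        Time constants in seconds, strictly positive.
    """

    weights: tuple[float, ...]
    taus: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.taus) or not self.weights:
            raise ConfigError("weights and taus must be equal-length, non-empty")
        if any(w < 0 for w in self.weights):
            raise ConfigError("mixture weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ConfigError(f"mixture weights must sum to 1, got {sum(self.weights)}")
        if any(t <= 0 for t in self.taus):
            raise ConfigError("mixture time constants must be positive")

    @property
    def k(self) -> int:
        return len(self.weights)

    @property
    def mean(self) -> float:
        return float(sum(w * t for w, t in zip(self.weights, self.taus)))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` durations (seconds)."""
        comp = rng.choice(self.k, size=n, p=np.asarray(self.weights))
        return rng.exponential(np.asarray(self.taus)[comp])

    def sample_components(
        self, n: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` durations together with their component index."""
        comp = rng.choice(self.k, size=n, p=np.asarray(self.weights))
        return rng.exponential(np.asarray(self.taus)[comp]), comp

    def survival(self, t: np.ndarray | float) -> np.ndarray | float:
        """S(t) = sum_i f_i exp(-t / tau_i)."""
        t = np.asarray(t, dtype=float)
        return sum(w * np.exp(-t / tau) for w, tau in zip(self.weights, self.taus))


@dataclass(frozen=True)
class OrderProbs:
    """Categorical distributions over arrival and departure order classes.

    ``arrival`` is ordered (pcna_first, pold_first, simultaneous);
    ``departure`` is ordered (pold_first, pcna_first, simultaneous).
    """

    arrival: tuple[float, float, float] = (0.79, 0.10, 0.11)
    departure: tuple[float, float, float] = (0.84, 0.09, 0.07)

    def __post_init__(self) -> None:
        for name, probs in (("arrival", self.arrival), ("departure", self.departure)):
            if len(probs) != 3 or any(p < 0 for p in probs):
                raise ConfigError(f"{name} probabilities must be 3 non-negative values")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(f"{name} probabilities must sum to 1")


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth generator settings.

    Defaults reproduce the imaging conditions of the two-color experiment:
    a 512x512 px field at 84 nm/px, 1.34 s per-channel frame interval on an
    interleaved clock, ~22 min of acquisition, a two-population residence
    mixture with a dominant short-lived class, sparse colocalized pairs with
    an asymmetric arrival/departure order distribution, binding hubs with a
    three-component revisit-latency mixture, channel-specific photobleaching
    and ~25 nm localization noise.
    """

    nucleus_semiaxes: tuple[float, float] = (8000.0, 6000.0)  # nm
    field_size: tuple[int, int] = (512, 512)  # pixels (rows, cols)
    pixel_size: float = 84.0  # nm
    frame_interval: float = 1.34  # s, per channel
    movie_length: int = 1000  # frames per channel
    n_events_per_channel: int = 2000
    residence_mix: ExpMixture = ExpMixture((0.96, 0.04), (1.0, 12.4))
    coloc_fraction: float = 0.021
    order_probs: OrderProbs = OrderProbs()
    coloc_offset_scale: float = 20.0  # nm, max true pair offset
    hub_count: int = 20
    hub_radius: float = 84.0  # nm
    latency_mix: ExpMixture = ExpMixture((0.37, 0.40, 0.23), (8.0, 25.0, 200.0))
    label_fraction_per_channel: tuple[float, float] = (1.0, 1.0)  # (pold, pcna)
    bleach_tau_per_channel: tuple[float, float] = (99.3, 166.8)  # s (pold, pcna)
    loc_noise_sigma: float = 25.0  # nm per axis
    blink_gap_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.nucleus_semiaxes):
            raise ConfigError("nucleus semiaxes must be positive")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ConfigError("pixel_size and frame_interval must be positive")
        if self.movie_length < 1 or self.n_events_per_channel < 0:
            raise ConfigError("movie_length >= 1 and n_events_per_channel >= 0 required")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ConfigError("coloc_fraction must be in [0, 1]")
        if self.hub_count < 0:
            raise ConfigError("hub_count must be non-negative")
        if self.hub_radius >= min(self.nucleus_semiaxes):
            raise ConfigError("hub_radius must be smaller than the nucleus semiaxes")
        for f in self.label_fraction_per_channel:
            if not 0.0 < f <= 1.0:
                raise ConfigError("label fractions must be in (0, 1]")
        for tau in self.bleach_tau_per_channel:
            if tau <= 0:
                raise ConfigError("bleach time constants must be positive")
        if self.loc_noise_sigma < 0 or not 0.0 <= self.blink_gap_prob < 1.0:
            raise ConfigError("invalid noise or blink settings")

    # -- derived quantities -------------------------------------------------
    @property
    def movie_duration(self) -> float:
        """Total acquisition time in seconds (per channel clock)."""
        return self.movie_length * self.frame_interval

    @property
    def field_extent(self) -> tuple[float, float]:
        """Field size in nm (y, x)."""
        return (self.field_size[0] * self.pixel_size, self.field_size[1] * self.pixel_size)

    @property
    def nucleus_center(self) -> tuple[float, float]:
        """Nucleus center (x, y) in nm: the middle of the field."""
        ey, ex = self.field_extent
        return (ex / 2.0, ey / 2.0)

    def channel_offset(self, channel: str) -> float:
        """Time of frame 0 for a channel on the interleaved clock."""
        if channel == CH_PCNA:
            return 0.0
        if channel == CH_POLD:
            return self.frame_interval / 2.0
        raise ConfigError(f"unknown channel {channel!r}")

    def frame_times(self, channel: str) -> np.ndarray:
        off = self.channel_offset(channel)
        return off + self.frame_interval * np.arange(self.movie_length)

    def label_fraction(self, channel: str) -> float:
        return self.label_fraction_per_channel[CHANNELS.index(channel)]

    def bleach_tau(self, channel: str) -> float:
        return self.bleach_tau_per_channel[CHANNELS.index(channel)]

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["residence_mix"] = dataclasses.asdict(self.residence_mix)
        d["latency_mix"] = dataclasses.asdict(self.latency_mix)
        d["order_probs"] = dataclasses.asdict(self.order_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("residence_mix", "latency_mix"):
            if key in d and isinstance(d[key], dict):
                d[key] = ExpMixture(tuple(d[key]["weights"]), tuple(d[key]["taus"]))
        if "order_probs" in d and isinstance(d["order_probs"], dict):
            d["order_probs"] = OrderProbs(
                tuple(d["order_probs"]["arrival"]), tuple(d["order_probs"]["departure"])
            )
        for key in ("nucleus_semiaxes", "field_size", "label_fraction_per_channel",
                    "bleach_tau_per_channel"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def point_in_ellipse(x, y, cx: float, cy: float, a: float, b: float):
    """Axis-aligned ellipse membership test, inclusive of the boundary."""
    return ((np.asarray(x) - cx) / a) ** 2 + ((np.asarray(y) - cy) / b) ** 2 <= 1.0


def uniform_in_ellipse(
    n: int, cx: float, cy: float, a: float, b: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform points over an axis-aligned ellipse (exact, via disc mapping)."""
    r = np.sqrt(rng.random(n))
    theta = rng.random(n) * 2.0 * math.pi
    return cx + a * r * np.cos(theta), cy + b * r * np.sin(theta)
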