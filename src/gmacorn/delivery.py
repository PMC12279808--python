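"""Front-camera / rear-funnel (FCRF) delivery-timing model and simulator.

The camera sits a distance ``L1`` ahead of the release funnel.  After a
plant is detected, the signal chain takes ``T1`` seconds, granules fall for
``T2 = sqrt(2 ΔH / g)`` seconds from funnel height ``H1`` to target height
``H2``, and the platform needs ``T3 = L1 / V1`` seconds to carry the funnel
over the plant.  Precise delivery requires ``T1 + T2 + T4 = T3``, with the
programmable delay ``T4`` absorbing the slack; a platform too fast for its
geometry (``T1 + T2 > T3``) cannot be compensated and is rejected.

Granule kinematics are drag-free vertical fall (wind effects on the solid
granules are negligible); the horizontal platform motion during the fall is
exactly what the ``L1`` offset absorbs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["TimingConfig", "FieldLayout", "DeliveryOutcome", "fall_time",
           "travel_time", "required_delay", "simulate_run", "DetectorModel"]

G_DEFAULT = 9.81  # m/s^2


class InfeasibleTimingError(ValueError):
    """Platform too fast for the camera-to-funnel distance."""


@dataclass(frozen=True)
class TimingConfig:
    L1: float          # camera-to-funnel distance (m)
    H1: float          # funnel height (m)
    H2: float          # target (whorl) height (m)
    V1: float          # platform speed (m/s)
    T1: float = 0.0    # signal processing/transmission delay (s)
    T4: float = 0.0    # programmable extra delay (s)
    g: float = G_DEFAULT

    def __post_init__(self):
        if self.L1 <= 0:
            raise ValueError("L1 must be > 0")
        if not (self.H1 > self.H2 >= 0):
            raise ValueError("heights must satisfy H1 > H2 >= 0")
        if self.V1 <= 0:
            raise ValueError("V1 must be > 0")
        if self.T1 < 0 or self.T4 < 0:
            raise ValueError("delays must be >= 0")


@dataclass(frozen=True)
class DetectorModel:
    p_detect: float = 1.0
    center_error_sd: float = 0.0   # m, along-row detection position error

    def __post_init__(self):
        if not (0.0 <= self.p_detect <= 1.0):
            raise ValueError("p_detect must be in [0, 1]")


@dataclass(frozen=True)
class FieldLayout:
    positions: tuple           # plant positions along the row (m), increasing
    tolerance: float = 0.05    # landing tolerance radius (m)
    detectable: tuple | None = None

    def __post_init__(self):
        pos = tuple(float(p) for p in self.positions)
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("plant positions must be strictly increasing")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        object.__setattr__(self, "positions", pos)
        if self.detectable is None:
            object.__setattr__(self, "detectable", tuple(True for _ in pos))


@dataclass
class DeliveryOutcome:
    detected: bool
    delivered: bool
    landing_offset: float      # m; NaN when not detected

    def __post_init__(self):
        if self.delivered and not self.detected:
            raise ValueError("delivered implies detected")


def fall_time(cfg: TimingConfig) -> float:
    """T2 = sqrt(2 ΔH / g), drag-free fall from H1 to H2."""
    dh = cfg.H1 - cfg.H2
    if dh <= 0:
        raise ValueError("H1 must exceed H2")
    return float(np.sqrt(2.0 * dh / cfg.g))


def travel_time(cfg: TimingConfig) -> float:
    """T3 = L1 / V1."""
    if cfg.V1 <= 0:
        raise ValueError("V1 must be > 0")
    return cfg.L1 / cfg.V1


def required_delay(cfg: TimingConfig) -> float:
    """T4 such that T1 + T2 + T4 = T3; raises if the chain is infeasible."""
    t4 = travel_time(cfg) - cfg.T1 - fall_time(cfg)
    if t4 < 0:
        raise InfeasibleTimingError(
            f"platform too fast: T1 + T2 exceeds T3 by {-t4:.4f} s")
    return t4


def simulate_run(layout: FieldLayout, cfg: TimingConfig,
                 detector: DetectorModel = DetectorModel(),
                 timing_jitter_sd: float = 0.0,
                 speed_jitter_sd: float = 0.0,
                 speed_estimate_error_sd: float = 0.0,
                 seed: int = 0) -> list[DeliveryOutcome]:
    """Simulate one pass over a plant row.

    Each plant is detected with probability ``p_detect``.  On detection the
    release is scheduled ``T1 + T2 + T4`` after the plant crosses the
    camera line, where ``T4`` is recomputed from the (possibly erroneous)
    speed estimate; the granule lands where the funnel is at release time
    plus the fall displacement.  A plant is *delivered* iff the landing
    point is within the layout tolerance of the plant.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    outcomes = []
    for pos, detectable in zip(layout.positions, layout.detectable):
        v = cfg.V1 + (rng.normal(0, speed_jitter_sd) if speed_jitter_sd else 0.0)
        v = max(v, 1e-6)
        detected = detectable and rng.random() < detector.p_detect
        if not detected:
            outcomes.append(DeliveryOutcome(False, False, float("nan")))
            continue
        v_est = v + (rng.normal(0, speed_estimate_error_sd)
                     if speed_estimate_error_sd else 0.0)
        est_cfg = replace(cfg, V1=max(v_est, 1e-6))
        t4 = required_delay(est_cfg)       # compensation from estimated speed
        delay = cfg.T1 + fall_time(cfg) + t4
        if timing_jitter_sd:
            delay += rng.normal(0, timing_jitter_sd)
        sensed = pos + (rng.normal(0, detector.center_error_sd)
                        if detector.center_error_sd else 0.0)
        # camera sees the plant when the funnel is L1 behind it; the funnel
        # covers v*delay during the signal+fall chain
        landing = (sensed - cfg.L1) + v * delay
        offset = landing - pos
        outcomes.append(DeliveryOutcome(True, abs(offset) <= layout.tolerance,
                                        float(offset)))
    return outcomes


def outcome_counts(outcomes) -> tuple[int, int, int]:
    """(n_total, n_identified, n_success) from a list of outcomes."""
    n_total = len(outcomes)
    n_ident = sum(o.detected for o in outcomes)
    n_succ = sum(o.delivered for o in outcomes)
    return n_total, n_ident, n_succ
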