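"""Agri Spray Decision System: per-frame trigger logic and signal packets.

A detection triggers a release command when its *center point* lies inside
the configured decision rectangle (edges inclusive); the trigger test uses
only the center, matching the post-processing pseudocode that hands the
decision routine the detection's (x, y).  A refractory window debounces the
region so one plant crossing emits exactly one packet.  Packets are plain
ASCII ``X<x>,Y<y>,C<centi-confidence>\\n`` lines pushed to a byte sink (a
file or loopback object stands in for the serial port).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

__all__ = ["DetectionBox", "DecisionRegion", "SignalPacket", "EngineState",
           "intersects_region", "format_signal", "parse_signal",
           "process_frame", "run_stream", "DEFAULT_CONF_THRES",
           "DEFAULT_IOU_THRES", "DEFAULT_REFRACTORY_FRAMES"]

log = logging.getLogger(__name__)

# operating point used in the field protocol
DEFAULT_CONF_THRES = 0.25
DEFAULT_IOU_THRES = 0.45
# ~0.5 s at 30 fps
DEFAULT_REFRACTORY_FRAMES = 15


@dataclass(frozen=True)
class DetectionBox:
    """Pixel-space detection; origin top-left, x right, y down."""
    x: float
    y: float
    w: float
    h: float
    conf: float
    cls: int = 0

    def __post_init__(self):
        if not (0.0 <= self.conf <= 1.0):
            raise ValueError("confidence must be in [0, 1]")
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box extent must be positive")


@dataclass(frozen=True)
class DecisionRegion:
    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError("region must satisfy x1 < x2 and y1 < y2")


@dataclass(frozen=True)
class SignalPacket:
    x: int
    y: int
    confidence_centi: int


@dataclass
class EngineState:
    refractory_remaining: int = 0
    region_occupied: bool = False

    def __post_init__(self):
        if self.refractory_remaining < 0:
            raise ValueError("refractory count must be >= 0")


def intersects_region(det: DetectionBox, region: DecisionRegion) -> bool:
    """True iff the detection center lies inside the region (edges inclusive)."""
    return (region.x1 <= det.x <= region.x2
            and region.y1 <= det.y <= region.y2)


def format_signal(x: float, y: float, conf: float) -> bytes:
    if not (0.0 <= conf <= 1.0):
        raise ValueError("confidence must be in [0, 1]")
    return f"X{int(round(x))},Y{int(round(y))},C{int(round(100 * conf))}\n" \
        .encode("ascii")


def parse_signal(packet: bytes) -> SignalPacket:
    text = packet.decode("ascii").strip()
    xs, ys, cs = text.split(",")
    if not (xs.startswith("X") and ys.startswith("Y") and cs.startswith("C")):
        raise ValueError(f"malformed packet {text!r}")
    return SignalPacket(int(xs[1:]), int(ys[1:]), int(cs[1:]))


def process_frame(dets, region: DecisionRegion, state: EngineState,
                  conf_thres: float = DEFAULT_CONF_THRES,
                  refractory_frames: int = DEFAULT_REFRACTORY_FRAMES):
    """Process one frame of (already NMS-filtered) detections.

    Returns ``(packets, new_state)``.  All detections whose centers are in
    the region trigger in the same frame; the region then enters a
    refractory window during which no further packets are emitted.
    """
    new_state = replace(state)
    if new_state.refractory_remaining > 0:
        new_state.refractory_remaining -= 1

    packets: list[bytes] = []
    triggering = []
    for d in dets:
        try:
            if not isinstance(d, DetectionBox):
                d = DetectionBox(**d)
        except (TypeError, ValueError) as exc:
            log.warning("malformed detection skipped: %s", exc)
            continue
        if d.conf < conf_thres:
            continue
        if intersects_region(d, region):
            triggering.append(d)

    if triggering and state.refractory_remaining == 0:
        for d in triggering:
            packets.append(format_signal(d.x, d.y, d.conf))
        new_state.refractory_remaining = refractory_frames
    new_state.region_occupied = bool(triggering)
    return packets, new_state


def run_stream(frames, region: DecisionRegion, sink=None,
               conf_thres: float = DEFAULT_CONF_THRES,
               refractory_frames: int = DEFAULT_REFRACTORY_FRAMES):
    """Drive the engine over an iterable of frame dicts (``{"frame", "boxes"}``)
    or plain detection lists; write packets to ``sink`` if given.

    Returns the full list of emitted packets (bytes)."""
    state = EngineState()
    out: list[bytes] = []
    for frame in frames:
        dets = frame.get("boxes", []) if isinstance(frame, dict) else frame
        packets, state = process_frame(dets, region, state, conf_thres,
                                       refractory_frames)
        for p in packets:
            out.append(p)
            if sink is not None:
                sink.write(p)
    return out


def load_jsonl(path):
    """Read a JSON-lines detection stream file."""
    frames = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                frames.append(json.loads(line))
    return frames
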