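"""LED-driver command language, pulse semantics and stimulus schedules.

The LED driver (five channels: red, green, blue, white, infrared)
accepts compact JSON objects over serial or an MQTT topic; the same
format is used on both transports. Intensities are PWM duty values on a
0–1000 scale; an optional ``pulse`` key (milliseconds) makes the command
a temporary flash after which the previous light state is restored.
Omitted channels are left untouched, so commands compose: e.g.
``{"r":100,"ir":1000}`` sets dim red actinic light plus full infrared
imaging light, and ``{"pulse":100,"b":1000}`` then flashes blue for
100 ms without disturbing that state.

Transports are thin byte sinks: an in-memory mock for testing, plus
optional serial (115200 baud) and MQTT classes that import their
backends lazily.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "LightCommand",
    "DriverState",
    "StimulusSchedule",
    "build_command",
    "parse_command",
    "apply_command",
    "schedule_to_trace",
    "MockTransport",
]

CHANNELS = ("r", "g", "b", "w", "ir")
_KEY_ORDER = ("pulse",) + CHANNELS
MAX_INTENSITY = 1000


@dataclass(frozen=True)
class LightCommand:
    """One driver instruction: channel intensities plus optional pulse.

    All fields are optional but at least one must be present; intensities
    lie in [0, 1000], ``pulse_ms`` is a non-negative duration in ms.
    """

    r: int | None = None
    g: int | None = None
    b: int | None = None
    w: int | None = None
    ir: int | None = None
    pulse_ms: int | None = None

    def __post_init__(self) -> None:
        if all(
            getattr(self, k) is None for k in CHANNELS
        ) and self.pulse_ms is None:
            raise ValueError("command must set at least one field")
        for key in CHANNELS:
            val = getattr(self, key)
            if val is None:
                continue
            if not isinstance(val, (int, np.integer)) or isinstance(val, bool):
                raise ValueError(f"'{key}' must be an integer")
            if not 0 <= val <= MAX_INTENSITY:
                raise ValueError(f"'{key}' out of range 0–1000: {val}")
        if self.pulse_ms is not None:
            if not isinstance(self.pulse_ms, (int, np.integer)) or isinstance(
                self.pulse_ms, bool
            ):
                raise ValueError("'pulse' must be an integer")
            if self.pulse_ms < 0:
                raise ValueError("'pulse' must be >= 0 ms")

    def channels(self) -> dict[str, int]:
        """The explicitly set channel intensities."""
        return {k: getattr(self, k) for k in CHANNELS if getattr(self, k) is not None}


def build_command(
    r: int | None = None,
    g: int | None = None,
    b: int | None = None,
    w: int | None = None,
    ir: int | None = None,
    pulse_ms: int | None = None,
) -> str:
    """Serialise a command to the compact wire format.

    Only the provided keys appear; key order is ``pulse`` first, then
    r, g, b, w, ir, with no whitespace — byte-exact with the driver's
    documented examples.
    """
    cmd = LightCommand(r=r, g=g, b=b, w=w, ir=ir, pulse_ms=pulse_ms)
    obj: dict[str, int] = {}
    if cmd.pulse_ms is not None:
        obj["pulse"] = int(cmd.pulse_ms)
    for key in CHANNELS:
        val = getattr(cmd, key)
        if val is not None:
            obj[key] = int(val)
    return json.dumps(obj, separators=(",", ":"))


def serialize_command(cmd: LightCommand) -> str:
    """Wire text of an existing :class:`LightCommand`."""
    return build_command(
        r=cmd.r, g=cmd.g, b=cmd.b, w=cmd.w, ir=cmd.ir, pulse_ms=cmd.pulse_ms
    )


def _reject_duplicates(pairs):
    seen = set()
    out = {}
    for k, v in pairs:
        if k in seen:
            raise ValueError(f"duplicate key {k!r}")
        seen.add(k)
        out[k] = v
    return out


def parse_command(text: str) -> LightCommand:
    """Parse wire text back into a :class:`LightCommand` (strict).

    Unknown keys, duplicate keys, non-integer values and out-of-range
    intensities are all rejected. ``parse_command(build_command(...))``
    is the identity on the valid domain.
    """
    try:
        obj = json.loads(text, object_pairs_hook=_reject_duplicates)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed command text: {exc}") from exc
    if not isinstance(obj, dict):
        raise ValueError("command must be a JSON object")
    unknown = set(obj) - set(_KEY_ORDER)
    if unknown:
        raise ValueError(f"unknown keys: {sorted(unknown)}")
    for k, v in obj.items():
        if not isinstance(v, int) or isinstance(v, bool):
            raise ValueError(f"value of {k!r} must be an integer, got {v!r}")
    return LightCommand(
        r=obj.get("r"),
        g=obj.get("g"),
        b=obj.get("b"),
        w=obj.get("w"),
        ir=obj.get("ir"),
        pulse_ms=obj.get("pulse"),
    )


@dataclass
class DriverState:
    """Simulated driver: current intensities plus pulse bookkeeping.

    After a pulse elapses the pre-pulse state is restored. A non-pulse
    command received during an active pulse takes effect immediately and
    also updates the state restored at pulse end (last-writer-wins per
    channel). A second pulse while one is active is rejected — the
    firmware behaviour is unspecified, so the model refuses rather than
    guesses.
    """

    intensities: dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in CHANNELS}
    )
    pending_restore: dict[str, int] | None = None
    pulse_end_ms: float | None = None

    def settle(self, now_ms: float) -> "DriverState":
        """Restore the pre-pulse state if the active pulse has elapsed."""
        if self.pulse_end_ms is not None and now_ms >= self.pulse_end_ms:
            return DriverState(intensities=dict(self.pending_restore))
        return self


def apply_command(state: DriverState, cmd: LightCommand, now_ms: float = 0.0) -> DriverState:
    """Apply one command at time ``now_ms``; returns the new state."""
    state = state.settle(now_ms)
    new_int = dict(state.intensities)
    new_int.update(cmd.channels())
    if cmd.pulse_ms is not None:
        if state.pulse_end_ms is not None:
            raise ValueError("a pulse is already active; overlapping pulses rejected")
        return DriverState(
            intensities=new_int,
            pending_restore=dict(state.intensities),
            pulse_end_ms=now_ms + cmd.pulse_ms,
        )
    if state.pulse_end_ms is not None:
        restore = dict(state.pending_restore)
        restore.update(cmd.channels())
        return DriverState(
            intensities=new_int,
            pending_restore=restore,
            pulse_end_ms=state.pulse_end_ms,
        )
    return DriverState(intensities=new_int)


@dataclass
class StimulusSchedule:
    """Ordered light events aligned to recording time.

    Events are ``(onset_s, LightCommand)`` with strictly increasing
    onsets, all within ``duration_s``.
    """

    events: list[tuple[float, LightCommand]]
    duration_s: float

    def __post_init__(self) -> None:
        onsets = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        if onsets and (onsets[0] < 0 or onsets[-1] > self.duration_s):
            raise ValueError("events must lie within [0, duration_s]")

    @property
    def pulse_onsets_s(self) -> list[float]:
        """Onsets of the pulsed (transient) events."""
        return [t for t, c in self.events if c.pulse_ms is not None]

    def to_json(self) -> str:
        return json.dumps(
            {
                "duration_s": self.duration_s,
                "events": [
                    {"t": t, "cmd": json.loads(serialize_command(c))}
                    for t, c in self.events
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "StimulusSchedule":
        d = json.loads(text)
        events = [
            (float(e["t"]), parse_command(json.dumps(e["cmd"])))
            for e in d["events"]
        ]
        return cls(events=events, duration_s=float(d["duration_s"]))


def schedule_to_trace(
    schedule: StimulusSchedule, frame_rate: float, n_frames: int
) -> pd.DataFrame:
    """Per-frame channel intensities obtained by simulating the driver.

    Frame ``i`` samples the driver state at time ``i / frame_rate``.
    Events past the end of the recording are ignored with a warning.
    Used to align analysis windows with stimulus pulses.
    """
    import warnings

    state = DriverState()
    times_ms = np.arange(n_frames) / frame_rate * 1000.0
    events = list(schedule.events)
    for t, _ in events:
        if t * 1000.0 > times_ms[-1]:
            warnings.warn(
                f"stimulus event at {t} s is past the recording end; ignored",
                stacklevel=2,
            )
    rows = []
    ev = 0
    for i, now in enumerate(times_ms):
        while ev < len(events) and events[ev][0] * 1000.0 <= now:
            state = apply_command(state, events[ev][1], events[ev][0] * 1000.0)
            ev += 1
        state = state.settle(now)
        rows.append({"frame": i, "time_s": now / 1000.0, **state.intensities})
    return pd.DataFrame(rows)


class MockTransport:
    """In-memory transport: records every line it is given."""

    def __init__(self) -> None:
        self.sent: list[str] = []

    def send(self, text: str) -> None:
        self.sent.append(text)


class SerialTransport:
    """USB-serial transport for a physical driver (115200 baud default).

    Requires ``pyserial``; imported lazily so the package works without it.
    """

    def __init__(self, port: str, baudrate: int = 115200) -> None:
        try:
            import serial  # type: ignore[import-not-found]
        except ImportError as exc:
            raise ImportError("SerialTransport requires the pyserial package") from exc
        self._conn = serial.Serial(port, baudrate=baudrate)

    def send(self, text: str) -> None:
        self._conn.write(text.encode("ascii") + b"\n")


class MqttTransport:
    """MQTT transport publishing commands to a driver topic.

    Requires ``paho-mqtt``; imported lazily.
    """

    def __init__(self, host: str, topic: str, port: int = 1883) -> None:
        try:
            import paho.mqtt.client as mqtt  # type: ignore[import-not-found]
        except ImportError as exc:
            raise ImportError("MqttTransport requires the paho-mqtt package") from exc
        self._client = mqtt.Client()
        self._client.connect(host, port)
        self._topic = topic

    def send(self, text: str) -> None:
        self._client.publish(self._topic, text)
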