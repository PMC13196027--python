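"""The LED-driver command language and pulse-and-restore semantics.

Builds wire-format commands, simulates the driver state machine and
expands a stimulus schedule into a per-frame illumination trace.
"""

from microswim import (
    DriverState,
    LightCommand,
    MockTransport,
    StimulusSchedule,
    apply_command,
    build_command,
    parse_command,
    schedule_to_trace,
)

# compact wire format: only the specified channels appear
blue_pulse = build_command(b=1000, pulse_ms=100)
imaging = build_command(r=100, ir=1000)
print("100 ms blue flash at full intensity:", blue_pulse)
print("dim red actinic + full infrared imaging light:", imaging)
print("round-trips:", parse_command(blue_pulse), sep="\n  ")

# driver semantics: a pulse restores the previous state afterwards
state = apply_command(DriverState(), parse_command(imaging), now_ms=0)
state = apply_command(state, parse_command(blue_pulse), now_ms=5000)
print("\nduring pulse: ", state.intensities)
print("after pulse:  ", state.settle(now_ms=5101).intensities,
      " (imaging light restored)")

# a schedule expanded to per-frame channel intensities at 30 fps
sched = StimulusSchedule(
    events=[(0.0, parse_command(imaging)),
            (1.0, parse_command(blue_pulse))],
    duration_s=3.0,
)
trace = schedule_to_trace(sched, frame_rate=30.0, n_frames=90)
lit = trace[trace.b > 0]
print(f"\nblue channel lit in frames {lit.frame.min()}-{lit.frame.max()} "
      f"({len(lit)} frames = 100 ms at 30 fps)")

# transports are byte sinks; the in-memory mock records what would be sent
mock = MockTransport()
mock.send(imaging)
mock.send(blue_pulse)
print("sent over mock transport:", mock.sent)
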