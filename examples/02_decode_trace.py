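"""Open-loop anatomy of one selection: synthesise a pupil trace for an
attended stimulus, measure it cycle by cycle, and step the decoder.

The trace follows the attended item's brightness through a sluggish
light response, so the median pupil size in the last 0.25 s of each
cycle rises after the item darkens and falls after it brightens.  The
per-cycle ratio of these medians (PPSD) multiplies the likelihood of
the bright-to-dark group and divides the other until the ratio clears
the threshold T = 1.375.
"""

from pupilhci import (
    DecoderConfig,
    DisplayConfig,
    SelectionTreeState,
    make_partition,
    measure_ps,
    run_selection,
)
from pupilhci.pupilsim import (
    ParticipantProfile,
    attended_luminance_series,
    simulate_trace,
)
from pupilhci.schedule import CycleSchedule

display = DisplayConfig()
rate = 250.0
n_cycles = 40
schedule = CycleSchedule(display, make_partition(("a", "b")), n_cycles)

# the participant covertly attends 'b' (noise kept small for clarity)
profile = ParticipantProfile(drift_sd=8.0, sample_noise_sd=10.0,
                             blink_rate=0.0, seed=5)
lum = attended_luminance_series(schedule, "b", rate)
transitions = [c * display.cycle_period + display.transition_duration
               for c in range(n_cycles)]
trace = simulate_trace(profile, lum, transitions, rate)


def measurements():
    for c in range(n_cycles):
        end = (c + 1) * display.cycle_period
        yield measure_ps(trace, end - display.measurement_window, end,
                         cycle_index=c)


tree = SelectionTreeState.start(("a", "b"))
outcome = run_selection(measurements(), tree, DecoderConfig())

print(f"selected item : {outcome.selected_item!r} (attended 'b')")
print(f"cycles needed : {outcome.n_cycles} "
      f"({outcome.elapsed_time:.2f} s at 1.25 s/cycle)")
print("per-cycle evidence (PPSD, cumulative log-ratio):")
for c, (ppsd_value, log_ratio) in enumerate(outcome.trajectory):
    shown = "baseline" if ppsd_value is None else f"{ppsd_value:.4f}"
    print(f"  cycle {c:2d}: PPSD {shown:>8s}   log L1/L2 {log_ratio:+.4f}")
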