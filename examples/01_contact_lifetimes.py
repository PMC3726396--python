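"""Contact statistics of a scheduled two-group trajectory.

Builds a 50 ns synthetic trajectory in which a linker-like Lys-Arg-Tyr motif
touches a TI-loop-like Asp-Phe-Glu motif during two prescribed windows, then
computes the statistics an MD analysis would report: mean contacts over the
last 30 ns, bound/unbound populations in 100 ps steps, and the maximal
contact lifetime.
"""
import numpy as np

from vsplink import (
    AtomSelection,
    ContactScheduleSpec,
    contact_series,
    max_contact_lifetime,
    residue_contact_table,
    state_population,
    synth_contact_trajectory,
    window_stats,
)

spec = ContactScheduleSpec(
    duration_ns=50.0,
    frame_interval_ns=0.1,
    bound_intervals=((5.0, 29.2), (35.0, 48.0)),
    noise_sd_A=0.05,
    seed=42,
)
traj, truth = synth_contact_trajectory(spec)

linker = AtomSelection.residue_range(252, 255, label="linker 252-255")
ti_loop = AtomSelection.residue_range(400, 402, label="TI loop 400-402")
series = contact_series(traj, linker, ti_loop, cutoff=3.5)

mean, sd = window_stats(series, 20.0, 50.0)  # last 30 ns
bound, unbound = state_population(series, sample_interval=0.1)
lifetime = max_contact_lifetime(series, sample_interval=0.1)

print(f"pair: {series.group_a} vs {series.group_b} (cutoff {series.cutoff} Å)")
print(f"mean contacts, last 30 ns : {mean:.1f} ± {sd:.1f}")
print(f"states (bound – unbound)  : {bound} – {unbound} of {bound + unbound}")
print(f"maximal contact lifetime  : {lifetime:.1f} ns")
print()
print("Per-residue breakdown (dominant interaction class over the full run):")
table = residue_contact_table(traj, [252, 253, 255], ti_loop)
print(table.to_string(index=False))
print()
print(
    "The populations count 100-ps-spaced states with >0 contacts; the lifetime\n"
    "is the longest unbroken bound run — here it matches the longest scheduled\n"
    f"window, {max(b - a for a, b in spec.bound_intervals) + 0.1:.1f} ns of grid samples."
)
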