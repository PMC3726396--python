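"""Reporter-channel inhibition metrics: I_max, I_min, ratio and τ50.

Simulates a PI(4,5)P2-sensitive reporter-channel current during a
depolarization step: the channel activates, then decays as the phosphatase
depletes its lipid. A highly active enzyme suppresses ~99% of the current;
an impaired one leaves more residual current and takes longer to reach 50%
inhibition.
"""
import numpy as np

from vsplink import ChannelSpec, activity_metrics, synth_channel_sweep

scenarios = {
    "active phosphatase": ChannelSpec(
        activation_tau_ms=0.2, inhibition_rate_per_ms=0.01, floor_fraction=0.01,
        duration_ms=1000.0, sample_interval_ms=1.0,
    ),
    "impaired mutant": ChannelSpec(
        activation_tau_ms=0.2, inhibition_rate_per_ms=0.002, floor_fraction=0.40,
        duration_ms=1000.0, sample_interval_ms=1.0,
    ),
}

for name, spec in scenarios.items():
    m = activity_metrics(synth_channel_sweep(spec))
    tau50 = f"{m.tau50_ms:.0f} ms" if m.tau50_ms is not None else "never reached"
    print(f"{name:20s}: I_max = {m.I_max:.3f} µA  I_min = {m.I_min:.3f} µA  "
          f"inhibition = {m.inhibition_ratio:.2f}  τ50 = {tau50}")

k = scenarios["active phosphatase"].inhibition_rate_per_ms
print()
print(
    f"For fast activation the τ50 of the active enzyme approaches ln2/k = "
    f"{np.log(2) / k:.0f} ms;\nan inhibition ratio near 0.99 corresponds to almost "
    "complete current suppression,\nwhile ~0.6 marks a strongly impaired catalytic domain."
)
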