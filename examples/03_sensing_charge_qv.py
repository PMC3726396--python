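"""Off-sensing-charge analysis: exponential fits, charge, Boltzmann Q–V.

Simulates a family of off-sensing current sweeps (test pulses −40…+160 mV,
off step to −50 mV) whose total charge follows a Boltzmann curve with
V_half = 30 mV and z_q = 0.78, then runs the full quantification pipeline:
mono/biexponential fitting with χ² model selection, Q = I·τ charge
decomposition, normalization at +120 mV and the Boltzmann fit.
"""
from vsplink import QVFamilySpec, analyze_off_sweeps, synth_qv_family

spec = QVFamilySpec(V_half_mV=30.0, z_q=0.78, seed=11)
sweeps, truth = synth_qv_family(spec)

qv, bfit, fits = analyze_off_sweeps(sweeps, fit_start_ms=5.0, norm_voltage=120.0)

print("per-voltage decomposition (normalized to Q_all at +120 mV):")
print(qv.table.to_string(index=False, float_format=lambda x: f"{x: .3f}"))
print()
print("model selected per voltage:",
      {v: fits[v].n_components for v in sorted(fits)})
print()
print(f"Boltzmann fit : V_half = {bfit.V_half:.1f} mV   z_q = {bfit.z_q:.3f}")
print(f"ground truth  : V_half = {truth.V_half:.1f} mV   z_q = {truth.z_q:.3f}")
print()
print(
    "Q_fast dominates after weak depolarisations and Q_slow after strong ones\n"
    "(the generator's logistic fast-fraction); V_half is the midpoint of charge\n"
    "movement and z_q the effective gating valence — a right-shifted V_half or a\n"
    "monoexponential (fast-only) off-decay signals weakened linker-domain coupling."
)
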