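# Methods

`vsplink` quantifies how the linker between a transmembrane voltage-sensor
domain (VSD) and an intracellular catalytic domain (CD) couples the two — as
in the *Ciona intestinalis* voltage-sensitive phosphatase Ci-VSP, where the
18-residue linker M240–K257 contacts the TI loop (≈398–414) at the active
site. It implements two independent analysis arms plus the synthetic-data
generators used to validate them end to end.

## Conventions and units

Coordinates are Å, trajectory times ns, currents µA, sweep times ms, charge
nC (µA·ms), voltages mV, temperature K. Residue numbering follows the Ci-VSP
sequence and is never re-indexed. Hydrogens are kept when present and
selections default to all atoms; a heavy-only class exists. All inter-atomic
distances are plain Euclidean distances — there is no minimum-image/PBC
handling, which is a known limitation for genuinely periodic simulation
boxes (the synthetic fixtures are non-periodic, and for a linker–loop
interface far from the box boundary the difference is negligible).

## Contact statistics

A *contact* is an unordered atom pair, one atom from each of two disjoint
groups, with distance ≤ cutoff (default 3.5 Å). Counting **pairs** rather
than "atoms within the sphere" was a deliberate choice: pair counts are
symmetric in the two groups and exactly additive over any partition of one
group into residues, which makes per-residue tables sum to the group total.
A flag-level alternative (counting unique atoms) was considered and
rejected because it has neither property. The boundary is inclusive
(d ≤ cutoff) so that counts are deterministic statements in tests.

Windowed means (e.g. over the last 30 ns) use the population standard
deviation over frames. Bound/unbound populations are evaluated on a fixed
grid (default every 100 ps): a state is bound when the count is > 0. The
grid starts one interval in — t = s, 2s, …, duration — so a 50 ns run
sampled at 100 ps yields exactly 500 states; the t = 0 frame is the
pre-production structure and is excluded by default (`include_t0` restores
it). The maximal contact lifetime is the longest unbroken run of bound
sampled states times the interval; a single unbound sample breaks the run
(`gap_tolerance` can bridge short gaps but defaults to 0, i.e. beyond the
cutoff a contact counts as broken).

Interaction classification is identity-based, not geometric: a salt bridge
is a basic side-chain nitrogen (Lys NZ; Arg NE/NH1/NH2) against a
carboxylate oxygen (Asp OD1/OD2; Glu OE1/OE2); a hydrogen bond is any other
N/O–N/O pair (no angle criterion); carbon–carbon is hydrophobic; everything
else is "other". The per-residue table reports the modal class among
in-cutoff pairs over the analysis window, with deterministic tie-breaking
toward the more specific class (salt bridge > H-bond > hydrophobic > other).

## Structure metrics

Superposition is the standard least-squares (Kabsch) solution via SVD with
the determinant correction that excludes reflections; collinear point sets
are rejected as degenerate. Region RMSD pairs atoms by (residue number,
atom name) over the backbone set {N, CA, C, O} and by default superposes on
the compared region's own backbone; an `align_range` lets the caller anchor
the alignment elsewhere (e.g. a domain core) when the question is "how far
did this region move relative to that frame".

The helix bend angle at a pivot residue is the angle between axis fits
through the CA atoms of the four residues before and after the pivot.
The axis of each short segment is estimated by the bisector cross-product
construction: for consecutive CAs, b_i = (CA_{i−1} − CA_i) + (CA_{i+1} −
CA_i) points from the surface toward the helix axis, and b_i × b_{i+1} is
parallel to the axis (exact on ideal helical geometry). A plain principal
component of the centered CAs was evaluated and rejected: for a 4-CA
segment of an ideal helix (radius 2.3 Å, rise 1.5 Å/residue, 100°/residue)
the cross-sectional variance (≈3.0 Ų) exceeds the axial variance
(≈2.8 Ų), so the first PC lies in the helix cross-section and the angle is
meaningless. The bisector axis is exact in the noiseless case and degrades
gracefully with coordinate noise; signs are fixed along increasing residue
number, so 0° means straight.

## Off-sensing-current analysis

Off-currents are modelled as I(t) = I₀ + Σᵢ I_off,i·exp(−t/τ_off,i) with
N ∈ {1, 2} and t = 0 at the off-pulse onset. Fitting uses unweighted least
squares (lmfit) on samples with t ≥ 5 ms — the first 5 ms are excluded to
drop residual capacitive artefacts — while the amplitudes remain referenced
to t = 0 through the fitted function. Initial values come from log-linear
regression of the trace tail (slow component) and of the early residual
(fast component); five deterministic jittered restarts guard against local
minima and the lowest-SSE solution wins. Components are reported in
canonical ascending-τ order. χ² is the plain sum of squared residuals over
the fit window.

Model selection takes the fit (N = 1 vs N = 2) with the smaller χ², after a
resolvability guard demotes degenerate biexponentials: τ_slow/τ_fast below
3; either component's magnitude *at the start of the fit window* below the
noise floor (a component that decayed before t = 5 ms is unobservable no
matter how large its extrapolated t = 0 amplitude); or τ_slow longer than
the fitted window (indistinguishable from the baseline offset). The latter
two conditions matter in practice: with χ² alone, nearly half of noisy
monoexponential sweeps are "improved" by a spurious second exponential that
is either a pre-window spike or a quasi-constant drift. With the guard the
selection is correct in 100/100 seeded runs at 1% noise while genuinely
biexponential sweeps (τ 8 vs 80 ms) are kept at N = 2.

Charge per component is Q_i = I_off,i · τ_off,i (µA·ms = nC, the analytic
integral of the component from the off-pulse onset); the baseline carries
no charge, and Q_all = Q_fast + Q_slow holds exactly by construction. Q–V
tables are normalized to Q_all at +120 mV and fitted with

    Q(V) = A_min + (A_max − A_min) / (1 + exp(−z_q F (V − V_half) / (R T)))

with z_q constrained positive (charge increases with depolarisation) and
T defaulting to 295.15 K (recordings at 21–23 °C). At least five voltage
points are required. Only Q_all is Boltzmann-fitted; the fast/slow fractions
are reported but not separately fitted.

Reporter-channel sweeps are summarised by I_max (maximum during the test
phase), I_min (minimum after the I_max time), inhibition ratio
1 − I_min/I_max, and τ50 — the first time the current falls to I_max/2,
measured from the time of I_max. Referencing τ50 to the I_max time (rather
than pulse onset) makes it independent of the channel's activation delay;
a `reference="onset"` option provides the alternative.

## Synthetic data: what it emulates, what it does not

`ContactScheduleSpec` builds two rigid residue groups — by default a
Lys252/Arg253/Tyr255 motif versus Asp400/Phe401/Glu402, real names so the
classifier sees genuine salt-bridge and hydrophobic identities — whose
designated contact atoms (Arg NH1 vs Asp OD1 by default) sit exactly at the
bound distance (3.0 Å) on scheduled frames and the unbound distance (8.0 Å)
otherwise; every other atom is recessed ≥ 2.2 Å behind its group's contact
atom, so the designated pair is always the minimum-distance pair. I.i.d.
Gaussian positional noise is added per atom per frame. The spec validates
recoverability: bound + 3σ < cutoff < unbound − 3σ. The geometry is
schematic — it reproduces the *statistical* structure the contact analysis
assumes (on/off schedule, noise, realistic identities), not side-chain
stereochemistry, solvent, or a force field. Passing tests therefore
demonstrate correctness of the accounting, not fidelity to any real
trajectory; real MD frames additionally feature periodic boxes, partial
occupancy and correlated motion that these fixtures do not model.

`synth_helix` places backbone atoms on ideal helical geometry (rise 1.5 Å,
100°/residue, CA radius 2.3 Å) with an optional rigid kink at a pivot, so
the generated bend angle is exact ground truth. `SweepSpec` renders sums of
exponentials plus an optional sub-5-ms artefact and Gaussian current noise;
a sweep shorter than 10× its slowest τ is flagged `truncated` (the default
500 ms off-pulse with τ_slow = 80 ms is deliberately such a protocol).
`QVFamilySpec` makes the total charge follow a Boltzmann curve (defaults
V_half = 30 mV, z_q = 0.78, within the range reported for wild-type-like
sensors) and splits it fast/slow by a logistic fraction of voltage
(fast-dominated at negative potentials), with a 40 nC full-scale charge —
a realistic magnitude for an oocyte expressing a sensor at high density.
`ChannelSpec` multiplies an activation saturation by an exponential
inhibition toward a floor; with activation ≪ 1/k, τ50 → ln 2/k and the
final inhibition ratio → 1 − floor, which is how the closed-form tests and
the worked examples are constructed.

All generators are deterministic under a fixed seed (numpy
`default_rng`), and every spec serialises losslessly to a flat key=value
config read back by `spec_from_config`.

## Numerical choices and degenerate inputs

* Cutoff comparisons and window bounds are inclusive with a 1e-9 tolerance
  on time comparisons.
* Sampling grids must be integer multiples of the frame spacing (checked to
  1e-6 relative); non-uniform trajectories are rejected where uniformity is
  assumed.
* PDB coordinates round-trip at the format's 3-decimal precision; structure
  equality uses a 5e-4 Å tolerance accordingly.
* Kabsch requires ≥ 3 non-collinear points; rank is checked at 1e-8.
* Exponential τ is bounded to [1e-4, 100×window] during fitting; fit
  failure from every restart raises a `FitError` carrying diagnostics.
* Zero charge at the normalization voltage, a missing +120 mV anchor, or
  fewer than 5 Q–V points are hard errors, not warnings.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on synthetic data at
the scale the analyses are specified for: 50 ns schedules at 100 ps frames
(501 frames, ~60 atoms), 100 random 20+20-atom contact fixtures, 50 random
schedules for exact recovery, 10-point superposition toys against a
three-stage rotation-grid search, 100-seed Monte-Carlo fit recovery at 1–2%
current noise, and 11-voltage Q–V families. These sizes were chosen as the
smallest at which every statistic is well determined.

## Known limitations

* No periodic-boundary distances; no hydrogen-bond angle criteria; no
  water-mediated contacts.
* No DSSP secondary-structure assignment, per-residue RMSF or trajectory
  averaging.
* No leak/capacitance subtraction beyond the 5 ms window cut; no on-current
  analysis; binary acquisition formats (ABF, DCD/XTC) must be converted to
  the text dialects upstream.
* The χ² model selection compares exactly N = 1 vs N = 2, matching the
  analysis it implements; it is not a general information criterion.
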