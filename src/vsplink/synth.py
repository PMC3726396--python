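"""Synthetic trajectories and voltage-clamp sweeps with known ground truth.

Every analysis stage in this package can be exercised without external data:
the generators here produce (a) rigid two-group trajectories following a
prescribed contact on/off schedule with Gaussian positional noise, (b) ideal
α-helices with an optional kink, (c) off-sensing current sweeps that are sums
of decaying exponentials with an optional fast capacitive artefact, (d) whole
Q–V families whose total off-charge follows a Boltzmann curve split into fast
and slow components, and (e) reporter-channel sweeps whose decay encodes
phosphatase activity.

The toy residue motifs carry real residue and atom names (Lys/Arg/Tyr versus
Asp/Phe/Glu, numbered like linker 252–255 and TI loop 400–402) so that
interaction classification runs on realistic identities; the geometry itself
is schematic, not physical. All generators are deterministic under a fixed
seed, and every spec serialises losslessly to a flat key=value config.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import SpecError
from .ephys import BoltzmannFit, Protocol, SweepTrace, boltzmann, DEFAULT_TEMPERATURE_K
from .model import Atom, Structure, Trajectory

__all__ = [
    "ContactScheduleSpec",
    "SweepSpec",
    "ChannelSpec",
    "QVFamilySpec",
    "synth_contact_trajectory",
    "synth_helix",
    "synth_sensing_sweep",
    "synth_qv_family",
    "synth_channel_sweep",
    "spec_to_config",
    "spec_from_config",
]

# Default residue/atom layouts for the two interacting groups: a Lys-Arg-Tyr
# motif (linker-like, 252/253/255) and an Asp-Phe-Glu motif (TI-loop-like,
# 400/401/402). Heavy atoms only; names are real so classify_pair sees
# genuine salt-bridge/hydrophobic identities.
DEFAULT_GROUP_A = (
    ("LYS", 252, ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ")),
    ("ARG", 253, ("N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2")),
    ("TYR", 255, ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH")),
)
DEFAULT_GROUP_B = (
    ("ASP", 400, ("N", "CA", "C", "O", "CB", "CG", "OD1", "OD2")),
    ("PHE", 401, ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ")),
    ("GLU", 402, ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2")),
)

GroupDef = tuple[tuple[str, int, tuple[str, ...]], ...]


@dataclass
class ContactScheduleSpec:
    """Two rigid residue groups with a prescribed bound/unbound schedule.

    On frames inside any ``bound_intervals`` window (inclusive, ns) the
    minimum inter-group distance equals ``bound_distance_A``; elsewhere it is
    ``unbound_distance_A``. The designated contact atoms (by residue number
    and atom name) are the closest pair by construction. Recoverability at
    ``cutoff_A`` demands bound < cutoff < unbound with margin over the noise.
    """

    duration_ns: float = 50.0
    frame_interval_ns: float = 0.1
    bound_intervals: tuple[tuple[float, float], ...] = ()
    group_a_def: GroupDef = DEFAULT_GROUP_A
    group_b_def: GroupDef = DEFAULT_GROUP_B
    contact_atom_a: tuple[int, str] = (253, "NH1")
    contact_atom_b: tuple[int, str] = (400, "OD1")
    bound_distance_A: float = 3.0
    unbound_distance_A: float = 8.0
    cutoff_A: float = 3.5
    noise_sd_A: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.bound_intervals = tuple(
            (float(a), float(b)) for a, b in self.bound_intervals
        )
        if self.duration_ns <= 0 or self.frame_interval_ns <= 0:
            raise SpecError("duration and frame interval must be positive")
        if not self.bound_distance_A < self.cutoff_A:
            raise SpecError("bound_distance must lie below the cutoff")
        if self.bound_distance_A + 3.0 * self.noise_sd_A >= self.cutoff_A:
            raise SpecError("noise too large: bound frames may leave the cutoff sphere")
        if self.cutoff_A >= self.unbound_distance_A - 3.0 * self.noise_sd_A:
            raise SpecError("noise too large: unbound frames may enter the cutoff sphere")
        last_end = -np.inf
        for start, end in sorted(self.bound_intervals):
            if start > end:
                raise SpecError(f"Interval [{start}, {end}] is reversed")
            if start < -1e-9 or end > self.duration_ns + 1e-9:
                raise SpecError(f"Interval [{start}, {end}] exceeds the duration")
            if start <= last_end:
                raise SpecError("bound_intervals overlap")
            last_end = end

    def frame_times(self) -> np.ndarray:
        n = int(round(self.duration_ns / self.frame_interval_ns))
        return np.arange(n + 1) * self.frame_interval_ns

    def bound_flags(self) -> np.ndarray:
        times = self.frame_times()
        flags = np.zeros(len(times), dtype=bool)
        for start, end in self.bound_intervals:
            flags |= (times >= start - 1e-9) & (times <= end + 1e-9)
        return flags


def _layout_group(
    group_def: GroupDef,
    contact_atom: tuple[int, str],
    side: int,
    serial_start: int,
) -> list[Atom]:
    """Place one rigid group with its designated contact atom frontmost.

    The contact atom sits at the local origin; every other atom is recessed
    at least 2.2 Å along the contact axis (``side`` = −1 for the left group,
    +1 for the right) on a deterministic spiral, so the designated pair is
    always the inter-group minimum-distance pair.
    """
    atoms: list[Atom] = []
    serial = serial_start
    i_other = 0
    found = False
    for resname, resnum, names in group_def:
        for name in names:
            if (resnum, name) == contact_atom:
                pos = np.zeros(3)
                found = True
            else:
                depth = 2.2 + 0.15 * i_other
                angle = 0.7 * i_other
                pos = np.array(
                    [side * depth, 1.3 * np.cos(angle), 1.3 * np.sin(angle)]
                )
                i_other += 1
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element="",
                    residue_name=resname,
                    residue_number=resnum,
                    chain="A",
                    position=pos,
                )
            )
            serial += 1
    if not found:
        raise SpecError(
            f"Contact atom {contact_atom} not present in the group definition"
        )
    return atoms


def synth_contact_trajectory(
    spec: ContactScheduleSpec,
) -> tuple[Trajectory, np.ndarray]:
    """Generate a scheduled two-group trajectory and its ground-truth flags.

    Returns the trajectory plus a boolean array (one flag per frame, True on
    scheduled-bound frames). Group geometries are rigid; i.i.d. Gaussian
    positional noise of ``noise_sd_A`` is added per atom per frame.
    """
    atoms_a = _layout_group(spec.group_a_def, spec.contact_atom_a, side=-1, serial_start=1)
    atoms_b = _layout_group(
        spec.group_b_def, spec.contact_atom_b, side=+1, serial_start=len(atoms_a) + 1
    )
    base_a = np.stack([a.position for a in atoms_a])
    base_b = np.stack([a.position for a in atoms_b])
    n_a = len(atoms_a)

    times = spec.frame_times()
    flags = spec.bound_flags()
    rng = np.random.default_rng(spec.seed)
    n_atoms = n_a + len(atoms_b)
    frames = np.empty((len(times), n_atoms, 3))
    for i, bound in enumerate(flags):
        sep = spec.bound_distance_A if bound else spec.unbound_distance_A
        coords = np.vstack([base_a, base_b + np.array([sep, 0.0, 0.0])])
        if spec.noise_sd_A > 0:
            coords = coords + rng.normal(0.0, spec.noise_sd_A, coords.shape)
        frames[i] = coords

    topology = Structure(atoms_a + atoms_b).with_coordinates(frames[0])
    return Trajectory(topology=topology, times=times, frames=frames), flags


# ---------------------------------------------------------------------------
# Ideal helix
# ---------------------------------------------------------------------------

_HELIX_RISE = 1.5  # Å per residue
_HELIX_TWIST = 100.0  # degrees per residue
_HELIX_RADIUS = 2.3  # Å (CA)

# (radius Å, phase offset deg, rise offset Å) per backbone atom
_BACKBONE_OFFSETS = {
    "N": (1.60, -26.0, -0.90),
    "CA": (_HELIX_RADIUS, 0.0, 0.0),
    "C": (1.70, 21.0, 1.10),
    "O": (2.00, 38.0, 1.70),
}


def synth_helix(
    n_residues: int,
    kink_deg: float = 0.0,
    kink_at: Optional[int] = None,
    seed: Optional[int] = None,
    noise_sd_A: float = 0.0,
    start_residue: int = 1,
) -> Structure:
    """Ideal α-helix backbone (rise 1.5 Å, 100°/residue), optionally kinked.

    With ``kink_at`` set, residues beyond that (1-based within the helix
    numbering) are rigidly rotated by ``kink_deg`` about an axis through the
    pivot CA perpendicular to the helix axis, so the angle between the two
    half-axes equals ``kink_deg`` exactly in the noiseless case.
    """
    if n_residues < 8:
        raise SpecError("Helix generation needs at least 8 residues for bend analysis")
    atoms: list[Atom] = []
    serial = 1
    for i in range(n_residues):
        resnum = start_residue + i
        phase = np.radians(_HELIX_TWIST * i)
        z = _HELIX_RISE * i
        for name, (radius, dphi, dz) in _BACKBONE_OFFSETS.items():
            ang = phase + np.radians(dphi)
            pos = np.array([radius * np.cos(ang), radius * np.sin(ang), z + dz])
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=name[0],
                    residue_name="ALA",
                    residue_number=resnum,
                    chain="A",
                    position=pos,
                )
            )
            serial += 1

    if kink_at is not None and kink_deg != 0.0:
        pivot_res = start_residue + kink_at - 1
        pivot_ca = next(
            a.position for a in atoms if a.residue_number == pivot_res and a.name == "CA"
        )
        theta = np.radians(kink_deg)
        # rotation about the x-axis (perpendicular to the helix axis z)
        rot = np.array(
            [
                [1.0, 0.0, 0.0],
                [0.0, np.cos(theta), -np.sin(theta)],
                [0.0, np.sin(theta), np.cos(theta)],
            ]
        )
        for atom in atoms:
            if atom.residue_number > pivot_res:
                atom.position = pivot_ca + rot @ (atom.position - pivot_ca)

    if noise_sd_A > 0:
        rng = np.random.default_rng(seed)
        for atom in atoms:
            atom.position = atom.position + rng.normal(0.0, noise_sd_A, 3)
    return Structure(atoms)


# ---------------------------------------------------------------------------
# Voltage-clamp sweep generators
# ---------------------------------------------------------------------------


@dataclass
class SweepSpec:
    """An off-sensing sweep: sum of exponential decays plus artefact and noise."""

    components: tuple[tuple[float, float], ...] = ((1.0, 20.0),)  # (µA, ms)
    baseline_uA: float = 0.0
    noise_sd_uA: float = 0.0
    artifact_uA: float = 0.0
    artifact_tau_ms: float = 1.0
    duration_ms: float = 500.0
    sample_interval_ms: float = 0.5
    test_mV: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.components = tuple((float(a), float(t)) for a, t in self.components)
        if not self.components:
            raise SpecError("At least one exponential component is required")
        if any(tau <= 0 for _, tau in self.components):
            raise SpecError("Component time constants must be positive")
        if not 0 < self.artifact_tau_ms < 5.0:
            raise SpecError("The capacitive artefact must decay within the first 5 ms")
        if self.duration_ms <= 0 or self.sample_interval_ms <= 0:
            raise SpecError("Durations must be positive")

    @property
    def truncated(self) -> bool:
        """True when the sweep does not cover 10× the slowest time constant."""
        return self.duration_ms < 10.0 * max(tau for _, tau in self.components)


def synth_sensing_sweep(spec: SweepSpec) -> SweepTrace:
    """Render a SweepSpec into a sampled trace with t = 0 at the off-pulse onset."""
    t = np.arange(0.0, spec.duration_ms, spec.sample_interval_ms)
    current = np.full_like(t, spec.baseline_uA)
    for amp, tau in spec.components:
        current = current + amp * np.exp(-t / tau)
    if spec.artifact_uA != 0.0:
        current = current + spec.artifact_uA * np.exp(-t / spec.artifact_tau_ms)
    if spec.noise_sd_uA > 0:
        rng = np.random.default_rng(spec.seed)
        current = current + rng.normal(0.0, spec.noise_sd_uA, len(t))
    protocol = Protocol(
        holding_mV=-60.0,
        test_mV=spec.test_mV,
        off_mV=-50.0,
        test_duration_ms=500.0,
        off_duration_ms=spec.duration_ms,
    )
    return SweepTrace(time=t, current=current, protocol=protocol)


@dataclass
class QVFamilySpec:
    """A family of off-sweeps whose total charge follows a Boltzmann Q–V curve.

    The fast-charge fraction is logistic in voltage — fast-dominated after
    weak depolarisations, slow-dominated after strong ones — mirroring the
    behaviour of a sensor whose return motion is braked by a membrane-bound
    catalytic domain at activating potentials.
    """

    V_half_mV: float = 30.0
    z_q: float = 0.78
    A_min: float = 0.0
    A_max: float = 1.0
    q_scale_nC: float = 40.0
    tau_fast_ms: float = 8.0
    tau_slow_ms: float = 80.0
    fast_min: float = 0.1
    fast_max: float = 0.9
    fast_mid_mV: float = 40.0
    fast_slope_mV: float = 30.0
    voltages_mV: tuple[float, ...] = tuple(float(v) for v in range(-40, 161, 20))
    noise_sd_uA: float = 0.0
    duration_ms: float = 500.0
    sample_interval_ms: float = 0.5
    temperature_K: float = DEFAULT_TEMPERATURE_K
    seed: int = 0

    def __post_init__(self) -> None:
        self.voltages_mV = tuple(float(v) for v in self.voltages_mV)
        if 120.0 not in self.voltages_mV:
            raise SpecError("The voltage grid must include the +120 mV normalization anchor")
        if self.A_max <= self.A_min:
            raise SpecError("A_max must exceed A_min")
        if self.z_q <= 0 or self.q_scale_nC <= 0:
            raise SpecError("z_q and the charge scale must be positive")
        if not (0 <= self.fast_min < self.fast_max <= 1):
            raise SpecError("fast fraction bounds must satisfy 0 ≤ min < max ≤ 1")
        if self.tau_fast_ms <= 0 or self.tau_slow_ms <= self.tau_fast_ms:
            raise SpecError("Need 0 < tau_fast < tau_slow")

    def fast_fraction(self, v_mV: float) -> float:
        """Fraction of the off-charge carried by the fast component at V."""
        return self.fast_min + (self.fast_max - self.fast_min) / (
            1.0 + np.exp((v_mV - self.fast_mid_mV) / self.fast_slope_mV)
        )

    def charge_at(self, v_mV: float) -> float:
        """Ground-truth total off-charge (nC) at a test potential."""
        return float(
            self.q_scale_nC
            * boltzmann(
                np.array([v_mV]), self.V_half_mV, self.z_q, self.A_min, self.A_max,
                self.temperature_K,
            )[0]
        )


def synth_qv_family(
    spec: QVFamilySpec,
) -> tuple[dict[float, SweepTrace], BoltzmannFit]:
    """Generate one off-sweep per test voltage plus the ground-truth Boltzmann.

    Per voltage the total charge Q(V) follows the spec's Boltzmann curve and
    is split into a fast and a slow exponential via the logistic fast
    fraction; amplitudes are Q_i/τ_i so the charge decomposition is exact.
    """
    sweeps: dict[float, SweepTrace] = {}
    for k, v in enumerate(spec.voltages_mV):
        q_all = spec.charge_at(v)
        f = spec.fast_fraction(v)
        components = []
        q_fast = f * q_all
        q_slow = (1.0 - f) * q_all
        if abs(q_fast) > 1e-12:
            components.append((q_fast / spec.tau_fast_ms, spec.tau_fast_ms))
        if abs(q_slow) > 1e-12:
            components.append((q_slow / spec.tau_slow_ms, spec.tau_slow_ms))
        if not components:
            components = [(0.0, spec.tau_fast_ms)]
        sweep_spec = SweepSpec(
            components=tuple(components),
            baseline_uA=0.0,
            noise_sd_uA=spec.noise_sd_uA,
            duration_ms=spec.duration_ms,
            sample_interval_ms=spec.sample_interval_ms,
            test_mV=v,
            seed=spec.seed * 1009 + k,
        )
        sweeps[v] = synth_sensing_sweep(sweep_spec)
    truth = BoltzmannFit(
        V_half=spec.V_half_mV,
        z_q=spec.z_q,
        A_min=spec.A_min,
        A_max=spec.A_max,
        T=spec.temperature_K,
    )
    return sweeps, truth


@dataclass
class ChannelSpec:
    """A reporter-channel sweep: activation then exponential inhibition.

    I(t) = plateau · (1 − e^{−t/τ_act}) · (floor + (1 − floor) · e^{−k t}),
    so with activation much faster than inhibition the half-inhibition time
    approaches ln 2 / k and the final inhibition ratio approaches 1 − floor.
    """

    activation_tau_ms: float = 20.0
    plateau_uA: float = 1.0
    inhibition_rate_per_ms: float = 0.01
    floor_fraction: float = 0.01
    noise_sd_uA: float = 0.0
    duration_ms: float = 1000.0
    sample_interval_ms: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plateau_uA <= 0:
            raise SpecError("plateau must be positive")
        if not 0 <= self.floor_fraction < 1:
            raise SpecError("floor_fraction must be in [0, 1)")
        if self.activation_tau_ms <= 0 or self.inhibition_rate_per_ms < 0:
            raise SpecError("activation tau must be positive and rate non-negative")


def synth_channel_sweep(spec: ChannelSpec) -> SweepTrace:
    """Render a ChannelSpec into a depolarization-phase current trace."""
    t = np.arange(0.0, spec.duration_ms, spec.sample_interval_ms)
    activation = 1.0 - np.exp(-t / spec.activation_tau_ms)
    inhibition = spec.floor_fraction + (1.0 - spec.floor_fraction) * np.exp(
        -spec.inhibition_rate_per_ms * t
    )
    current = spec.plateau_uA * activation * inhibition
    if spec.noise_sd_uA > 0:
        rng = np.random.default_rng(spec.seed)
        current = current + rng.normal(0.0, spec.noise_sd_uA, len(t))
    protocol = Protocol(
        holding_mV=-80.0,
        test_mV=80.0,
        off_mV=-80.0,
        test_duration_ms=spec.duration_ms,
        off_duration_ms=1.0,
    )
    return SweepTrace(time=t, current=current, protocol=protocol)


# ---------------------------------------------------------------------------
# Flat key=value spec (de)serialisation
# ---------------------------------------------------------------------------

_SPEC_CLASSES = {
    "ContactScheduleSpec": ContactScheduleSpec,
    "SweepSpec": SweepSpec,
    "ChannelSpec": ChannelSpec,
    "QVFamilySpec": QVFamilySpec,
}


def _encode(value) -> str:
    if isinstance(value, tuple):
        if value and isinstance(value[0], tuple):
            return ";".join(_encode(v) for v in value)
        return ",".join(_encode(v) for v in value)
    return repr(value) if isinstance(value, str) else f"{value}"


def _encode_groupdef(gdef: GroupDef) -> str:
    return "|".join(f"{rn}:{num}:{','.join(names)}" for rn, num, names in gdef)


def _decode_groupdef(text: str) -> GroupDef:
    out = []
    for chunk in text.split("|"):
        rn, num, names = chunk.split(":")
        out.append((rn, int(num), tuple(names.split(","))))
    return tuple(out)


def spec_to_config(spec) -> str:
    """Serialise a generator spec to flat ``key = value`` text."""
    lines = [f"spec_class = {type(spec).__name__}"]
    for f in dataclasses.fields(spec):
        value = getattr(spec, f.name)
        if f.name in ("group_a_def", "group_b_def"):
            encoded = _encode_groupdef(value)
        elif f.name == "bound_intervals":
            encoded = ";".join(f"{a}:{b}" for a, b in value)
        elif f.name in ("contact_atom_a", "contact_atom_b"):
            encoded = f"{value[0]}:{value[1]}"
        elif f.name == "components":
            encoded = ";".join(f"{a}:{t}" for a, t in value)
        elif isinstance(value, tuple):
            encoded = ",".join(f"{v}" for v in value)
        else:
            encoded = f"{value}"
        lines.append(f"{f.name} = {encoded}")
    return "\n".join(lines) + "\n"


def spec_from_config(text: str):
    """Reconstruct a generator spec from :func:`spec_to_config` output."""
    entries: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        entries[key.strip()] = value.strip()
    cls_name = entries.pop("spec_class", None)
    if cls_name not in _SPEC_CLASSES:
        raise SpecError(f"Unknown or missing spec_class in config: {cls_name!r}")
    cls = _SPEC_CLASSES[cls_name]
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in entries:
            continue
        raw = entries[f.name]
        if f.name in ("group_a_def", "group_b_def"):
            kwargs[f.name] = _decode_groupdef(raw)
        elif f.name == "bound_intervals":
            kwargs[f.name] = tuple(
                tuple(float(x) for x in part.split(":"))
                for part in raw.split(";")
                if part
            )
        elif f.name in ("contact_atom_a", "contact_atom_b"):
            num, name = raw.split(":")
            kwargs[f.name] = (int(num), name)
        elif f.name == "components":
            kwargs[f.name] = tuple(
                tuple(float(x) for x in part.split(":"))
                for part in raw.split(";")
                if part
            )
        elif f.name == "voltages_mV":
            kwargs[f.name] = tuple(float(x) for x in raw.split(",") if x)
        elif f.type in ("int", int) or f.name == "seed":
            kwargs[f.name] = int(raw)
        else:
            kwargs[f.name] = float(raw)
    return cls(**kwargs)
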