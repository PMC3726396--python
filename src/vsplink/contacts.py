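"""Residue-group interaction statistics from MD trajectories.

A *contact* is an unordered atom pair — one atom from each of two disjoint
groups — whose Euclidean distance is within a cutoff sphere (default 3.5 Å,
boundary inclusive). From per-frame contact counts the module derives:

* windowed means and population standard deviations of the contact count
  (e.g. over the last 30 ns of a simulation),
* bound/unbound state populations on a fixed sampling grid (default every
  100 ps, excluding the t = 0 frame so a 50 ns run yields 500 states),
* maximal contact lifetimes (longest unbroken run of bound samples; a single
  unbound sample breaks the run),
* a chemical classification of interacting atom pairs (salt bridge,
  hydrogen bond, hydrophobic, other) and per-residue contact tables.

Counting atom *pairs* (rather than atoms) makes the statistic symmetric in
the two groups and additive over any partition of one group into residues.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import AnalysisError, SelectionError
from .model import (
    Atom,
    AtomSelection,
    CARBOXYLATE_OXYGEN,
    CHARGED_NITROGEN,
    Trajectory,
    resolve_selection,
)

__all__ = [
    "ContactSeries",
    "ContactStats",
    "InteractionClass",
    "frame_contacts",
    "contact_series",
    "window_stats",
    "state_population",
    "max_contact_lifetime",
    "classify_pair",
    "residue_contact_table",
    "format_contact_table",
]

DEFAULT_CUTOFF = 3.5  # Å
DEFAULT_SAMPLE_INTERVAL = 0.1  # ns (100 ps)


class InteractionClass(enum.Enum):
    """Chemical character of a contacting atom pair."""

    SALT_BRIDGE = "salt-bridge"
    HYDROGEN_BOND = "hydrogen-bond"
    HYDROPHOBIC = "hydrophobic"
    OTHER = "other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class ContactSeries:
    """Per-frame inter-group contact counts at a fixed cutoff."""

    times: np.ndarray  # ns
    counts: np.ndarray  # non-negative integers, one per frame
    cutoff: float  # Å
    group_a: str = "group_a"
    group_b: str = "group_b"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.times.shape != self.counts.shape:
            raise AnalysisError("times and counts must have equal length")
        if np.any(self.counts < 0):
            raise AnalysisError("contact counts must be non-negative")
        if self.cutoff <= 0:
            raise AnalysisError("cutoff must be positive")

    def frame_spacing(self) -> float:
        deltas = np.diff(self.times)
        if len(deltas) == 0:
            raise AnalysisError("Cannot determine spacing of a single-frame series")
        if not np.allclose(deltas, deltas[0], rtol=1e-6, atol=1e-9):
            raise AnalysisError("Contact series sampling is not uniform")
        return float(deltas[0])


@dataclass
class ContactStats:
    """Summary statistics for one interacting pair of groups."""

    mean_contacts: float
    sd_contacts: float
    window: tuple[float, float]  # ns
    bound_states: int
    unbound_states: int
    sample_interval: float  # ns
    max_lifetime: float  # ns

    def __post_init__(self) -> None:
        if self.sd_contacts < 0:
            raise AnalysisError("sd must be non-negative")
        if self.max_lifetime > self.bound_states * self.sample_interval + 1e-9:
            raise AnalysisError("max_lifetime cannot exceed bound_states × interval")


def frame_contacts(
    coords: np.ndarray,
    idx_a: Sequence[int],
    idx_b: Sequence[int],
    cutoff: float = DEFAULT_CUTOFF,
) -> int:
    """Count atom pairs (i ∈ a, j ∈ b) within ``cutoff`` Å in one frame.

    The comparison is inclusive (d ≤ cutoff counts) and symmetric in the two
    groups. Overlapping selections are rejected: self-contacts are undefined.
    """
    idx_a = np.asarray(idx_a, dtype=int)
    idx_b = np.asarray(idx_b, dtype=int)
    if len(np.intersect1d(idx_a, idx_b)) > 0:
        raise SelectionError("Groups overlap; contact counts require disjoint selections")
    if len(idx_a) == 0 or len(idx_b) == 0:
        return 0
    coords = np.asarray(coords, dtype=float)
    d = cdist(coords[idx_a], coords[idx_b])
    return int(np.count_nonzero(d <= cutoff))


def contact_series(
    traj: Trajectory,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    cutoff: float = DEFAULT_CUTOFF,
) -> ContactSeries:
    """Per-frame contact counts between two selections along a trajectory."""
    idx_a = resolve_selection(traj.topology, sel_a)
    idx_b = resolve_selection(traj.topology, sel_b)
    if not idx_a:
        raise SelectionError(f"Selection A ({sel_a.describe()}) resolves to no atoms")
    if not idx_b:
        raise SelectionError(f"Selection B ({sel_b.describe()}) resolves to no atoms")
    counts = np.array(
        [frame_contacts(traj.frames[i], idx_a, idx_b, cutoff) for i in range(traj.n_frames)]
    )
    return ContactSeries(
        times=traj.times.copy(),
        counts=counts,
        cutoff=cutoff,
        group_a=sel_a.describe(),
        group_b=sel_b.describe(),
    )


def window_stats(
    series: ContactSeries, t_start: float, t_end: float
) -> tuple[float, float]:
    """Mean and population SD of contact counts over t_start ≤ t ≤ t_end."""
    mask = (series.times >= t_start - 1e-9) & (series.times <= t_end + 1e-9)
    if not np.any(mask):
        raise AnalysisError(
            f"Window [{t_start}, {t_end}] ns contains no frames "
            f"(series spans [{series.times[0]}, {series.times[-1]}])"
        )
    window = series.counts[mask]
    return float(np.mean(window)), float(np.std(window))


def _sampled_states(
    series: ContactSeries, sample_interval: float, include_t0: bool
) -> np.ndarray:
    """Boolean bound flags on the sampling grid t = s, 2s, ... (or 0, s, ...)."""
    if sample_interval <= 0:
        raise AnalysisError("sample_interval must be positive")
    spacing = series.frame_spacing()
    ratio = sample_interval / spacing
    step = int(round(ratio))
    if step < 1 or abs(ratio - step) > 1e-6:
        raise AnalysisError(
            f"sample_interval {sample_interval} ns is not an integer multiple "
            f"of the frame spacing {spacing} ns"
        )
    start = 0 if include_t0 else step
    idx = np.arange(start, len(series.counts), step)
    if len(idx) == 0:
        raise AnalysisError("Sampling grid contains no states")
    return series.counts[idx] > 0


def state_population(
    series: ContactSeries,
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL,
    include_t0: bool = False,
) -> tuple[int, int]:
    """Bound/unbound state counts sampled every ``sample_interval`` ns.

    A state is *bound* when the contact count is > 0 and *unbound* at zero
    contacts. By default the grid starts one interval in (t = s, 2s, ...), so
    a 50 ns series checked in 100 ps steps yields 500 states; ``include_t0``
    adds the initial frame.
    """
    bound_flags = _sampled_states(series, sample_interval, include_t0)
    bound = int(np.count_nonzero(bound_flags))
    return bound, int(len(bound_flags) - bound)


def _longest_run(flags: np.ndarray) -> int:
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def max_contact_lifetime(
    series: ContactSeries,
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL,
    include_t0: bool = False,
    gap_tolerance: int = 0,
) -> float:
    """Longest unbroken run of bound sampled states × sample interval, in ns.

    With the default ``gap_tolerance`` of 0 a single unbound sample breaks the
    run (beyond the cutoff a contact is defined as broken). A positive
    tolerance lets runs bridge up to that many consecutive unbound samples.
    """
    flags = _sampled_states(series, sample_interval, include_t0)
    if gap_tolerance > 0:
        flags = flags.copy()
        last_bound = -1
        for i, f in enumerate(flags):
            if f:
                if last_bound >= 0 and 0 < i - last_bound - 1 <= gap_tolerance:
                    flags[last_bound + 1 : i] = True
                last_bound = i
    return _longest_run(flags) * sample_interval


_POLAR_ELEMENTS = {"N", "O"}


def classify_pair(atom_i: Atom, atom_j: Atom) -> InteractionClass:
    """Classify a contacting atom pair by residue and atom identity.

    Salt bridge: one atom a basic side-chain nitrogen (Lys NZ; Arg
    NE/NH1/NH2), the other an Asp/Glu carboxylate oxygen. Hydrogen bond: both
    atoms polar N/O not forming a salt bridge. Hydrophobic: both carbon.
    """
    key_i = (atom_i.residue_name, atom_i.name)
    key_j = (atom_j.residue_name, atom_j.name)
    if (key_i in CHARGED_NITROGEN and key_j in CARBOXYLATE_OXYGEN) or (
        key_j in CHARGED_NITROGEN and key_i in CARBOXYLATE_OXYGEN
    ):
        return InteractionClass.SALT_BRIDGE
    if atom_i.element in _POLAR_ELEMENTS and atom_j.element in _POLAR_ELEMENTS:
        return InteractionClass.HYDROGEN_BOND
    if atom_i.element == "C" and atom_j.element == "C":
        return InteractionClass.HYDROPHOBIC
    return InteractionClass.OTHER


_CLASS_PRIORITY = [
    InteractionClass.SALT_BRIDGE,
    InteractionClass.HYDROGEN_BOND,
    InteractionClass.HYDROPHOBIC,
    InteractionClass.OTHER,
]


def _dominant_class(
    traj: Trajectory,
    idx_a: list[int],
    idx_b: list[int],
    cutoff: float,
    frame_mask: np.ndarray,
) -> Optional[InteractionClass]:
    """Modal interaction class among in-cutoff pairs over masked frames."""
    if not idx_a or not idx_b:
        return None
    tallies: dict[InteractionClass, int] = {}
    atoms = traj.topology.atoms
    a_arr = np.asarray(idx_a)
    b_arr = np.asarray(idx_b)
    for fi in np.nonzero(frame_mask)[0]:
        d = cdist(traj.frames[fi][a_arr], traj.frames[fi][b_arr])
        ii, jj = np.nonzero(d <= cutoff)
        for i, j in zip(ii, jj):
            cls = classify_pair(atoms[a_arr[i]], atoms[b_arr[j]])
            tallies[cls] = tallies.get(cls, 0) + 1
    if not tallies:
        return None
    best = max(tallies.values())
    # deterministic tie-break: chemically most specific class wins
    for cls in _CLASS_PRIORITY:
        if tallies.get(cls) == best:
            return cls
    return None  # pragma: no cover


def residue_contact_table(
    traj: Trajectory,
    residues_a: Sequence[int],
    sel_b: AtomSelection,
    cutoff: float = DEFAULT_CUTOFF,
    window: Optional[tuple[float, float]] = None,
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL,
    chain_a: Optional[str] = None,
    include_t0: bool = False,
) -> pd.DataFrame:
    """Per-residue interaction summary versus a partner selection.

    One row per residue in ``residues_a``: windowed mean ± SD of contacts,
    bound/unbound populations and maximal lifetime over the full series, and
    the modal interaction class of in-cutoff pairs within the window.
    ``window`` defaults to the full time span.
    """
    rows = []
    idx_b = resolve_selection(traj.topology, sel_b)
    if not idx_b:
        raise SelectionError(f"Selection B ({sel_b.describe()}) resolves to no atoms")
    for res in residues_a:
        sel_a = AtomSelection(
            chain=chain_a, residues=frozenset({res}), label=f"residue {res}"
        )
        idx_a = resolve_selection(traj.topology, sel_a)
        if not idx_a:
            raise SelectionError(f"Residue {res} resolves to no atoms")
        series = contact_series(traj, sel_a, sel_b, cutoff)
        w = window if window is not None else (float(traj.times[0]), float(traj.times[-1]))
        mean, sd = window_stats(series, *w)
        bound, unbound = state_population(series, sample_interval, include_t0)
        lifetime = max_contact_lifetime(series, sample_interval, include_t0)
        mask = (traj.times >= w[0] - 1e-9) & (traj.times <= w[1] + 1e-9)
        dom = _dominant_class(traj, idx_a, idx_b, cutoff, mask)
        rows.append(
            {
                "residue": res,
                "mean": mean,
                "sd": sd,
                "bound": bound,
                "unbound": unbound,
                "max_lifetime_ns": lifetime,
                "dominant_class": dom.value if dom is not None else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "residue", "mean", "sd", "bound", "unbound", "max_lifetime_ns",
            "dominant_class",
        ],
    )


def format_contact_table(table: pd.DataFrame) -> str:
    """Render a residue contact table as TSV with mean±sd / bound–unbound columns."""
    lines = ["pair\tcontacts\tstates\tmax_lifetime_ns\tdominant_class"]
    for _, row in table.iterrows():
        lines.append(
            f"{row['residue']}\t{row['mean']:.1f}±{row['sd']:.1f}"
            f"\t{row['bound']}–{row['unbound']}\t{row['max_lifetime_ns']:.1f}"
            f"\t{row['dominant_class']}"
        )
    return "\n".join(lines) + "\n"
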