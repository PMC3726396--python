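"""Contact counting, windowed statistics, populations, lifetimes, classification."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vsplink import (
    AnalysisError,
    Atom,
    AtomSelection,
    ContactSeries,
    InteractionClass,
    SelectionError,
    classify_pair,
    contact_series,
    frame_contacts,
    max_contact_lifetime,
    residue_contact_table,
    state_population,
    window_stats,
)
from vsplink.synth import ContactScheduleSpec, synth_contact_trajectory


def _pair_coords(distance):
    return np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]])


def brute_force_contacts(coords, idx_a, idx_b, cutoff):
    """Independent O(n²) recount: explicit double loop over atom pairs."""
    count = 0
    for i in idx_a:
        for j in idx_b:
            if np.sqrt(np.sum((coords[i] - coords[j]) ** 2)) <= cutoff:
                count += 1
    return count


def test_cutoff_boundary_is_inclusive():
    assert frame_contacts(_pair_coords(3.4), [0], [1], 3.5) == 1
    assert frame_contacts(_pair_coords(3.5), [0], [1], 3.5) == 1
    assert frame_contacts(_pair_coords(3.6), [0], [1], 3.5) == 0


def test_overlapping_groups_rejected():
    with pytest.raises(SelectionError):
        frame_contacts(_pair_coords(1.0), [0, 1], [1], 3.5)


@pytest.mark.parametrize("seed", range(10))
def test_count_matches_brute_force_and_is_symmetric(seed):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 10, (40, 3))
    idx_a, idx_b = list(range(20)), list(range(20, 40))
    cutoff = rng.uniform(1.0, 5.0)
    fast = frame_contacts(coords, idx_a, idx_b, cutoff)
    assert fast == brute_force_contacts(coords, idx_a, idx_b, cutoff)
    assert fast == frame_contacts(coords, idx_b, idx_a, cutoff)


@given(st.integers(0, 2**31 - 1), st.floats(0.5, 4.0), st.floats(0.1, 3.0))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_count_monotone_in_cutoff(seed, cutoff, extra):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 8, (20, 3))
    idx_a, idx_b = list(range(10)), list(range(10, 20))
    assert frame_contacts(coords, idx_a, idx_b, cutoff) <= frame_contacts(
        coords, idx_a, idx_b, cutoff + extra
    )


def test_partition_additivity(schedule_trajectory, ti_loop_selection):
    """Contacts of a group equal the sum over its per-residue partition."""
    traj, _ = schedule_trajectory
    whole = contact_series(
        traj, AtomSelection.residue_range(252, 255), ti_loop_selection
    )
    parts = [
        contact_series(traj, AtomSelection(residues=frozenset({r})), ti_loop_selection)
        for r in (252, 253, 255)
    ]
    summed = np.sum([p.counts for p in parts], axis=0)
    assert np.array_equal(summed, whole.counts)


def test_contact_series_schedule_echo(schedule_spec, schedule_trajectory,
                                      linker_selection, ti_loop_selection):
    traj, flags = schedule_trajectory
    series = contact_series(traj, linker_selection, ti_loop_selection)
    assert np.array_equal(series.counts > 0, flags)


def test_zero_cutoff_gives_zero_counts(schedule_trajectory, linker_selection,
                                       ti_loop_selection):
    traj, _ = schedule_trajectory
    series = contact_series(traj, linker_selection, ti_loop_selection, cutoff=1e-9)
    assert not series.counts.any()


def test_empty_selection_error_names_the_selection(schedule_trajectory):
    traj, _ = schedule_trajectory
    with pytest.raises(SelectionError, match="999"):
        contact_series(
            traj,
            AtomSelection.residue_range(999, 999),
            AtomSelection.residue_range(400, 402),
        )


def _series(counts, spacing=0.1):
    counts = np.asarray(counts)
    return ContactSeries(
        times=np.arange(len(counts)) * spacing, counts=counts, cutoff=3.5
    )


def test_window_stats_constant_and_two_point():
    assert window_stats(_series([5] * 10), 0.0, 0.9) == (5.0, 0.0)
    mean, sd = window_stats(_series([0, 10]), 0.0, 0.1)
    assert (mean, sd) == (5.0, 5.0)


def test_window_stats_matches_slice_oracle():
    rng = np.random.default_rng(11)
    counts = rng.integers(0, 40, 200)
    series = _series(counts)
    t_start = series.times[-1] * 0.4
    mean, sd = window_stats(series, t_start, series.times[-1])
    window = counts[series.times >= t_start - 1e-9]
    assert mean == pytest.approx(np.mean(window))
    assert sd == pytest.approx(np.std(window))


def test_window_stats_empty_window_errors():
    with pytest.raises(AnalysisError):
        window_stats(_series([1, 2, 3]), 5.0, 6.0)


def test_state_population_grid_and_bounds():
    # 50 ns at 0.1 ns spacing → 501 frames → 500 sampled states (t = 0 dropped)
    counts = np.ones(501, dtype=int)
    series = _series(counts)
    bound, unbound = state_population(series, 0.1)
    assert bound + unbound == 500
    assert (bound, unbound) == (500, 0)
    # with the initial frame included the grid has 501 points
    bound0, unbound0 = state_population(series, 0.1, include_t0=True)
    assert bound0 + unbound0 == 501

    zero = _series(np.zeros(501, dtype=int))
    assert state_population(zero, 0.1) == (0, 500)


def test_state_population_rejects_non_commensurate_interval():
    with pytest.raises(AnalysisError):
        state_population(_series(np.ones(100, dtype=int)), 0.15)


def test_max_lifetime_run_times_interval():
    counts = np.zeros(501, dtype=int)
    counts[100:343] = 1  # 243 consecutive bound samples on the 0.1 ns grid
    series = _series(counts)
    assert max_contact_lifetime(series, 0.1) == pytest.approx(24.3, abs=1e-9)
    assert max_contact_lifetime(_series(np.zeros(501, dtype=int)), 0.1) == 0.0


def test_max_lifetime_matches_linear_scan_oracle():
    rng = np.random.default_rng(23)
    for _ in range(20):
        flags = rng.random(500) < 0.6
        series = _series(flags.astype(int))
        # oracle: brute-force scan over sampled states (t = s, 2s, ... ⇒ drop index 0)
        best = run = 0
        for f in flags[1:]:
            run = run + 1 if f else 0
            best = max(best, run)
        assert max_contact_lifetime(series, 0.1) == pytest.approx(best * 0.1)


def test_max_lifetime_gap_tolerance_bridges_single_gap():
    counts = np.array([0, 1, 1, 0, 1, 1, 1, 0, 0, 1])
    series = _series(counts)
    assert max_contact_lifetime(series, 0.1) == pytest.approx(0.3)
    assert max_contact_lifetime(series, 0.1, gap_tolerance=1) == pytest.approx(0.6)


def test_lifetime_bounded_by_population(schedule_trajectory, linker_selection,
                                        ti_loop_selection):
    traj, _ = schedule_trajectory
    series = contact_series(traj, linker_selection, ti_loop_selection)
    bound, unbound = state_population(series)
    assert bound + unbound == 500
    assert max_contact_lifetime(series) <= bound * 0.1 + 1e-9


def _named_atom(name, resname, element=""):
    return Atom(
        serial=1, name=name, element=element, residue_name=resname,
        residue_number=1, chain="A", position=np.zeros(3),
    )


@pytest.mark.parametrize(
    "a, b, expected",
    [
        (("NH1", "ARG"), ("OD1", "ASP"), InteractionClass.SALT_BRIDGE),
        (("NZ", "LYS"), ("OE2", "GLU"), InteractionClass.SALT_BRIDGE),
        (("CZ", "TYR"), ("CE1", "PHE"), InteractionClass.HYDROPHOBIC),
        (("O", "GLY"), ("N", "ALA"), InteractionClass.HYDROGEN_BOND),
        (("NZ", "LYS"), ("CZ", "PHE"), InteractionClass.OTHER),
    ],
)
def test_classify_pair_rules(a, b, expected):
    atom_a = _named_atom(a[0], a[1])
    atom_b = _named_atom(b[0], b[1])
    assert classify_pair(atom_a, atom_b) == expected
    assert classify_pair(atom_b, atom_a) == expected  # symmetric


def test_residue_table_salt_bridge_fixture():
    """Only the Arg analog touches the Asp analog → salt-bridge row, others zero."""
    spec = ContactScheduleSpec(
        duration_ns=5.0, bound_intervals=((0.0, 5.0),), noise_sd_A=0.0, seed=0
    )
    traj, _ = synth_contact_trajectory(spec)
    table = residue_contact_table(
        traj, [252, 253, 255], AtomSelection.residue_range(400, 402)
    )
    by_res = table.set_index("residue")
    assert by_res.loc[253, "mean"] > 0
    assert by_res.loc[253, "dominant_class"] == "salt-bridge"
    assert by_res.loc[252, "mean"] == 0
    assert by_res.loc[255, "mean"] == 0
    assert by_res.loc[252, "dominant_class"] == ""


def test_residue_table_empty_and_partition(schedule_trajectory, ti_loop_selection):
    traj, _ = schedule_trajectory
    empty = residue_contact_table(traj, [], ti_loop_selection)
    assert len(empty) == 0

    table = residue_contact_table(traj, [252, 253, 255], ti_loop_selection)
    whole = contact_series(
        traj, AtomSelection.residue_range(252, 255), ti_loop_selection
    )
    w = (float(traj.times[0]), float(traj.times[-1]))
    whole_mean, _ = window_stats(whole, *w)
    assert table["mean"].sum() == pytest.approx(whole_mean)
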