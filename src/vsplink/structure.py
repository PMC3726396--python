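"""Rigid-body superposition, region RMSD and helix bend angle.

These are the linker-integrity metrics: least-squares (Kabsch) superposition
of paired point sets, backbone RMSD over a residue range (e.g. the VSD–CD
linker, residues 240–257), and the bend of an α-helix at a pivot residue
(e.g. R245), measured as the angle between axis fits through the CA atoms on
either side of the pivot.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import AnalysisError
from .model import BACKBONE_NAMES, Structure

__all__ = [
    "Superposition",
    "kabsch_superpose",
    "region_rmsd",
    "helix_bend_angle",
]


@dataclass
class Superposition:
    """Optimal rigid motion (proper rotation + translation) and resulting RMSD."""

    rotation: np.ndarray  # 3×3, det +1
    translation: np.ndarray  # Å
    rmsd: float  # Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation (reflections excluded) and translation
    minimising the RMSD between the transformed mobile points and the
    reference, together with that minimal RMSD. Requires ≥ 3 paired,
    non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise AnalysisError(
            f"Point counts differ: mobile {mobile.shape} vs reference {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise AnalysisError("Superposition needs ≥ 3 three-dimensional points")

    mob_center = mobile.mean(axis=0)
    ref_center = reference.mean(axis=0)
    p = mobile - mob_center
    q = reference - ref_center

    # degenerate (collinear) geometry: covariance has rank < 2
    if np.linalg.matrix_rank(p, tol=1e-8) < 2 or np.linalg.matrix_rank(q, tol=1e-8) < 2:
        raise AnalysisError("Degenerate (collinear) point set; superposition undefined")

    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = ref_center - rotation @ mob_center
    moved = p @ rotation.T + ref_center
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return Superposition(rotation=rotation, translation=translation, rmsd=rmsd)


_ATOM_CLASS_NAMES = {
    "backbone": BACKBONE_NAMES,
    "ca": frozenset({"CA"}),
}


def _region_coords(
    structure: Structure,
    residue_range: Iterable[int],
    atom_names: frozenset[str],
) -> tuple[np.ndarray, list[tuple[str, int, str]]]:
    """Coordinates of the named atoms over the range, plus missing-atom keys."""
    residues = sorted(set(residue_range))
    coords = []
    missing = []
    chains = sorted({a.chain for a in structure.atoms})
    for res in residues:
        for name in sorted(atom_names):
            atom = None
            for chain in chains:
                atom = structure.find(chain, res, name)
                if atom is not None:
                    break
            if atom is None:
                missing.append((chains[0] if chains else "?", res, name))
            else:
                coords.append(atom.position)
    return (np.stack(coords) if coords else np.empty((0, 3))), missing


def region_rmsd(
    a: Structure,
    b: Structure,
    residue_range: Iterable[int],
    atom_class: str = "backbone",
    superpose: bool = True,
    align_range: Optional[Iterable[int]] = None,
) -> float:
    """Backbone RMSD (Å) between two structures over a residue range.

    Atoms are paired by (residue number, atom name). With ``superpose`` the
    structures are first optimally aligned — by default on the compared
    region's own atoms, or on ``align_range`` (e.g. a domain core) when given.
    """
    if atom_class not in _ATOM_CLASS_NAMES:
        raise AnalysisError(f"Unsupported atom class {atom_class!r} for region RMSD")
    names = _ATOM_CLASS_NAMES[atom_class]
    residue_range = list(residue_range)
    coords_a, missing_a = _region_coords(a, residue_range, names)
    coords_b, missing_b = _region_coords(b, residue_range, names)
    if missing_a or missing_b:
        raise AnalysisError(
            "Missing atoms for region RMSD: "
            + ", ".join(f"{c}/{r}/{n}" for c, r, n in missing_a + missing_b)
        )
    if superpose:
        anchor = list(align_range) if align_range is not None else residue_range
        anchor_a, miss_a = _region_coords(a, anchor, names)
        anchor_b, miss_b = _region_coords(b, anchor, names)
        if miss_a or miss_b:
            raise AnalysisError(
                "Missing atoms in alignment anchor: "
                + ", ".join(f"{c}/{r}/{n}" for c, r, n in miss_a + miss_b)
            )
        sup = kabsch_superpose(anchor_a, anchor_b)
        coords_a = sup.apply(coords_a)
    return float(np.sqrt(np.mean(np.sum((coords_a - coords_b) ** 2, axis=1))))


def _helix_axis(ca: np.ndarray) -> np.ndarray:
    """Axis of a short helical CA segment by the bisector cross-product method.

    For CA atoms i−1, i, i+1 the bisector b_i = (CA_{i−1} − CA_i) +
    (CA_{i+1} − CA_i) points from the helix surface toward the axis, and the
    cross product of consecutive bisectors is parallel to the axis — exact on
    ideal helical geometry and stable down to 4-point segments, where a plain
    principal-component fit is dominated by the helix cross-section.
    Sign is fixed along the direction of increasing residue number.
    """
    n = len(ca)
    if n < 4:
        raise AnalysisError("Axis fit needs at least 4 CA atoms")
    bis = [ca[i - 1] - ca[i] + ca[i + 1] - ca[i] for i in range(1, n - 1)]
    chain_dir = ca[-1] - ca[0]
    estimates = []
    for b1, b2 in zip(bis[:-1], bis[1:]):
        axis = np.cross(b1, b2)
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            continue
        axis = axis / norm
        if np.dot(axis, chain_dir) < 0:
            axis = -axis
        estimates.append(axis)
    if not estimates:
        raise AnalysisError("Degenerate CA geometry; helix axis undefined")
    mean_axis = np.mean(estimates, axis=0)
    norm = np.linalg.norm(mean_axis)
    if norm < 1e-12:
        raise AnalysisError("Helix axis estimates cancel; geometry degenerate")
    return mean_axis / norm


def helix_bend_angle(
    s: Structure,
    residue_range: Iterable[int],
    pivot: int,
    half_window: int = 4,
) -> float:
    """Bend angle (degrees) of a helix at a pivot residue.

    Axes are fit through the CA atoms of [pivot − half_window, pivot − 1] and
    [pivot + 1, pivot + half_window]; 0° means a straight helix. The pivot
    with its half-windows must lie inside ``residue_range`` and every CA must
    be present.
    """
    residues = sorted(set(residue_range))
    lo = pivot - half_window
    hi = pivot + half_window
    needed = set(range(lo, hi + 1))
    if not needed <= set(residues):
        raise AnalysisError(
            f"Pivot {pivot} ± {half_window} exceeds residue range "
            f"[{residues[0]}, {residues[-1]}]"
        )
    chains = sorted({a.chain for a in s.atoms})

    def _ca(res: int) -> np.ndarray:
        for chain in chains:
            atom = s.find(chain, res, "CA")
            if atom is not None:
                return atom.position
        raise AnalysisError(f"Missing CA atom for residue {res}")

    ca_before = np.stack([_ca(r) for r in range(lo, pivot)])
    ca_after = np.stack([_ca(r) for r in range(pivot + 1, hi + 1)])
    axis1 = _helix_axis(ca_before)
    axis2 = _helix_axis(ca_after)
    cosang = float(np.clip(np.dot(axis1, axis2), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))
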