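"""Rigid-body superposition and domain-motion quantification.

Superposition is the classical least-squares (Kabsch) problem: find the
proper rotation R and translation t minimising ||R x_i + t - y_i||² over
paired points.  Solved by SVD of the cross-covariance with a sign
correction of the smallest singular direction so the result is always a
proper rotation (det +1), never a reflection.

Domain motion between two ligand-bound states is quantified by first
aligning on a reference selection (e.g. the SAM oligomerisation domain),
then measuring the residual rotation that still superposes the mobile
selection (e.g. ARM+TIR); the rotation angle comes from the matrix trace
and marker-atom displacements are Euclidean distances after reference
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import InputError, InsufficientDataError
from .structure_io import AtomRef, AtomSelection, StructureModel, resolve_selection


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, proper
    translation: np.ndarray  # 3-vector, Å
    rmsd: float  # Å
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class DomainMotion:
    angle_deg: float
    marker_displacements: dict[tuple, Optional[float]]  # address -> Å (None if missing)
    screw_translation: float  # Å along the residual rotation axis
    ref_rmsd: float
    mobile_rmsd_after_ref_align: float


def superpose(fixed: np.ndarray, moving: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid transform taking ``moving`` onto ``fixed``.

    Correspondence is positional; the returned rotation is always proper
    (det +1), with reflection-optimal degenerate cases resolved by sign
    correction of the smallest singular direction.
    """
    fixed = np.asarray(fixed, dtype=float).reshape(-1, 3)
    moving = np.asarray(moving, dtype=float).reshape(-1, 3)
    if fixed.shape != moving.shape:
        raise InputError(
            f"point sets differ in length: {len(fixed)} vs {len(moving)}"
        )
    n = len(fixed)
    if n < 3:
        raise InsufficientDataError("superposition needs at least 3 points")
    cf = fixed.mean(axis=0)
    cm = moving.mean(axis=0)
    x = moving - cm
    y = fixed - cf
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cf - rotation @ cm
    moved = moving @ rotation.T + translation
    rmsd = float(np.sqrt(((moved - fixed) ** 2).sum() / n))
    return SuperpositionResult(
        rotation=rotation, translation=translation, rmsd=rmsd, n_atoms=n
    )


def rotation_angle(rotation: np.ndarray) -> float:
    """Rotation magnitude in degrees from the matrix trace, in [0, 180]."""
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise InputError("rotation must be a 3x3 matrix")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-6) or not np.isclose(
        np.linalg.det(rotation), 1.0, atol=1e-6
    ):
        raise InputError("matrix is not a proper rotation (orthonormal, det +1)")
    cos_theta = np.clip((np.trace(rotation) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos_theta)))


def _sel_for_b(
    sel: AtomSelection, chain_map: Optional[Mapping[str, str]]
) -> AtomSelection:
    """Re-express a selection written in a's chain labels in b's labels.

    ``chain_map`` maps b's chain ids onto a's; selections name a's ids.
    """
    if not chain_map or not sel.chain_ids:
        return sel
    mapped_targets = set(chain_map.values())
    b_ids = {b for b, a_id in chain_map.items() if a_id in sel.chain_ids}
    b_ids |= {c for c in sel.chain_ids if c not in mapped_targets}
    return AtomSelection(
        chain_ids=frozenset(b_ids), res_range=sel.res_range, atom_names=sel.atom_names
    )


def _pair_atoms(
    a_atoms: Sequence[AtomRef],
    b_atoms: Sequence[AtomRef],
    chain_map: Optional[Mapping[str, str]] = None,
) -> tuple[np.ndarray, np.ndarray, list[tuple]]:
    """Pair atoms across structures by (chain, res_num, icode, atom_name).

    ``chain_map`` renames b's chains onto a's labels (deposited models may
    label equivalent protomers differently).  Unpaired atoms are dropped
    and their keys reported.
    """
    chain_map = chain_map or {}
    b_index = {}
    for atom in b_atoms:
        cid = chain_map.get(atom.chain_id, atom.chain_id)
        b_index[(cid, atom.res_num, atom.insertion_code, atom.atom_name)] = atom
    fixed, moving, dropped = [], [], []
    matched_b = set()
    for atom in a_atoms:
        other = b_index.get(atom.key)
        if other is None:
            dropped.append(atom.key)
        else:
            fixed.append(atom.coords)
            moving.append(other.coords)
            matched_b.add(atom.key)
    dropped.extend(k for k in b_index if k not in matched_b)
    return (
        np.asarray(fixed, dtype=float).reshape(-1, 3),
        np.asarray(moving, dtype=float).reshape(-1, 3),
        dropped,
    )


def rmsd_selection(
    a: StructureModel,
    b: StructureModel,
    measure_sel: AtomSelection,
    align_sel: Optional[AtomSelection] = None,
    chain_map: Optional[Mapping[str, str]] = None,
) -> float:
    """RMSD of a selection between two structures.

    With ``align_sel`` given, the structures are first superposed on that
    selection and the measured atoms are compared without refitting;
    otherwise the superposition is performed on the measured selection
    itself (standard fit-RMSD).  Atoms missing from either structure are
    dropped pairwise.
    """
    ma, mb, _ = _pair_atoms(
        resolve_selection(a, measure_sel).atoms,
        resolve_selection(b, _sel_for_b(measure_sel, chain_map)).atoms,
        chain_map,
    )
    if len(ma) < 3:
        raise InsufficientDataError(
            f"only {len(ma)} paired atoms in the measured selection"
        )
    if align_sel is None:
        return superpose(ma, mb).rmsd
    fa, fb, _ = _pair_atoms(
        resolve_selection(a, align_sel).atoms,
        resolve_selection(b, _sel_for_b(align_sel, chain_map)).atoms,
        chain_map,
    )
    if len(fa) < 3:
        raise InsufficientDataError("alignment selection pairs fewer than 3 atoms")
    sup = superpose(fa, fb)
    moved = sup.apply(mb)
    return float(np.sqrt(((moved - ma) ** 2).sum() / len(ma)))


def _marker_coords(
    structure: StructureModel, marker: tuple[str, int, str]
) -> Optional[np.ndarray]:
    chain_id, res_num, atom_name = marker
    chain = structure.chain(chain_id)
    if chain is None:
        return None
    res = chain.residue(res_num)
    if res is None:
        return None
    atom = res.atom(atom_name)
    return None if atom is None else atom.coords


def domain_motion(
    a: StructureModel,
    b: StructureModel,
    ref_sel: AtomSelection,
    mobile_sel: AtomSelection,
    markers: Sequence[tuple[str, int, str]] = (),
    chain_map: Optional[Mapping[str, str]] = None,
) -> DomainMotion:
    """Rotation of a mobile selection between states, after reference alignment.

    Procedure: (1) superpose b onto a via ``ref_sel``; (2) superpose the
    reference-aligned mobile atoms of b onto a's to obtain the residual
    rotation, whose trace gives the swing angle; (3) marker displacements
    are distances between each marker atom in a and in reference-aligned
    b (``(chain, res_num, atom_name)`` addresses, a's labels).  The screw
    translation is the mobile-centroid displacement along the residual
    rotation axis.
    """
    inv_map = None
    if chain_map:
        inv_map = {v: k for k, v in chain_map.items()}
    fa, fb, _ = _pair_atoms(
        resolve_selection(a, ref_sel).atoms,
        resolve_selection(b, _sel_for_b(ref_sel, chain_map)).atoms,
        chain_map,
    )
    if len(fa) < 3:
        raise InsufficientDataError("reference selection pairs fewer than 3 atoms")
    ref_sup = superpose(fa, fb)

    ma_refs = resolve_selection(a, mobile_sel).atoms
    mb_refs = resolve_selection(b, _sel_for_b(mobile_sel, chain_map)).atoms
    ma, mb, _ = _pair_atoms(ma_refs, mb_refs, chain_map)
    if len(ma) < 3:
        raise InsufficientDataError("mobile selection pairs fewer than 3 atoms")
    mb_aligned = ref_sup.apply(mb)
    mobile_rmsd = float(np.sqrt(((mb_aligned - ma) ** 2).sum() / len(ma)))
    residual = superpose(ma, mb_aligned)
    angle = rotation_angle(residual.rotation)

    # rotation axis (unit eigenvector of R for eigenvalue 1) for the screw component
    r = residual.rotation
    axis = np.array([r[2, 1] - r[1, 2], r[0, 2] - r[2, 0], r[1, 0] - r[0, 1]])
    norm = np.linalg.norm(axis)
    if norm > 1e-12:
        axis /= norm
        centroid_shift = ma.mean(axis=0) - mb_aligned.mean(axis=0)
        screw = float(abs(np.dot(centroid_shift, axis)))
    else:
        screw = float(np.linalg.norm(ma.mean(axis=0) - mb_aligned.mean(axis=0)))

    displacements: dict[tuple, Optional[float]] = {}
    for marker in markers:
        pa = _marker_coords(a, marker)
        marker_b = marker
        if inv_map and marker[0] in inv_map:
            marker_b = (inv_map[marker[0]], marker[1], marker[2])
        pb = _marker_coords(b, marker_b)
        if pa is None or pb is None:
            displacements[tuple(marker)] = None
        else:
            displacements[tuple(marker)] = float(
                np.linalg.norm(ref_sup.apply(pb.reshape(1, 3))[0] - pa)
            )
    return DomainMotion(
        angle_deg=angle,
        marker_displacements=displacements,
        screw_translation=screw,
        ref_rmsd=ref_sup.rmsd,
        mobile_rmsd_after_ref_align=mobile_rmsd,
    )
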