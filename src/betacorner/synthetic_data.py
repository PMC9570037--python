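"""Synthetic structure and ensemble generators.

Everything the test battery consumes is built here from first principles:
ideal polypeptide backbones placed residue-by-residue in torsion space
(natural-extension frames with ideal bond lengths and angles), 3beta-corner
motifs assembled from rigidly placed ideal beta-strands joined by loops
closed with cyclic coordinate descent, negative-control decoys (coils,
helices, flat sheets, mirror and left-handed corners), and multi-model
conformer ensembles with planted cluster structure.

Generated geometry is idealised: strands are straight and untwisted, loops
are closed geometrically rather than energy-minimised, and side chains stop
at CB.  That is sufficient for — and matched to — the geometric analysis
battery; it does not emulate thermal physics.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._geom import angle, dihedral, place_atom, principal_axis, wrap_angle
from .structure_io import Atom, Residue, Structure

__all__ = [
    "BackboneSpec",
    "EnsembleSpec",
    "IDEAL_GEOMETRY",
    "build_ideal_segment",
    "build_ideal_strand",
    "build_synthetic_corner",
    "build_negative_control",
    "generate_ensemble",
    "default_sequence",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 17

#: Ideal backbone bond lengths (Angstrom) and angles (degrees).
IDEAL_GEOMETRY: dict[str, float] = {
    "N_CA": 1.458,
    "CA_C": 1.525,
    "C_N": 1.329,
    "C_O": 1.231,
    "CA_CB": 1.530,
    "ang_N_CA_C": 111.0,
    "ang_CA_C_N": 116.2,
    "ang_C_N_CA": 121.7,
    "ang_CA_C_O": 120.8,
    "ang_CB_CA_C": 109.45,
    # improper dihedral(N, C, CA, CB); +120 gives the L-configuration
    "dih_N_C_CA_CB": 120.0,
}

#: Beta-strand torsions used for ideal strands: a flat (two-fold, untwisted)
#: extended conformation, which keeps assembled sheets planar.
BETA_PHI_PSI = (-120.0, 120.0)
ALPHA_PHI_PSI = (-57.0, -47.0)

#: Inter-strand spacing in an assembled sheet (Angstrom, Calpha to Calpha).
SHEET_SPACING = 4.9

#: Repeating sequence pattern with ~40% hydrophobic residues, the fraction
#: typical of corner motifs.
_SEQ_PATTERN = ("VAL", "THR", "LEU", "SER", "ASN")


def default_sequence(n: int) -> list[str]:
    """Repeating 5-residue pattern (40% hydrophobic) of length ``n``."""
    return [_SEQ_PATTERN[i % len(_SEQ_PATTERN)] for i in range(n)]


@dataclass
class BackboneSpec:
    """Recipe for an ideal backbone segment.

    ``torsions`` holds one (phi, psi, omega) triple per residue; phi of the
    first residue and omega of the last are not used in construction but are
    kept for symmetry.
    """

    sequence: list[str]
    torsions: list[tuple[float, float, float]]
    start_num: int = 1
    chain: str = "A"
    geometry: dict[str, float] = field(default_factory=lambda: dict(IDEAL_GEOMETRY))

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.torsions):
            raise ValueError("torsion list length must equal residue count")


@dataclass
class EnsembleSpec:
    """Recipe for a conformer ensemble with planted cluster structure.

    ``state_fractions`` are the planted cluster occupancies (must sum to 1);
    ``state_hinge_deg`` gives, per state, the hinge-bend angle(s) relative
    to the base conformer — a scalar for a single mid-chain hinge, or a
    tuple of angles for several hinges spread evenly along the chain
    (state 0 is conventionally all-zero).  Frames are the state conformer
    plus isotropic Gaussian coordinate noise of ``noise_sigma`` Angstrom.
    Frame counts per state are allocated deterministically
    (``round(fraction * n)``, remainder to the largest state) so the planted
    occupancy is exact and only the noise is stochastic.
    """

    base: Structure
    n_frames: int = 200
    noise_sigma: float = 0.5
    state_fractions: tuple[float, ...] = (1.0,)
    state_hinge_deg: tuple = (0.0,)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("ensembles need at least 2 frames")
        if len(self.state_fractions) != len(self.state_hinge_deg):
            raise ValueError("one hinge angle (set) per state is required")
        if abs(sum(self.state_fractions) - 1.0) > 1e-9:
            raise ValueError("state fractions must sum to 1")

    def hinge_angles(self, state: int) -> tuple[float, ...]:
        v = self.state_hinge_deg[state]
        return tuple(v) if isinstance(v, (tuple, list)) else (float(v),)


# ---------------------------------------------------------------------------
# torsion-space chain construction
# ---------------------------------------------------------------------------


def _build_backbone(torsions, geom=IDEAL_GEOMETRY) -> list[dict[str, np.ndarray]]:
    """Place N/CA/C for each residue by sequential natural-extension frames."""
    n_res = len(torsions)
    out: list[dict[str, np.ndarray]] = []
    theta = math.radians(geom["ang_N_CA_C"])
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([geom["N_CA"], 0.0, 0.0])
    c0 = ca0 + geom["CA_C"] * np.array([-math.cos(theta), math.sin(theta), 0.0])
    out.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        phi_i = torsions[i][0]
        psi_prev = torsions[i - 1][1]
        omega_prev = torsions[i - 1][2]
        prev = out[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"], geom["C_N"], geom["ang_CA_C_N"], psi_prev)
        ca = place_atom(prev["CA"], prev["C"], n, geom["N_CA"], geom["ang_C_N_CA"], omega_prev)
        c = place_atom(prev["C"], n, ca, geom["CA_C"], geom["ang_N_CA_C"], phi_i)
        out.append({"N": n, "CA": ca, "C": c})
    return out


def _extend_backbone(prev, phi, psi_prev, omega_prev, geom=IDEAL_GEOMETRY):
    """One natural-extension step from a residue's (N, CA, C)."""
    n = place_atom(prev["N"], prev["CA"], prev["C"], geom["C_N"], geom["ang_CA_C_N"], psi_prev)
    ca = place_atom(prev["CA"], prev["C"], n, geom["N_CA"], geom["ang_C_N_CA"], omega_prev)
    c = place_atom(prev["C"], n, ca, geom["CA_C"], geom["ang_N_CA_C"], phi)
    return {"N": n, "CA": ca, "C": c}


def _decorate(backbone, sequence, torsions, geom=IDEAL_GEOMETRY):
    """Add O (and CB for non-glycine) to bare N/CA/C backbones.

    O is placed trans to the following amide nitrogen, i.e. with
    dihedral(N, CA, C, O) = psi + 180.
    """
    full = []
    for res, name, tors in zip(backbone, sequence, torsions):
        atoms = dict(res)
        psi = tors[1]
        atoms["O"] = place_atom(
            res["N"], res["CA"], res["C"], geom["C_O"], geom["ang_CA_C_O"], wrap_angle(psi + 180.0)
        )
        if name != "GLY":
            atoms["CB"] = place_atom(
                res["N"], res["C"], res["CA"], geom["CA_CB"], geom["ang_CB_CA_C"], geom["dih_N_C_CA_CB"]
            )
        full.append(atoms)
    return full


_ATOM_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
_ATOM_ORDER = ("N", "CA", "C", "O", "CB")


def _to_structure(full_atoms, sequence, start_num=1, chain="A", struct_id="synthetic"):
    residues = []
    serial = 1
    for i, (atoms, name) in enumerate(zip(full_atoms, sequence)):
        alist = []
        for aname in _ATOM_ORDER:
            if aname in atoms:
                alist.append(
                    Atom(serial=serial, name=aname, element=_ATOM_ELEMENTS[aname], coords=atoms[aname])
                )
                serial += 1
        residues.append(Residue(res_name=name, seq_num=start_num + i, atoms=alist))
    return Structure(id=struct_id, models=[{chain: residues}], source="synthetic")


def build_ideal_segment(spec: BackboneSpec) -> Structure:
    """Build an ideal backbone (N, CA, C, O and CB for non-GLY) from torsions.

    Recomputing torsions on the result reproduces the spec values exactly
    (up to floating-point rounding) for interior residues.
    """
    backbone = _build_backbone(spec.torsions, spec.geometry)
    full = _decorate(backbone, spec.sequence, spec.torsions, spec.geometry)
    return _to_structure(full, spec.sequence, spec.start_num, spec.chain)


def build_ideal_strand(
    n_residues: int,
    phi: float = BETA_PHI_PSI[0],
    psi: float = BETA_PHI_PSI[1],
    omega: float = 180.0,
    sequence: list[str] | None = None,
    start_num: int = 1,
    chain: str = "A",
) -> Structure:
    """Convenience wrapper: a uniform-torsion segment (beta strand by default)."""
    seq = sequence if sequence is not None else ["GLY"] * n_residues
    spec = BackboneSpec(sequence=seq, torsions=[(phi, psi, omega)] * n_residues, start_num=start_num, chain=chain)
    return build_ideal_segment(spec)


# ---------------------------------------------------------------------------
# rigid strand placement
# ---------------------------------------------------------------------------


def _ideal_strand_backbone(n: int):
    tors = [(BETA_PHI_PSI[0], BETA_PHI_PSI[1], 180.0)] * n
    return _build_backbone(tors), tors


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation matrix taking unit vector a to unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # pick any axis orthogonal to a for the 180 degree flip
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return _axis_rotation(axis, 180.0)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _axis_rotation(axis: np.ndarray, deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = math.radians(deg)
    k = np.array(
        [[0.0, -axis[2], axis[1]], [axis[2], 0.0, -axis[0]], [-axis[1], axis[0], 0.0]]
    )
    return np.eye(3) + math.sin(t) * k + (1.0 - math.cos(t)) * (k @ k)


def _strand_ca(backbone) -> np.ndarray:
    return np.array([r["CA"] for r in backbone])


def _oriented_axis(ca: np.ndarray) -> np.ndarray:
    ax = principal_axis(ca)
    if np.dot(ax, ca[-1] - ca[0]) < 0:
        ax = -ax
    return ax


def _transform_backbone(backbone, rot: np.ndarray, trans: np.ndarray):
    return [{k: rot @ v + trans for k, v in res.items()} for res in backbone]


def _place_strand_on_line(n: int, direction: np.ndarray, first_ca: np.ndarray, spin_ref: np.ndarray):
    """Rigidly place an ideal n-residue strand with its Calpha axis along
    ``direction``, first Calpha at ``first_ca``, and the strand's off-axis
    scatter aligned with ``spin_ref`` (fixes the spin about the axis)."""
    backbone, tors = _ideal_strand_backbone(n)
    ca = _strand_ca(backbone)
    axis = _oriented_axis(ca)
    r1 = _rotation_between(axis, direction)
    # align the secondary (pleat) direction with spin_ref
    ca_r = (r1 @ (ca - ca[0]).T).T
    resid = ca_r - np.outer(ca_r @ direction, direction)
    if n >= 3 and np.linalg.norm(resid, axis=1).max() > 1e-9:
        pleat = principal_axis(resid + 1e-12)
        spin_target = spin_ref - np.dot(spin_ref, direction) * direction
        if np.linalg.norm(spin_target) > 1e-9 and np.linalg.norm(pleat) > 1e-9:
            pleat -= np.dot(pleat, direction) * direction
            if np.linalg.norm(pleat) > 1e-9:
                a = pleat / np.linalg.norm(pleat)
                b = spin_target / np.linalg.norm(spin_target)
                ang_s = math.degrees(math.atan2(np.dot(np.cross(a, b), direction), np.dot(a, b)))
                r1 = _axis_rotation(direction, ang_s) @ r1
    trans = first_ca - r1 @ ca[0]
    return _transform_backbone(backbone, r1, trans), tors


# ---------------------------------------------------------------------------
# CCD loop closure
# ---------------------------------------------------------------------------

# Loop psi values are confined to this window during closure, which keeps
# loop residues out of the beta torsion box (psi >= 45) so the generated
# label pattern is strand-loop-strand by construction.  The last loop
# residue is pinned further from the box edge because its effective psi is
# measured against the *placed* next strand and absorbs the closure
# residual.
_LOOP_PSI_RANGE = (-160.0, 30.0)
_LOOP_PSI_RANGE_LAST = (-160.0, -20.0)
_LOOP_SEED_TORSION = (-90.0, 0.0)


def _loop_chain(anchor, loop_torsions, target_phi, geom=IDEAL_GEOMETRY):
    """NeRF-extend anchor by the loop residues plus one virtual residue whose
    N/CA/C should coincide with the first residue of the next strand.

    ``loop_torsions`` holds (phi, psi, omega) per loop residue, omega being
    the peptide bond *following* the residue.
    """
    chain = []
    prev = anchor["res"]
    psi_prev = anchor["psi"]
    omega_prev = 180.0
    for phi, psi, omega in loop_torsions:
        nxt = _extend_backbone(prev, phi, psi_prev, omega_prev, geom)
        chain.append(nxt)
        prev = nxt
        psi_prev = psi
        omega_prev = omega
    virtual = _extend_backbone(prev, target_phi, psi_prev, omega_prev, geom)
    chain.append(virtual)
    return chain


def _psi_range(k: int, n_loop: int) -> tuple[float, float]:
    return _LOOP_PSI_RANGE_LAST if k == n_loop - 1 else _LOOP_PSI_RANGE


def _ccd_close_loop(anchor, target_res, n_loop, rng, target_phi=BETA_PHI_PSI[0], max_sweeps=80, tol=0.12, n_restarts=8):
    """Solve loop torsions so the virtual end residue lands on the target.

    Cyclic coordinate descent over the loop's phi/psi dihedrals, with psi
    clamped to the coil window.  Rotations are applied incrementally to the
    downstream atoms (no chain rebuilds inside the sweep).  Returns
    (torsion list, residual) of the best of a few seeded restarts.
    """
    targets = np.array([target_res["N"], target_res["CA"], target_res["C"]])

    def chain_to_array(chain):
        return np.array([res[a] for res in chain for a in ("N", "CA", "C")])

    def residual_of(atoms):
        return float(np.sqrt(np.mean(np.sum((atoms[-3:] - targets) ** 2, axis=1))))

    def decode_torsions(atoms):
        """Read the loop phi/psi/omega back off the final coordinates."""
        tors = []
        c_prev = anchor["res"]["C"]
        for k in range(n_loop):
            n_k, ca_k, c_k = atoms[3 * k], atoms[3 * k + 1], atoms[3 * k + 2]
            n_next, ca_next = atoms[3 * (k + 1)], atoms[3 * (k + 1) + 1]
            tors.append(
                (
                    dihedral(c_prev, n_k, ca_k, c_k),
                    dihedral(n_k, ca_k, c_k, n_next),
                    dihedral(ca_k, c_k, n_next, ca_next),
                )
            )
            c_prev = c_k
        return tors

    def solve_axis(atoms, o, u):
        ux, uy, uz = u
        a = b = 0.0
        for m in range(3):
            mv = atoms[m - 3]
            tv = targets[m]
            rx, ry, rz = mv[0] - o[0], mv[1] - o[1], mv[2] - o[2]
            along = rx * ux + ry * uy + rz * uz
            radx, rady, radz = rx - along * ux, ry - along * uy, rz - along * uz
            dx = tv[0] - (o[0] + along * ux)
            dy = tv[1] - (o[1] + along * uy)
            dz = tv[2] - (o[2] + along * uz)
            a += dx * radx + dy * rady + dz * radz
            cx = uy * radz - uz * rady
            cy = uz * radx - ux * radz
            cz = ux * rady - uy * radx
            b += dx * cx + dy * cy + dz * cz
        if abs(a) < 1e-12 and abs(b) < 1e-12:
            return None
        return math.degrees(math.atan2(b, a))

    best = None
    for _restart in range(n_restarts):
        tors0 = [
            (
                _LOOP_SEED_TORSION[0] + rng.uniform(-60, 60),
                float(np.clip(_LOOP_SEED_TORSION[1] + rng.uniform(-60, 60), *_psi_range(k, n_loop))),
                180.0,
            )
            for k in range(n_loop)
        ]
        atoms = chain_to_array(_loop_chain(anchor, tors0, target_phi))
        prev_resid = residual_of(atoms)
        stalled = 0
        for _sweep in range(max_sweeps):
            for k in range(n_loop):
                # phi, psi and (slightly flexible) omega axes of residue k
                for which in (0, 1, 2):
                    if which == 0:  # phi: axis N_k -> CA_k, moves C_k onward
                        o, u = atoms[3 * k], atoms[3 * k + 1] - atoms[3 * k]
                        down = 3 * k + 2
                    elif which == 1:  # psi: axis CA_k -> C_k, moves N_{k+1} onward
                        o, u = atoms[3 * k + 1], atoms[3 * k + 2] - atoms[3 * k + 1]
                        down = 3 * (k + 1)
                    else:  # omega: axis C_k -> N_{k+1}, moves CA_{k+1} onward
                        o, u = atoms[3 * k + 2], atoms[3 * (k + 1)] - atoms[3 * k + 2]
                        down = 3 * (k + 1) + 1
                    u = u / np.linalg.norm(u)
                    dtheta = solve_axis(atoms, o, u)
                    if dtheta is None:
                        continue
                    if which == 0:
                        # phi may roam anywhere unless psi sits in the beta
                        # range, in which case phi must stay out of the beta
                        # phi arc (the box needs both angles)
                        psi_now = dihedral(atoms[3 * k], atoms[3 * k + 1], atoms[3 * k + 2], atoms[3 * (k + 1)])
                        if psi_now >= 40.0 or psi_now <= -165.0:
                            c_prev = anchor["res"]["C"] if k == 0 else atoms[3 * k - 1]
                            phi_now = dihedral(c_prev, atoms[3 * k], atoms[3 * k + 1], atoms[3 * k + 2])
                            phi_new = float(np.clip(wrap_angle(phi_now + dtheta), -35.0, 175.0))
                            dtheta = wrap_angle(phi_new - phi_now)
                    elif which == 1:
                        # psi is clamped to the coil window only while phi is
                        # inside the beta phi arc
                        c_prev = anchor["res"]["C"] if k == 0 else atoms[3 * k - 1]
                        phi_now = dihedral(c_prev, atoms[3 * k], atoms[3 * k + 1], atoms[3 * k + 2])
                        if phi_now <= -40.0:
                            psi_now = dihedral(atoms[3 * k], atoms[3 * k + 1], atoms[3 * k + 2], atoms[3 * (k + 1)])
                            psi_new = float(np.clip(wrap_angle(psi_now + dtheta), *_psi_range(k, n_loop)))
                            dtheta = psi_new - psi_now
                    else:  # keep the peptide bond near trans
                        om_now = dihedral(atoms[3 * k + 1], atoms[3 * k + 2], atoms[3 * (k + 1)], atoms[3 * (k + 1) + 1])
                        dev = float(np.clip(wrap_angle(om_now + dtheta - 180.0), -15.0, 15.0))
                        dtheta = wrap_angle(180.0 + dev - om_now)
                    rot = _axis_rotation(u, dtheta)
                    atoms[down:] = (rot @ (atoms[down:] - o).T).T + o
            r = residual_of(atoms)
            if r < tol:
                prev_resid = r
                break
            if prev_resid - r < 1e-4:
                stalled += 1
                if stalled > 3:
                    break
                # kick the loop out of the local minimum with a random
                # clamped perturbation of every torsion
                tors_now = decode_torsions(atoms)
                kicked = []
                for kk, (p, ps, om) in enumerate(tors_now):
                    p_new = wrap_angle(p + rng.uniform(-25, 25))
                    ps_new = wrap_angle(ps + rng.uniform(-25, 25))
                    if p_new <= -40.0:
                        ps_new = float(np.clip(ps_new, *_psi_range(kk, n_loop)))
                    kicked.append((p_new, ps_new, om))
                atoms = chain_to_array(_loop_chain(anchor, kicked, target_phi))
                r = residual_of(atoms)
            else:
                stalled = 0
            prev_resid = r
        if best is None or prev_resid < best[1]:
            best = (decode_torsions(atoms), prev_resid)
        if best[1] < tol:
            break
    return best


# ---------------------------------------------------------------------------
# corner assembly
# ---------------------------------------------------------------------------


def _measured_rise() -> float:
    bb, _ = _ideal_strand_backbone(8)
    ca = _strand_ca(bb)
    ax = _oriented_axis(ca)
    return float(np.dot(ca[-1] - ca[0], ax) / (len(ca) - 1))


_RISE = None


def _rise() -> float:
    global _RISE
    if _RISE is None:
        _RISE = _measured_rise()
    return _RISE


def _join_strand_halves(half1, dir2: np.ndarray, m2: int, geom=IDEAL_GEOMETRY):
    """Continue a strand through a rigid bend: place an ideal m2-residue
    strand along ``dir2`` so its first N bonds onto half1's last residue,
    choosing the spin about the new axis that keeps the junction bond
    geometry closest to ideal."""
    prev = half1[-1]
    n_target = place_atom(prev["N"], prev["CA"], prev["C"], geom["C_N"], geom["ang_CA_C_N"], BETA_PHI_PSI[1])
    backbone, tors = _ideal_strand_backbone(m2)
    ca = _strand_ca(backbone)
    axis = _oriented_axis(ca)
    r1 = _rotation_between(axis, dir2)
    best = None
    for gamma in range(0, 360, 2):
        rot = _axis_rotation(dir2, float(gamma)) @ r1
        trans = n_target - rot @ backbone[0]["N"]
        ca0 = rot @ backbone[0]["CA"] + trans
        c0 = rot @ backbone[0]["C"] + trans
        ang_err = abs(angle(prev["C"], n_target, ca0) - geom["ang_C_N_CA"])
        omega = dihedral(prev["CA"], prev["C"], n_target, ca0)
        om_err = abs(wrap_angle(omega - 180.0))
        score = ang_err + 0.5 * om_err
        if best is None or score < best[0]:
            best = (score, rot, trans)
    _, rot, trans = best
    return _transform_backbone(backbone, rot, trans), tors


def _close_piece(anchor_res, piece_bb, n_loop, rng, slide_dir=None):
    """Close a loop from an anchor residue onto a rigid piece, optionally
    sliding the piece along a direction to find the most reachable
    placement.  Returns (placed piece, loop torsions, residual)."""
    anchor = {"res": anchor_res, "psi": BETA_PHI_PSI[1]}
    if slide_dir is None:
        offsets = [0.0]
    else:
        offsets = [0.0, -0.5, 0.5, -1.0, 1.0, -1.5, 1.5, -2.0, 2.0]

    def junction_safe(bb, tors):
        """The closure residual leaks into two dihedrals measured against the
        *placed* piece: the last loop psi and the piece's first phi.  Both
        must stay out of the beta box (psi) / inside it (phi) for the label
        pattern to match the construction."""
        chain = _loop_chain(anchor, tors, BETA_PHI_PSI[0])
        last = chain[n_loop - 1]
        eff_phi = dihedral(last["C"], bb[0]["N"], bb[0]["CA"], bb[0]["C"])
        if not -175.0 <= eff_phi <= -50.0:
            return False
        # the last loop residue's effective psi absorbs the closure residual;
        # it only matters when that residue's phi is in the beta phi arc
        if tors[n_loop - 1][0] > -35.0:
            return True
        eff_psi = dihedral(last["N"], last["CA"], last["C"], bb[0]["N"])
        return -168.0 <= eff_psi <= 38.0

    candidates = []
    for off in offsets:
        bb = piece_bb if off == 0.0 else _transform_backbone(piece_bb, np.eye(3), off * slide_dir)
        tors, resid = _ccd_close_loop(anchor, bb[0], n_loop, rng, max_sweeps=30, n_restarts=2)
        safe = junction_safe(bb, tors)
        candidates.append((not safe, resid, bb, tors))
        if safe and resid < 0.15:
            break
    unsafe, resid, bb, tors = min(candidates, key=lambda t: (t[0], t[1]))
    if unsafe or resid >= 0.15:
        tors2, resid2 = _ccd_close_loop(anchor, bb[0], n_loop, rng, max_sweeps=120, n_restarts=8)
        if (not junction_safe(bb, tors2), resid2) < (unsafe, resid):
            tors, resid = tors2, resid2
    return bb, tors, resid


def _assemble_chain(pieces, loop_specs, sequence, rng, start_num=1, chain="A", struct_id="synthetic", slide_dirs=None):
    """Stitch rigid strand pieces together with CCD-closed loops.

    ``pieces`` is a list of (backbone, torsions); ``loop_specs`` gives the
    loop length between consecutive pieces; ``slide_dirs`` optionally allows
    each non-first piece to slide along a direction during closure.
    """
    all_bb = []
    all_tors = []
    for idx, (bb, tors) in enumerate(pieces):
        if idx > 0:
            n_loop = loop_specs[idx - 1]
            slide = slide_dirs[idx - 1] if slide_dirs else None
            bb, loop_tors, _resid = _close_piece(all_bb[-1], bb, n_loop, rng, slide)
            anchor = {"res": all_bb[-1], "psi": BETA_PHI_PSI[1]}
            loop_bb = _loop_chain(anchor, loop_tors, BETA_PHI_PSI[0])[:-1]
            all_bb.extend(loop_bb)
            all_tors.extend(loop_tors)
        all_bb.extend(bb)
        all_tors.extend(tors)
    return _finalize_chain(all_bb, all_tors, sequence, start_num, chain, struct_id)


def _finalize_chain(all_bb, all_tors, sequence, start_num=1, chain="A", struct_id="synthetic"):
    # recompute effective psi from coordinates where defined so O placement
    # is consistent with the actual assembled geometry
    eff_tors = []
    for i, res in enumerate(all_bb):
        phi, psi, omega = all_tors[i]
        if i + 1 < len(all_bb):
            psi = dihedral(res["N"], res["CA"], res["C"], all_bb[i + 1]["N"])
        eff_tors.append((phi, psi, omega))
    full = _decorate(all_bb, sequence, eff_tors)
    return _to_structure(full, sequence, start_num, chain, struct_id)


def build_synthetic_corner(
    strand_lengths: tuple[int, int, int] = (6, 8, 6),
    loop_lengths: tuple[int, int] = (4, 4),
    handedness: str = "right",
    seed: int = DEFAULT_SEED,
    sequence: list[str] | None = None,
    start_num: int = 1,
    chain: str = "A",
):
    """Assemble a 3beta-corner: two beta-hairpins in orthogonal planes joined
    through a central strand bent by ~90 degrees with the requested
    handedness.

    Returns ``(structure, ground_truth)`` where ``ground_truth`` is a dict of
    the planted strand/loop residue ranges (author numbering, inclusive) and
    construction parameters; the planted geometry follows the same
    measurement conventions the motif detector applies.
    """
    a, b, c = strand_lengths
    l1, l2 = loop_lengths
    for s in (a, b, c):
        if not 4 <= s <= 10:
            raise ValueError(f"strand length {s} outside the 4-10 residue window")
    for l in (l1, l2):
        if not 3 <= l <= 12:
            raise ValueError(f"loop length {l} outside the 3-12 residue window")
    total = a + b + c + l1 + l2
    if not 25 <= total <= 55:
        raise ValueError(f"total motif length {total} outside the 25-55 residue window")
    if handedness not in ("right", "left"):
        raise ValueError("handedness must be 'right' or 'left'")

    rng = np.random.default_rng(seed)
    rise = _rise()
    d = SHEET_SPACING
    xhat = np.array([1.0, 0.0, 0.0])
    yhat = np.array([0.0, 1.0, 0.0])
    zhat = np.array([0.0, 0.0, 1.0])
    bend_dir = zhat if handedness == "right" else -zhat

    m1 = max(b // 2, 2)
    m2 = b - m1

    # strand A: antiparallel above the B N-half, running -x
    a_first = np.array([(a - 1) * rise - 1.0, d, 0.0])
    a_bb, a_tors = _place_strand_on_line(a, -xhat, a_first, zhat)
    # B N-half along +x from the origin
    h1_bb, h1_tors = _place_strand_on_line(m1, xhat, np.array([0.0, 0.0, 0.0]), zhat)

    all_bb = list(a_bb)
    all_tors = list(a_tors)
    # close loop A->B, letting the whole B strand slide along its axis
    h1_bb, loop1_tors, _r1 = _close_piece(all_bb[-1], h1_bb, l1, rng, slide_dir=xhat)
    anchor = {"res": all_bb[-1], "psi": BETA_PHI_PSI[1]}
    all_bb.extend(_loop_chain(anchor, loop1_tors, BETA_PHI_PSI[0])[:-1])
    all_tors.extend(loop1_tors)
    all_bb.extend(h1_bb)
    all_tors.extend(h1_tors)
    # B C-half bent through ~90 degrees off the placed N-half
    h2_bb, h2_tors = _join_strand_halves(h1_bb, bend_dir, m2)
    all_bb.extend(h2_bb)
    all_tors.extend(h2_tors)
    # strand C: antiparallel to the placed B C-half, displaced along +x
    h2_ca = _strand_ca(h2_bb)
    c_first = h2_ca[-1] + d * xhat
    c_bb, c_tors = _place_strand_on_line(c, -bend_dir, c_first, yhat)
    c_bb, loop2_tors, _r2 = _close_piece(all_bb[-1], c_bb, l2, rng, slide_dir=np.asarray(-bend_dir, dtype=float))
    anchor = {"res": all_bb[-1], "psi": BETA_PHI_PSI[1]}
    all_bb.extend(_loop_chain(anchor, loop2_tors, BETA_PHI_PSI[0])[:-1])
    all_tors.extend(loop2_tors)
    all_bb.extend(c_bb)
    all_tors.extend(c_tors)

    seq = sequence if sequence is not None else default_sequence(total)
    if len(seq) != total:
        raise ValueError("sequence length must equal the total motif length")
    structure = _finalize_chain(
        all_bb,
        all_tors,
        seq,
        start_num=start_num,
        chain=chain,
        struct_id=f"corner_{a}-{b}-{c}_{handedness}_s{seed}",
    )

    sA = (start_num, start_num + a - 1)
    sB = (sA[1] + l1 + 1, sA[1] + l1 + b)
    sC = (sB[1] + l2 + 1, sB[1] + l2 + c)
    ground_truth = {
        "chain": chain,
        "strand_a": sA,
        "strand_b": sB,
        "strand_c": sC,
        "loop_ab": (sA[1] + 1, sB[0] - 1),
        "loop_bc": (sB[1] + 1, sC[0] - 1),
        "handedness": handedness,
        "total_length": total,
        "seed": seed,
    }
    return structure, ground_truth


def build_ideal_hairpin(
    strand_length: int = 6,
    loop_length: int = 4,
    seed: int = DEFAULT_SEED,
    sequence: list[str] | None = None,
) -> Structure:
    """An antiparallel two-strand beta-hairpin: two rigidly placed ideal
    strands at sheet spacing joined by a CCD-closed turn."""
    rng = np.random.default_rng(seed)
    rise = _rise()
    d = SHEET_SPACING
    xhat = np.array([1.0, 0.0, 0.0])
    zhat = np.array([0.0, 0.0, 1.0])
    total = 2 * strand_length + loop_length
    s1_bb, s1_tors = _place_strand_on_line(
        strand_length, -xhat, np.array([(strand_length - 1) * rise - 1.0, d, 0.0]), zhat
    )
    s2_bb, s2_tors = _place_strand_on_line(strand_length, xhat, np.array([0.0, 0.0, 0.0]), zhat)
    seq = sequence if sequence is not None else default_sequence(total)
    return _assemble_chain(
        [(s1_bb, s1_tors), (s2_bb, s2_tors)],
        [loop_length],
        seq,
        rng,
        struct_id=f"hairpin_{strand_length}_{loop_length}_s{seed}",
        slide_dirs=[xhat],
    )


def build_negative_control(kind: str, n_residues: int, seed: int = DEFAULT_SEED) -> Structure:
    """Decoy structures for the detector and the stability battery.

    ``coil``: torsions drawn from a broad distribution that avoids both the
    beta and alpha boxes.  ``helix``: ideal alpha helix.  ``flat_sheet``:
    three antiparallel strands in a single plane (a corner decoy with no
    bend and coplanar hairpins).
    """
    if n_residues < 5:
        raise ValueError("negative controls need at least 5 residues")
    rng = np.random.default_rng(seed)
    if kind == "coil":
        tors = []
        for _ in range(n_residues):
            phi = float(rng.uniform(-180.0, 180.0))
            psi = float(rng.uniform(-160.0, 35.0))
            # stay out of the alpha box as well
            while -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0:
                phi = float(rng.uniform(-180.0, 180.0))
                psi = float(rng.uniform(-160.0, 35.0))
            tors.append((phi, psi, 180.0))
        spec = BackboneSpec(sequence=default_sequence(n_residues), torsions=tors)
        st = build_ideal_segment(spec)
        st.id = f"coil_{n_residues}_s{seed}"
        return st
    if kind == "helix":
        spec = BackboneSpec(
            sequence=default_sequence(n_residues),
            torsions=[(ALPHA_PHI_PSI[0], ALPHA_PHI_PSI[1], 180.0)] * n_residues,
        )
        st = build_ideal_segment(spec)
        st.id = f"helix_{n_residues}_s{seed}"
        return st
    if kind == "flat_sheet":
        # three strands + two loops filling n_residues, all in one plane
        n_loop = 4
        n_strand = (n_residues - 2 * n_loop) // 3
        n_strand = int(np.clip(n_strand, 4, 10))
        rise = _rise()
        d = SHEET_SPACING
        xhat = np.array([1.0, 0.0, 0.0])
        zhat = np.array([0.0, 0.0, 1.0])
        aa_bb, aa_tors = _place_strand_on_line(
            n_strand, -xhat, np.array([(n_strand - 1) * rise - 1.0, 2 * d, 0.0]), zhat
        )
        bb_bb, bb_tors = _place_strand_on_line(n_strand, xhat, np.array([0.0, d, 0.0]), zhat)
        cc_bb, cc_tors = _place_strand_on_line(
            n_strand, -xhat, np.array([(n_strand - 1) * rise - 1.0, 0.0, 0.0]), zhat
        )
        total = 3 * n_strand + 2 * n_loop
        st = _assemble_chain(
            [(aa_bb, aa_tors), (bb_bb, bb_tors), (cc_bb, cc_tors)],
            [n_loop, n_loop],
            default_sequence(total),
            rng,
            struct_id=f"flat_sheet_{total}_s{seed}",
        )
        return st
    raise ValueError(f"unknown negative-control kind {kind!r}")


# ---------------------------------------------------------------------------
# conformer ensembles
# ---------------------------------------------------------------------------


def _hinge_rotate(coords: np.ndarray, ca_indices: np.ndarray, split_atom: int, pivot: np.ndarray, axis: np.ndarray, deg: float) -> np.ndarray:
    rot = _axis_rotation(axis, deg)
    out = coords.copy()
    out[split_atom:] = (rot @ (coords[split_atom:] - pivot).T).T + pivot
    return out


def generate_ensemble(spec: EnsembleSpec):
    """Generate a multi-model conformer ensemble with planted cluster
    structure.

    Returns ``(ensemble_structure, labels)``: a Structure whose models are
    the frames (in shuffled state order) and the integer state label of each
    frame.  States are hinge-bent copies of the base conformer; frames add
    isotropic Gaussian noise.
    """
    import copy as _copy

    base = spec.base
    rng = np.random.default_rng(spec.seed)
    residues = base.residues(model=0)
    coords = base.coords(model=0)
    n_res = len(residues)
    counts = np.cumsum([len(r.atoms) for r in residues])
    ca = np.array([r.atom("CA").coords for r in residues if r.atom("CA") is not None])

    n_hinges = max(len(spec.hinge_angles(k)) for k in range(len(spec.state_fractions)))
    hinges = []  # (split_atom_index, pivot, axis)
    for h in range(n_hinges):
        hinge_res = int(round((h + 1) * n_res / (n_hinges + 1)))
        hinge_res = min(max(hinge_res, 1), n_res - 2)
        split_atom = int(counts[hinge_res - 1])
        pivot = ca[hinge_res]
        v1 = ca[hinge_res] - ca[hinge_res - 1]
        v2 = ca[hinge_res + 1] - ca[hinge_res]
        axis = np.cross(v1, v2)
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(v1, [0.0, 0.0, 1.0])
        hinges.append((split_atom, pivot, axis / np.linalg.norm(axis)))

    state_coords = []
    for k in range(len(spec.state_fractions)):
        c = coords
        for h, deg in enumerate(spec.hinge_angles(k)):
            if deg != 0.0:
                split_atom, pivot, axis = hinges[h]
                c = _hinge_rotate(c, None, split_atom, pivot, axis, deg)
        state_coords.append(c)

    n = spec.n_frames
    counts_per_state = [int(round(f * n)) for f in spec.state_fractions]
    diff = n - sum(counts_per_state)
    counts_per_state[int(np.argmax(spec.state_fractions))] += diff
    labels = np.repeat(np.arange(len(counts_per_state)), counts_per_state)
    labels = labels[rng.permutation(n)]

    models = []
    template = base.models[0]
    chain_id = list(template.keys())[0]
    for lab in labels:
        frame = state_coords[lab] + rng.normal(0.0, spec.noise_sigma, size=coords.shape)
        res_list = []
        k = 0
        for r in template[chain_id]:
            new_r = Residue(res_name=r.res_name, seq_num=r.seq_num, icode=r.icode, atoms=[])
            for a in r.atoms:
                new_r.atoms.append(
                    Atom(serial=a.serial, name=a.name, element=a.element, coords=frame[k].copy())
                )
                k += 1
            res_list.append(new_r)
        models.append({chain_id: res_list})
    ensemble = Structure(id=f"{base.id}_ens_s{spec.seed}", models=models, source="synthetic")
    return ensemble, labels
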