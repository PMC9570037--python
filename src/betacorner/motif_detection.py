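"""3beta-corner motif detection.

A 3beta-corner is a triple-stranded beta-sheet folded onto itself: two
beta-hairpins packed roughly orthogonally in different layers, with the
central strand bending by about 90 degrees in the right-handed direction as
it passes from one layer to the other (a Z-like sheet seen from its concave
face).

Detection is a two-stage filter:

1. :func:`candidate_patterns` — the sequence pattern
   strand -> coil -> strand -> coil -> strand on secondary-structure labels,
   with strand lengths 4-10, loop lengths 3-12 and a 25-55 residue total
   span.
2. :func:`corner_geometry` — the packing geometry: interplanar angle of the
   two hairpin planes, bend angle of the central strand's halves, and the
   handedness of the bend from a signed triple product.

Overlapping candidates are all geometry-tested; no non-maximum suppression
is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geom import angle_between, fit_plane_normal, principal_axis
from .config import MotifWindows
from .secondary_structure import assign_hbond_based, assign_torsion_based, consensus
from .structure_io import Structure

__all__ = [
    "StrandRange",
    "ThreeBetaCorner",
    "Rejection",
    "candidate_patterns",
    "strand_axis",
    "corner_geometry",
    "find_3b_corners",
]


@dataclass(frozen=True)
class StrandRange:
    """A strand's author-numbered residue range with its fitted axis."""

    chain: str
    start: int
    end: int
    axis: tuple[float, float, float]
    centroid: tuple[float, float, float]

    @property
    def n_residues(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ThreeBetaCorner:
    """An accepted corner: three strands (sequence order A, B, C), the two
    connecting loops, and the measured packing geometry."""

    chain: str
    strand_a: StrandRange
    strand_b: StrandRange
    strand_c: StrandRange
    loop_ab: tuple[int, int]
    loop_bc: tuple[int, int]
    interplanar_angle: float
    bend_angle: float
    handedness: str
    total_length: int


@dataclass(frozen=True)
class Rejection:
    """A candidate that failed the geometric filter, with the reason."""

    chain: str
    ranges: tuple[tuple[int, int], ...]
    reason: str


def candidate_patterns(labels: list[str], windows: MotifWindows | None = None):
    """Enumerate strand-coil-strand-coil-strand windows in a label vector.

    Returns index-range tuples ``(A, loopAB, B, loopBC, C)`` (0-based,
    half-open is *not* used: ranges are inclusive ``(start, end)``).
    Candidates may overlap; enumeration is exhaustive over consecutive
    triples of qualifying strand runs.
    """
    w = windows or MotifWindows()
    runs = []  # (start, end_inclusive, label)
    start = 0
    n = len(labels)
    for i in range(1, n + 1):
        if i == n or (labels[i] == "E") != (labels[start] == "E"):
            runs.append((start, i - 1, "E" if labels[start] == "E" else "-"))
            start = i
    e_runs = [(s, e) for s, e, lab in runs if lab == "E"]
    out = []
    for k in range(len(e_runs) - 2):
        (a0, a1), (b0, b1), (c0, c1) = e_runs[k], e_runs[k + 1], e_runs[k + 2]
        la, lb, lc = a1 - a0 + 1, b1 - b0 + 1, c1 - c0 + 1
        gap_ab = b0 - a1 - 1
        gap_bc = c0 - b1 - 1
        total = c1 - a0 + 1
        if not all(w.strand_min <= L <= w.strand_max for L in (la, lb, lc)):
            continue
        if not all(w.loop_min <= g <= w.loop_max for g in (gap_ab, gap_bc)):
            continue
        if not w.total_min <= total <= w.total_max:
            continue
        out.append(((a0, a1), (a1 + 1, b0 - 1), (b0, b1), (b1 + 1, c0 - 1), (c0, c1)))
    return out


def strand_axis(ca_coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal direction and centroid of a strand's Calpha trace.

    The axis is the largest-variance principal direction of the centred
    points, oriented N-to-C (positive projection on last - first).
    """
    ca = np.asarray(ca_coords, dtype=float)
    if ca.shape[0] < 3:
        raise ValueError("strand axis needs at least 3 Calpha positions")
    axis = principal_axis(ca)
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis, ca.mean(axis=0)


def _segment_direction(ca: np.ndarray) -> np.ndarray:
    """N-to-C direction of a Calpha segment; principal axis when 3+ points,
    plain end-to-end difference for 2 (central-strand halves can be short)."""
    if len(ca) >= 3:
        return strand_axis(ca)[0]
    d = ca[-1] - ca[0]
    return d / np.linalg.norm(d)


def corner_geometry(
    candidate,
    s: Structure,
    chain: str | None = None,
    model: int = 0,
    windows: MotifWindows | None = None,
):
    """Measure a candidate's packing geometry and accept or reject it.

    The two hairpins are A + the N-half of B and the C-half of B + C; each
    hairpin plane is fitted to its pooled Calpha scatter.  The bend angle is
    the angle between the two halves' axes.  Handedness is right when
    ``(b1 x b2) . w > 0`` with b1/b2 the half axes and w the vector from the
    first hairpin's centroid to the second's.

    Returns a :class:`ThreeBetaCorner` on acceptance, else a
    :class:`Rejection` naming the failed criterion.
    """
    w = windows or MotifWindows()
    if chain is None:
        chain = s.chains(model)[0]
    residues = s.residues(chain=chain, model=model)
    (a0, a1), (ab0, ab1), (b0, b1), (bc0, bc1), (c0, c1) = candidate

    def ca_range(i0, i1):
        out = []
        for i in range(i0, i1 + 1):
            atom = residues[i].atom("CA")
            if atom is not None:
                out.append(atom.coords)
        return np.array(out).reshape(-1, 3)

    ranges = tuple((residues[i].seq_num, residues[j].seq_num) for i, j in [(a0, a1), (b0, b1), (c0, c1)])
    ca_a, ca_b, ca_c = ca_range(a0, a1), ca_range(b0, b1), ca_range(c0, c1)
    if min(len(ca_a), len(ca_b), len(ca_c)) < 3:
        return Rejection(chain, ranges, "unresolved Calpha in a strand")

    mid = len(ca_b) // 2
    b_n_half, b_c_half = ca_b[:mid], ca_b[mid:]
    hairpin1 = np.vstack([ca_a, b_n_half])
    hairpin2 = np.vstack([b_c_half, ca_c])
    try:
        n1 = fit_plane_normal(hairpin1)
        n2 = fit_plane_normal(hairpin2)
    except ValueError:
        return Rejection(chain, ranges, "degenerate hairpin plane")
    # rank check: the scatter must actually span a plane
    for pts in (hairpin1, hairpin2):
        sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if sv[1] < 1.0:  # Angstrom: second principal extent too thin
            return Rejection(chain, ranges, "degenerate hairpin plane")

    inter = angle_between(n1, n2)
    inter = min(inter, 180.0 - inter)  # plane normals have no sign
    half_n_axis = _segment_direction(b_n_half)
    half_c_axis = _segment_direction(b_c_half)
    bend = angle_between(half_n_axis, half_c_axis)
    wvec = hairpin2.mean(axis=0) - hairpin1.mean(axis=0)
    handed = "right" if float(np.dot(np.cross(half_n_axis, half_c_axis), wvec)) > 0 else "left"

    lo, hi = w.interplanar_window
    if not lo <= inter <= hi:
        return Rejection(chain, ranges, f"interplanar angle {inter:.1f} outside [{lo}, {hi}]")
    lo, hi = w.bend_window
    if not lo <= bend <= hi:
        return Rejection(chain, ranges, f"bend angle {bend:.1f} outside [{lo}, {hi}]")
    if w.require_right_handed and handed != "right":
        return Rejection(chain, ranges, "left-handed central-strand bend")

    def mk_strand(i0, i1, ca):
        ax, cen = _segment_direction(ca), ca.mean(axis=0)
        return StrandRange(
            chain=chain,
            start=residues[i0].seq_num,
            end=residues[i1].seq_num,
            axis=tuple(float(x) for x in ax),
            centroid=tuple(float(x) for x in cen),
        )

    return ThreeBetaCorner(
        chain=chain,
        strand_a=mk_strand(a0, a1, ca_a),
        strand_b=mk_strand(b0, b1, ca_b),
        strand_c=mk_strand(c0, c1, ca_c),
        loop_ab=(residues[ab0].seq_num, residues[ab1].seq_num),
        loop_bc=(residues[bc0].seq_num, residues[bc1].seq_num),
        interplanar_angle=float(inter),
        bend_angle=float(bend),
        handedness=handed,
        total_length=c1 - a0 + 1,
    )


def find_3b_corners(
    s: Structure,
    windows: MotifWindows | None = None,
    assigner: str = "torsion",
    model: int = 0,
    return_rejections: bool = False,
):
    """Scan every chain for 3beta-corners.

    ``assigner`` selects the secondary-structure labels fed to the pattern
    stage: ``torsion`` (default; robust on idealised backbones), ``hbond``,
    or ``consensus`` of both.  Results are deterministic and ordered by
    chain then start residue.
    """
    w = windows or MotifWindows()
    found: list[ThreeBetaCorner] = []
    rejected: list[Rejection] = []
    for chain in sorted(s.chains(model)):
        if assigner == "torsion":
            labels = assign_torsion_based(s, chain=chain, model=model)
        elif assigner == "hbond":
            labels = assign_hbond_based(s, chain=chain, model=model)
        elif assigner == "consensus":
            lv = [
                assign_torsion_based(s, chain=chain, model=model),
                assign_hbond_based(s, chain=chain, model=model),
            ]
            labels = list(consensus(lv).agreed)
        else:
            raise ValueError(f"unknown assigner {assigner!r}")
        for cand in candidate_patterns(labels, w):
            result = corner_geometry(cand, s, chain=chain, model=model, windows=w)
            if isinstance(result, ThreeBetaCorner):
                found.append(result)
            else:
                rejected.append(result)
    found.sort(key=lambda m: (m.chain, m.strand_a.start))
    if return_rejections:
        return found, rejected
    return found
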