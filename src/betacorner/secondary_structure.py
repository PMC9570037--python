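"""Per-residue secondary-structure assignment.

Two independent assigners are provided and can be combined by consensus:

* :func:`assign_hbond_based` — a Kabsch–Sander-style assigner: backbone
  amide/carbonyl hydrogen bonds are scored with the classic electrostatic
  energy model, ladders of inter-strand bonds become strand (E) and helical
  n-turns become helix (H).
* :func:`assign_torsion_based` — a phi/psi box assigner with singleton
  smoothing, robust on idealised backbones and Calpha-level fixtures.

Real assigners famously disagree on a large fraction of residues; the
:func:`consensus` operation makes that disagreement measurable (match rate)
and resolves it by majority.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import TorsionSSBoxes
from .geometry_metrics import torsions
from .structure_io import Structure

__all__ = [
    "SSConsensus",
    "assign_hbond_based",
    "assign_torsion_based",
    "consensus",
    "smooth_labels",
]

#: Kabsch-Sander electrostatic H-bond model constants.
_KS_Q = 0.084  # partial charge product factor
_KS_F = 332.0  # electrostatic conversion, kcal*A/mol
_KS_CUTOFF = -0.5  # kcal/mol
_NH_BOND = 1.01  # Angstrom, amide N-H


@dataclass(frozen=True)
class SSConsensus:
    """Combined view of several assigners on the same residue range."""

    per_assigner: tuple[str, ...]
    agreed: str
    match_rate: float


def _amide_hydrogens(residues) -> list[np.ndarray | None]:
    """Backbone amide H positions: the explicit atom when present, otherwise
    reconstructed on the bisector of the N-C(prev) and N-CA directions.
    The first residue (free amine) gets none."""
    out: list[np.ndarray | None] = []
    for i, res in enumerate(residues):
        h = res.atom("H")
        if h is not None:
            out.append(h.coords)
            continue
        if i == 0:
            out.append(None)
            continue
        n, ca = res.atom("N"), res.atom("CA")
        c_prev = residues[i - 1].atom("C")
        if n is None or ca is None or c_prev is None:
            out.append(None)
            continue
        d1 = n.coords - c_prev.coords
        d2 = n.coords - ca.coords
        d1 /= np.linalg.norm(d1)
        d2 /= np.linalg.norm(d2)
        bis = d1 + d2
        norm = np.linalg.norm(bis)
        out.append(n.coords + _NH_BOND * bis / norm if norm > 1e-8 else None)
    return out


def _ks_hbond_matrix(residues) -> np.ndarray:
    """hbond[i, j] is True when the carbonyl of residue i accepts a hydrogen
    bond from the amide of residue j (Kabsch-Sander energy < -0.5 kcal/mol)."""
    n_res = len(residues)
    hpos = _amide_hydrogens(residues)
    hb = np.zeros((n_res, n_res), dtype=bool)
    for i, acc in enumerate(residues):
        c, o = acc.atom("C"), acc.atom("O")
        if c is None or o is None:
            continue
        for j, don in enumerate(residues):
            if abs(i - j) < 2:
                continue
            nn = don.atom("N")
            h = hpos[j]
            if nn is None or h is None:
                continue
            r_on = np.linalg.norm(o.coords - nn.coords)
            r_ch = np.linalg.norm(c.coords - h)
            r_oh = np.linalg.norm(o.coords - h)
            r_cn = np.linalg.norm(c.coords - nn.coords)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue  # clashing geometry, not a bond
            energy = _KS_Q * _KS_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            hb[i, j] = energy < _KS_CUTOFF
    return hb


def assign_hbond_based(s: Structure, chain: str | None = None, model: int = 0) -> list[str]:
    """Kabsch-Sander-style labels: E (strand, from bridge ladders), H (helix,
    from consecutive 4-turns), T (isolated turns), C otherwise.

    Purely distance-based, hence invariant under rigid motion *and* mirror
    reflection (handedness is the motif detector's job, not the assigner's).
    """
    residues = s.residues(chain=chain, model=model)
    n = len(residues)
    if n < 3:
        return ["C"] * n
    hb = _ks_hbond_matrix(residues)

    def hbond(i: int, j: int) -> bool:
        return 0 <= i < n and 0 <= j < n and bool(hb[i, j])

    labels = ["C"] * n
    # helices: two consecutive 4-turns
    turn4 = [hbond(i, i + 4) for i in range(n)]
    for i in range(n - 1):
        if turn4[i] and i + 1 < n and turn4[i + 1]:
            for k in range(i + 1, min(i + 5, n)):
                labels[k] = "H"
    # beta bridges
    in_bridge = [False] * n
    for i in range(n):
        for j in range(i + 3, n):
            anti = (hbond(i, j) and hbond(j, i)) or (
                hbond(i - 1, j + 1) and hbond(j - 1, i + 1)
            )
            para = (hbond(i - 1, j) and hbond(j, i + 1)) or (
                hbond(j - 1, i) and hbond(i, j + 1)
            )
            if anti or para:
                in_bridge[i] = in_bridge[j] = True
    for i in range(n):
        if in_bridge[i] and labels[i] != "H":
            labels[i] = "E"
    # isolated turns
    for i in range(n):
        for t in (3, 4, 5):
            if hbond(i, i + t):
                for k in range(i + 1, min(i + t, n)):
                    if labels[k] == "C":
                        labels[k] = "T"
    return labels


def smooth_labels(labels: list[str]) -> list[str]:
    """Remove singleton label runs.

    A run of length one takes its neighbours' label when they agree and at
    least one of them is a genuine run (length > 1); a singleton flanked
    only by other singletons, or by disagreeing neighbours, becomes coil.
    Applied iteratively to a fixed point, so alternating label sequences
    collapse to a coil-dominant vector with no singleton runs."""
    labels = list(labels)
    for _ in range(len(labels)):
        runs = []  # (start, end_exclusive, label)
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                runs.append((start, i, labels[start]))
                start = i
        new = list(labels)
        changed = False
        for k, (a, b, lab) in enumerate(runs):
            if b - a != 1:
                continue
            left = runs[k - 1] if k > 0 else None
            right = runs[k + 1] if k + 1 < len(runs) else None
            if left is None and right is None:
                continue
            if left is None:
                repl = right[2] if right[1] - right[0] > 1 else "C"
            elif right is None:
                repl = left[2] if left[1] - left[0] > 1 else "C"
            elif left[2] == right[2] and (left[1] - left[0] > 1 or right[1] - right[0] > 1):
                repl = left[2]
            else:
                repl = "C"
            if repl != lab:
                new[a] = repl
                changed = True
        labels = new
        if not changed:
            break
    return labels


def assign_torsion_based(
    s: Structure,
    chain: str | None = None,
    model: int = 0,
    boxes: TorsionSSBoxes | None = None,
    smooth: bool = True,
) -> list[str]:
    """phi/psi box labels: E in the beta box, H in the alpha box, C
    otherwise (and at termini, where a torsion is undefined).  Singleton
    runs are smoothed away by default."""
    boxes = boxes or TorsionSSBoxes()
    tors = torsions(s, chain=chain, model=model)
    labels = []
    for t in tors:
        if t.phi is None or t.psi is None:
            labels.append("C")
            continue
        phi, psi = t.phi, t.psi
        in_beta = boxes.beta_phi[0] <= phi <= boxes.beta_phi[1] and (
            boxes.beta_psi[0] <= psi <= boxes.beta_psi[1]
            or boxes.beta_psi_wrap[0] <= psi <= boxes.beta_psi_wrap[1]
        )
        in_alpha = (
            boxes.alpha_phi[0] <= phi <= boxes.alpha_phi[1]
            and boxes.alpha_psi[0] <= psi <= boxes.alpha_psi[1]
        )
        labels.append("E" if in_beta else "H" if in_alpha else "C")
    return smooth_labels(labels) if smooth else labels


def consensus(label_vectors: list[list[str]]) -> SSConsensus:
    """Combine assigner outputs: unanimous label where all agree, majority
    otherwise (ties resolved in favour of the first assigner).  The match
    rate is the fraction of residues with unanimous agreement."""
    if len(label_vectors) < 2:
        raise ValueError("consensus needs at least 2 label vectors")
    lengths = {len(v) for v in label_vectors}
    if len(lengths) != 1:
        raise ValueError(f"label vectors differ in length: {sorted(lengths)}")
    n = lengths.pop()
    agreed = []
    n_match = 0
    for i in range(n):
        votes = [v[i] for v in label_vectors]
        if len(set(votes)) == 1:
            n_match += 1
            agreed.append(votes[0])
            continue
        counts: dict[str, int] = {}
        for lab in votes:
            counts[lab] = counts.get(lab, 0) + 1
        best = max(counts.values())
        winners = [lab for lab, c in counts.items() if c == best]
        if len(winners) == 1:
            agreed.append(winners[0])
        else:
            agreed.append(next(lab for lab in votes if lab in winners))
    return SSConsensus(
        per_assigner=tuple("".join(v) for v in label_vectors),
        agreed="".join(agreed),
        match_rate=n_match / n if n else 1.0,
    )
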