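"""Hydrophobic contact topology of corner motifs.

Corner motifs carry an unusually high fraction (~40%) of hydrophobic
residues, and their packing shows up as a bimodal distribution of
hydrophobic contact distances: a short mode from residues within one strand
or between hydrogen-bonded neighbour strands, and a longer mode from
first-to-third strand (A-C) contacts across the two orthogonal sheet
layers.  This module measures residue-pair distances, classifies each
contact as inside-strand or cross-strand (A-B, B-C, A-C; pairs involving
loop residues are "other"), and histograms them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ContactParams
from .motif_detection import ThreeBetaCorner
from .structure_io import Residue, Structure

__all__ = [
    "ContactRecord",
    "DistanceHistogram",
    "hydrophobic_fraction",
    "residue_distance",
    "hydrophobic_contacts",
    "contact_histogram",
]

CONTACT_CLASSES = ("inside-strand", "A-B", "B-C", "A-C", "other")

_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass(frozen=True)
class ContactRecord:
    """One hydrophobic residue pair: author seq numbers (i < j in sequence),
    distance in Angstrom, and the strand-membership class."""

    res_i: int
    res_j: int
    distance: float
    contact_class: str


@dataclass(frozen=True)
class DistanceHistogram:
    """Fixed-width left-closed right-open binning from zero, per class and
    pooled."""

    bin_edges: np.ndarray
    counts: dict[str, np.ndarray]

    @property
    def pooled(self) -> np.ndarray:
        return sum(self.counts.values())


def hydrophobic_fraction(residues: list[Residue], params: ContactParams | None = None) -> float:
    """Fraction of residues in the configured hydrophobic set.

    Nonstandard residue names count as non-hydrophobic (with a warning).
    """
    import warnings

    p = params or ContactParams()
    if not residues:
        raise ValueError("no residues")
    n_hydro = 0
    for r in residues:
        if r.res_name not in _STANDARD_RESIDUES:
            warnings.warn(f"nonstandard residue {r.res_name} counted as non-hydrophobic")
        elif r.res_name in p.hydrophobic:
            n_hydro += 1
    return n_hydro / len(residues)


def residue_distance(r1: Residue, r2: Residue, metric: str = "sidechain_centroid") -> float:
    """Distance between two residues under the configured metric.

    ``sidechain_centroid``: centroid of heavy side-chain atoms (CA for
    glycine or when no side chain is resolved); ``cb``: CB-CB (CA for
    glycine); ``closest_heavy``: minimum heavy-atom distance.
    """

    def sidechain_centroid(r: Residue) -> np.ndarray:
        side = [
            a.coords
            for a in r.atoms
            if a.element != "H" and a.name not in ("N", "CA", "C", "O", "OXT")
        ]
        if side:
            return np.mean(side, axis=0)
        ca = r.atom("CA")
        if ca is None:
            raise ValueError(f"residue {r.label} has no side chain and no CA")
        return ca.coords

    def cb_or_ca(r: Residue) -> np.ndarray:
        for name in ("CB", "CA"):
            a = r.atom(name)
            if a is not None:
                return a.coords
        raise ValueError(f"residue {r.label} has neither CB nor CA")

    if metric == "sidechain_centroid":
        return float(np.linalg.norm(sidechain_centroid(r1) - sidechain_centroid(r2)))
    if metric == "cb":
        return float(np.linalg.norm(cb_or_ca(r1) - cb_or_ca(r2)))
    if metric == "closest_heavy":
        c1 = np.array([a.coords for a in r1.atoms if a.element != "H"])
        c2 = np.array([a.coords for a in r2.atoms if a.element != "H"])
        d = np.linalg.norm(c1[:, None, :] - c2[None, :, :], axis=-1)
        return float(d.min())
    raise ValueError(f"unknown contact metric {metric!r}")


def _strand_membership(motif: ThreeBetaCorner, seq_num: int) -> str | None:
    for name, sr in (("A", motif.strand_a), ("B", motif.strand_b), ("C", motif.strand_c)):
        if sr.start <= seq_num <= sr.end:
            return name
    return None


def classify_pair(motif: ThreeBetaCorner, seq_i: int, seq_j: int) -> str:
    """Contact class from strand membership alone: same strand ->
    inside-strand; two strands -> the strand pair; any loop residue ->
    other."""
    mi = _strand_membership(motif, seq_i)
    mj = _strand_membership(motif, seq_j)
    if mi is None or mj is None:
        return "other"
    if mi == mj:
        return "inside-strand"
    return "-".join(sorted((mi, mj)))


def hydrophobic_contacts(
    motif: ThreeBetaCorner,
    s: Structure,
    params: ContactParams | None = None,
    model: int = 0,
) -> list[ContactRecord]:
    """All hydrophobic residue pairs within the distance cutoff.

    Pairs are reported once, with i < j in sequence order; the class comes
    from strand membership only.
    """
    p = params or ContactParams()
    residues = [
        r
        for r in s.residues(chain=motif.chain, model=model)
        if motif.strand_a.start <= r.seq_num <= motif.strand_c.end
    ]
    hydro = [r for r in residues if r.res_name in p.hydrophobic]
    out = []
    for i in range(len(hydro)):
        for j in range(i + 1, len(hydro)):
            r1, r2 = hydro[i], hydro[j]
            d = residue_distance(r1, r2, p.metric)
            if d <= p.max_distance:
                out.append(
                    ContactRecord(
                        res_i=r1.seq_num,
                        res_j=r2.seq_num,
                        distance=d,
                        contact_class=classify_pair(motif, r1.seq_num, r2.seq_num),
                    )
                )
    return out


def contact_histogram(
    records: list[ContactRecord],
    bin_width: float | None = None,
    params: ContactParams | None = None,
    smooth_window: int = 3,
):
    """Histogram contact distances per class and find the pooled modes.

    Bins are fixed-width, left-closed right-open, starting at zero.  Modes
    are local maxima of the (moving-average smoothed) pooled counts;
    returns ``(histogram, mode_positions)`` with mode positions at bin
    centres, sorted by descending height.
    """
    p = params or ContactParams()
    width = p.bin_width if bin_width is None else bin_width
    if not records:
        return DistanceHistogram(bin_edges=np.array([0.0]), counts={}), []
    dmax = max(r.distance for r in records)
    n_bins = int(np.floor(dmax / width)) + 1
    edges = np.arange(n_bins + 1) * width
    counts = {c: np.zeros(n_bins, dtype=int) for c in CONTACT_CLASSES}
    for r in records:
        b = int(np.floor(r.distance / width))
        counts[r.contact_class][b] += 1
    pooled = sum(counts.values()).astype(float)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        smoothed = np.convolve(pooled, kernel, mode="same")
    else:
        smoothed = pooled
    modes = []
    for b in range(len(smoothed)):
        left = smoothed[b - 1] if b > 0 else -np.inf
        right = smoothed[b + 1] if b + 1 < len(smoothed) else -np.inf
        if smoothed[b] > left and smoothed[b] >= right and pooled[b] > 0:
            modes.append((smoothed[b], (edges[b] + edges[b + 1]) / 2.0))
    modes.sort(key=lambda t: -t[0])
    return DistanceHistogram(bin_edges=edges, counts=counts), [m for _h, m in modes]
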