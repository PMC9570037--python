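"""Per-structure stability metric battery.

Backbone RMSD under optimal (proper-rotation) superposition, radius of
gyration, Shrake-Rupley solvent-accessible surface area, geometric
hydrogen-bond counting, phi/psi torsions and Ramachandran region
classification, plus the delta metrics comparing an experimental structure
with the simulated (major-cluster) one:

    dSASA = SASA(exp) - SASA(sim)
    dRg   = Rg(exp)   - Rg(sim)
    dHB   = HB(exp)   - HB(sim)

Lengths are Angstrom internally; the gyration radius is conventionally
reported in nm at table boundaries (see :attr:`StabilityMetrics.rg_nm`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from . import config as cfg
from ._geom import angle, dihedral, rmsd_after_superposition, wrap_angle
from .structure_io import Structure

__all__ = [
    "StabilityMetrics",
    "DeltaMetrics",
    "TorsionPair",
    "RamaClass",
    "kabsch_rmsd",
    "radius_of_gyration",
    "sasa",
    "count_hbonds",
    "torsions",
    "residue_category",
    "rama_classify",
    "delta_metrics",
    "compute_metrics",
    "load_rama_polygons",
]

BACKBONE_SELECTION = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class StabilityMetrics:
    """One structure's metric battery: SASA (A^2), gyration radius (A),
    hydrogen-bond count and, when a reference exists, backbone RMSD (A)."""

    sasa: float
    rg: float
    n_hbonds: float
    rmsd_to_ref: float | None = None

    def __post_init__(self) -> None:
        if self.sasa < 0 or self.rg < 0:
            raise ValueError("sasa and rg must be non-negative")
        if self.rmsd_to_ref is not None and self.rmsd_to_ref < 0:
            raise ValueError("rmsd must be non-negative")

    @property
    def rg_nm(self) -> float:
        """Gyration radius in nm (the unit used in comparison tables)."""
        return self.rg / 10.0


@dataclass(frozen=True)
class DeltaMetrics:
    """Componentwise exp - sim differences of the metric battery."""

    d_sasa: float
    d_rg: float
    d_hb: float
    d_rg_fraction: float


@dataclass(frozen=True)
class TorsionPair:
    """phi/psi in degrees, each None when a chain terminus (or a missing
    neighbour backbone atom) leaves the dihedral undefined."""

    phi: float | None
    psi: float | None


@dataclass(frozen=True)
class RamaClass:
    category: str  # general | glycine | pre-proline | proline
    region: str  # allowed | disallowed | unclassified


# ---------------------------------------------------------------------------
# superposition RMSD
# ---------------------------------------------------------------------------


def _paired_coords(p, q, selection: str):
    """Resolve two inputs to matched coordinate arrays.

    Structures are paired atom-by-atom through (residue identity, atom name);
    bare arrays must already correspond row-by-row.
    """
    names = {
        "backbone": BACKBONE_SELECTION,
        "CA": ("CA",),
        "all": None,
    }[selection]

    def atom_map(s: Structure):
        out = {}
        for chain in s.chains():
            for res in s.residues(chain=chain):
                for a in res.atoms:
                    if names is None or a.name in names:
                        out[(chain, res.identity(), a.name)] = a.coords
        return out

    if isinstance(p, Structure) and isinstance(q, Structure):
        mp, mq = atom_map(p), atom_map(q)
        common = [k for k in mp if k in mq]
        missing = [k for k in mp if k not in mq] + [k for k in mq if k not in mp]
        if missing:
            raise ValueError(f"unpaired atoms between structures: {missing[:5]}...")
        return np.array([mp[k] for k in common]), np.array([mq[k] for k in common])
    pa, qa = np.asarray(p, dtype=float), np.asarray(q, dtype=float)
    if pa.shape != qa.shape:
        raise ValueError("coordinate sets must have identical shapes")
    return pa, qa


def kabsch_rmsd(p, q, selection: str = "backbone") -> float:
    """Least RMSD (Angstrom) of q onto p over proper rotations/translations.

    ``p`` and ``q`` may be Structures (paired by residue/atom identity) or
    plain (n, 3) arrays in row correspondence.
    """
    pa, qa = _paired_coords(p, q, selection)
    if pa.shape[0] < 3:
        raise ValueError("need at least 3 paired points")
    return rmsd_after_superposition(pa, qa)


# ---------------------------------------------------------------------------
# radius of gyration
# ---------------------------------------------------------------------------


def radius_of_gyration(s, weighting: str = "mass", model: int = 0) -> float:
    """sqrt(sum w_i |r_i - rbar|^2 / sum w_i) in Angstrom.

    Mass weighting (the molecular-dynamics convention) is the default;
    ``uniform`` weights every atom equally.
    """
    if isinstance(s, Structure):
        coords, weights = [], []
        for res in s.residues(model=model):
            for a in res.atoms:
                coords.append(a.coords)
                weights.append(cfg.ATOMIC_MASSES.get(a.element, 12.011))
        coords = np.array(coords)
        weights = np.array(weights)
    else:
        coords = np.asarray(s, dtype=float)
        weights = np.ones(len(coords))
    if coords.size == 0:
        raise ValueError("no atoms")
    if weighting == "uniform":
        weights = np.ones(len(coords))
    centre = np.average(coords, axis=0, weights=weights)
    msd = np.average(np.sum((coords - centre) ** 2, axis=1), weights=weights)
    return float(np.sqrt(msd))


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(
    s,
    probe_radius: float | None = None,
    n_sphere_points: int | None = None,
    params: cfg.SasaParams | None = None,
    model: int = 0,
    radii=None,
):
    """Shrake-Rupley SASA.  Returns ``(per_atom, total)`` in Angstrom^2.

    Each atom is inflated by the probe radius and sampled with a fixed
    quasi-uniform point set; a point is accessible when it lies outside every
    neighbouring inflated sphere.  Deterministic for a fixed point count.
    """
    params = params or cfg.SasaParams()
    probe = params.probe_radius if probe_radius is None else probe_radius
    npts = params.n_sphere_points if n_sphere_points is None else n_sphere_points

    if isinstance(s, Structure):
        coords, elements, names = [], [], []
        for res in s.residues(model=model):
            for a in res.atoms:
                if params.ignore_hydrogens and a.element == "H":
                    continue
                coords.append(a.coords)
                elements.append(a.element)
                names.append(f"{res.label}/{a.name}")
        coords = np.array(coords).reshape(-1, 3)
    else:
        coords = np.asarray(s, dtype=float)
        elements = ["C"] * len(coords)
        names = [str(i) for i in range(len(coords))]

    if radii is not None:
        radii = np.broadcast_to(np.asarray(radii, dtype=float), (len(coords),)).copy()
    else:
        radii = np.empty(len(coords))
        for i, el in enumerate(elements):
            if el not in cfg.VDW_RADII:
                raise ValueError(f"no van der Waals radius for atom {names[i]} (element {el!r})")
            radii[i] = cfg.VDW_RADII[el]

    sphere = _sphere_points(npts)
    inflated = radii + probe
    tree = cKDTree(coords)
    max_reach = 2.0 * inflated.max()
    per_atom = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + inflated[i] * sphere
        neighbours = [j for j in tree.query_ball_point(coords[i], inflated[i] + max_reach / 2.0) if j != i]
        accessible = np.ones(npts, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 >= (inflated[j] ** 2)
            if not accessible.any():
                break
        per_atom[i] = 4.0 * np.pi * inflated[i] ** 2 * accessible.mean()
    return per_atom, float(per_atom.sum())


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

#: Side-chain donor atoms (atom -> antecedent) and acceptor atoms per residue.
_SIDECHAIN_DONORS: dict[str, dict[str, str]] = {
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TYR": {"OH": "CZ"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "LYS": {"NZ": "CE"},
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "TRP": {"NE1": "CD1"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
}
_SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}


def count_hbonds(
    s: Structure, criterion: cfg.HBondCriterion | None = None, model: int = 0
):
    """Count unique donor-acceptor pairs satisfying the geometric criterion.

    Returns ``(count, pairs)`` where each pair is
    ``((donor_res_index, donor_atom), (acceptor_res_index, acceptor_atom))``.
    Heavy-atom mode (no explicit amide hydrogens) uses the
    donor...acceptor distance plus the acceptor-donor-antecedent angle;
    explicit hydrogens switch the donor to the D-H...A angle test.
    Trivially-contacting covalent neighbours — the same residue and the
    backbone N(i)...O(i-1) pair — are excluded.
    """
    criterion = criterion or cfg.HBondCriterion()
    residues = []
    res_keys = []  # (chain, seq_num) for covalent-adjacency exclusion
    for chain in s.chains(model):
        for res in s.residues(chain=chain, model=model):
            residues.append(res)
            res_keys.append((chain, res.seq_num))

    donors = []  # (res_idx, atom_name, coords, antecedent_coords, h_coords|None)
    acceptors = []  # (res_idx, atom_name, coords)
    for i, res in enumerate(residues):
        n = res.atom("N")
        if n is not None:
            if i > 0 and residues[i - 1].atom("C") is not None:
                ante = residues[i - 1].atom("C").coords
            elif res.atom("CA") is not None:
                ante = res.atom("CA").coords
            else:
                ante = None
            h = res.atom("H")
            if ante is not None:
                donors.append((i, "N", n.coords, ante, h.coords if h else None))
        for aname, ante_name in _SIDECHAIN_DONORS.get(res.res_name, {}).items():
            a = res.atom(aname)
            ante = res.atom(ante_name)
            if a is not None and ante is not None:
                donors.append((i, aname, a.coords, ante.coords, None))
        o = res.atom("O")
        if o is not None:
            acceptors.append((i, "O", o.coords))
        oxt = res.atom("OXT")
        if oxt is not None:
            acceptors.append((i, "OXT", oxt.coords))
        for aname in _SIDECHAIN_ACCEPTORS.get(res.res_name, ()):
            a = res.atom(aname)
            if a is not None:
                acceptors.append((i, aname, a.coords))

    pairs = []
    for di, dname, dpos, ante, hpos in donors:
        for ai, aname, apos in acceptors:
            if ai == di:
                continue
            if (
                dname == "N"
                and aname == "O"
                and res_keys[di][0] == res_keys[ai][0]
                and res_keys[di][1] - res_keys[ai][1] == 1
            ):
                continue  # covalently adjacent through the peptide bond
            if np.linalg.norm(dpos - apos) > criterion.da_cutoff:
                continue
            if hpos is not None:
                if angle(dpos, hpos, apos) < criterion.dha_min:
                    continue
            else:
                if angle(apos, dpos, ante) < criterion.antecedent_min:
                    continue
            pairs.append(((di, dname), (ai, aname)))
    return len(pairs), pairs


# ---------------------------------------------------------------------------
# torsions and Ramachandran classification
# ---------------------------------------------------------------------------


def torsions(s: Structure, chain: str | None = None, model: int = 0) -> list[TorsionPair]:
    """Backbone phi/psi per residue (degrees, IUPAC sign, wrapped to
    (-180, 180]).  Undefined at termini or where neighbour backbone atoms
    are missing."""
    residues = s.residues(chain=chain, model=model)
    out = []
    for i, res in enumerate(residues):
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        phi = psi = None
        if n and ca and c:
            if i > 0:
                c_prev = residues[i - 1].atom("C")
                if c_prev is not None:
                    phi = dihedral(c_prev.coords, n.coords, ca.coords, c.coords)
            if i + 1 < len(residues):
                n_next = residues[i + 1].atom("N")
                if n_next is not None:
                    psi = dihedral(n.coords, ca.coords, c.coords, n_next.coords)
        out.append(TorsionPair(phi=phi, psi=psi))
    return out


def residue_category(res_name: str, next_res_name: str | None = None) -> str:
    """Ramachandran category from residue identity and its successor."""
    if res_name == "GLY":
        return "glycine"
    if res_name == "PRO":
        return "proline"
    if next_res_name == "PRO":
        return "pre-proline"
    return "general"


_POLYGON_CACHE: dict[str, dict[str, np.ndarray]] | None = None


def load_rama_polygons() -> dict[str, dict[str, np.ndarray]]:
    """Load the allowed-region polygons shipped with the package
    (``data/rama_polygons.txt``; editable plain text)."""
    global _POLYGON_CACHE
    if _POLYGON_CACHE is None:
        polys: dict[str, dict[str, list]] = {}
        text = resources.files("betacorner").joinpath("data/rama_polygons.txt").read_text()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            category, name, phi, psi = line.split()
            polys.setdefault(category, {}).setdefault(name, []).append((float(phi), float(psi)))
        _POLYGON_CACHE = {
            cat: {name: np.array(v) for name, v in d.items()} for cat, d in polys.items()
        }
    return _POLYGON_CACHE


def _point_in_polygon(point: np.ndarray, polygon: np.ndarray) -> bool:
    """Even-odd rule point-in-polygon test."""
    x, y = point
    inside = False
    n = len(polygon)
    for i in range(n):
        x1, y1 = polygon[i]
        x2, y2 = polygon[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def rama_classify(
    t: TorsionPair, category: str = "general", regions=None
) -> RamaClass:
    """Classify a phi/psi pair as allowed/disallowed for its category.

    Angles are wrapped to (-180, 180] first, so classification is invariant
    under +/-360 degree shifts.  Undefined angles yield ``unclassified``.
    """
    if t.phi is None or t.psi is None:
        return RamaClass(category=category, region="unclassified")
    regions = regions or load_rama_polygons()
    if category not in regions:
        raise ValueError(f"unknown Ramachandran category {category!r}")
    pt = np.array([wrap_angle(t.phi), wrap_angle(t.psi)])
    for poly in regions[category].values():
        if _point_in_polygon(pt, poly):
            return RamaClass(category=category, region="allowed")
    return RamaClass(category=category, region="disallowed")


def classify_structure(s: Structure, chain: str | None = None, model: int = 0) -> list[RamaClass]:
    """Per-residue Ramachandran classes for a whole structure."""
    residues = s.residues(chain=chain, model=model)
    tors = torsions(s, chain=chain, model=model)
    out = []
    for i, (res, t) in enumerate(zip(residues, tors)):
        nxt = residues[i + 1].res_name if i + 1 < len(residues) else None
        out.append(rama_classify(t, residue_category(res.res_name, nxt)))
    return out


# ---------------------------------------------------------------------------
# deltas and convenience battery
# ---------------------------------------------------------------------------


def delta_metrics(exp: StabilityMetrics, md: StabilityMetrics) -> DeltaMetrics:
    """Componentwise exp - sim metric differences, plus the relative
    gyration-radius change used by the stability criterion."""
    d_rg = exp.rg - md.rg
    return DeltaMetrics(
        d_sasa=exp.sasa - md.sasa,
        d_rg=d_rg,
        d_hb=exp.n_hbonds - md.n_hbonds,
        d_rg_fraction=d_rg / exp.rg if exp.rg > 0 else 0.0,
    )


def compute_metrics(
    s: Structure,
    reference: Structure | None = None,
    model: int = 0,
    sasa_params: cfg.SasaParams | None = None,
    hbond_criterion: cfg.HBondCriterion | None = None,
) -> StabilityMetrics:
    """Run the full battery on one model of a structure."""
    _per_atom, total = sasa(s, params=sasa_params, model=model)
    rg = radius_of_gyration(s, model=model)
    nhb, _pairs = count_hbonds(s, criterion=hbond_criterion, model=model)
    rmsd = None
    if reference is not None:
        rmsd = kabsch_rmsd(reference, s if model == 0 else _model_view(s, model))
    return StabilityMetrics(sasa=total, rg=rg, n_hbonds=nhb, rmsd_to_ref=rmsd)


def _model_view(s: Structure, model: int) -> Structure:
    return Structure(id=s.id, models=[s.models[model]], source=s.source)
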