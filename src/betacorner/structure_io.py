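"""PDB-format structure I/O.

Reads and writes fixed-column PDB files (single structures and multi-model
conformer ensembles) into a small coordinate hierarchy that the rest of the
package operates on.  Parsing and serialisation are delegated to gemmi; this
module adds the author-numbering addressing scheme, alternate-location
resolution, model-consistency checks and region excision used downstream.

Addressing is always by author residue numbering with insertion codes, and
region selections are inclusive on both ends (``216-246`` means 31 residues).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "RegionSelector",
    "PDBParseError",
    "EmptyStructureError",
    "EmptySelectionError",
    "PDBFormatError",
    "parse_pdb",
    "extract_region",
    "write_pdb",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class PDBParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class EmptyStructureError(PDBParseError):
    """Raised when a file contains no usable ATOM records."""


class EmptySelectionError(ValueError):
    """Raised when a region selector matches no residues."""


class PDBFormatError(ValueError):
    """Raised when a structure cannot be encoded in fixed-column PDB."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    alt_loc: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class Residue:
    res_name: str
    seq_num: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def label(self) -> str:
        return f"{self.res_name}{self.seq_num}{self.icode}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_backbone(self) -> bool:
        """True when N, CA and C are all present."""
        names = {a.name for a in self.atoms}
        return {"N", "CA", "C"} <= names

    def identity(self) -> tuple[str, int, str]:
        return (self.res_name, self.seq_num, self.icode)


@dataclass
class Structure:
    """Parsed coordinates: an ordered list of models, each mapping chain id
    to an ordered residue list.  Multi-model files must agree on residue
    identity across models (conformer-ensemble semantics)."""

    id: str
    models: list[dict[str, list[Residue]]]
    source: str = "synthetic"

    @property
    def n_models(self) -> int:
        return len(self.models)

    def chains(self, model: int = 0) -> list[str]:
        return list(self.models[model].keys())

    def residues(self, chain: str | None = None, model: int = 0) -> list[Residue]:
        mod = self.models[model]
        if chain is not None:
            return mod[chain]
        out: list[Residue] = []
        for res_list in mod.values():
            out.extend(res_list)
        return out

    def n_atoms(self, model: int = 0) -> int:
        return sum(len(r.atoms) for r in self.residues(model=model))

    def coords(
        self,
        model: int = 0,
        chain: str | None = None,
        atom_names: tuple[str, ...] | None = None,
    ) -> np.ndarray:
        """Stacked coordinates, optionally restricted to named atoms."""
        rows = []
        for res in self.residues(chain=chain, model=model):
            for a in res.atoms:
                if atom_names is None or a.name in atom_names:
                    rows.append(a.coords)
        return np.array(rows, dtype=float).reshape(-1, 3)

    def _validate_models(self) -> None:
        if not self.models:
            raise ValueError("structure must have at least one model")
        ref = [
            (ch, res.identity())
            for ch, res_list in self.models[0].items()
            for res in res_list
        ]
        for i, mod in enumerate(self.models[1:], start=2):
            ids = [
                (ch, res.identity()) for ch, res_list in mod.items() for res in res_list
            ]
            if ids != ref:
                raise PDBParseError(
                    f"model {i} residue identities differ from model 1"
                )


@dataclass(frozen=True)
class RegionSelector:
    """Inclusive author-numbered residue range on one chain."""

    chain: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("selector start must not exceed end")


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: the highest-occupancy alternate location,
    ties broken in favour of altloc 'A' (then lexicographic)."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occupancy, a.alt_loc or "A"))
        best.alt_loc = ""
        out.append(best)
    return out


def parse_pdb(path: str | Path, keep_hetero: bool = False) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    All models are read; author numbering and insertion codes are preserved.
    HETATM records and waters are dropped unless ``keep_hetero`` is set.
    Alternate locations are collapsed to the highest-occupancy conformer.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc

    models: list[dict[str, list[Residue]]] = []
    for model in st:
        chains: dict[str, list[Residue]] = {}
        for chain in model:
            res_list: list[Residue] = []
            for res in chain:
                if not keep_hetero and (res.is_water() or res.het_flag == "H"):
                    continue
                atoms = [
                    Atom(
                        serial=a.serial,
                        name=a.name,
                        element=a.element.name.upper(),
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        alt_loc=a.altloc.strip("\x00") if a.altloc else "",
                        occupancy=a.occ,
                        b_factor=a.b_iso,
                    )
                    for a in res
                ]
                atoms = _resolve_altlocs(atoms)
                if atoms:
                    res_list.append(
                        Residue(
                            res_name=res.name,
                            seq_num=res.seqid.num,
                            icode=res.seqid.icode.strip(),
                            atoms=atoms,
                        )
                    )
            if res_list:
                chains[chain.name] = res_list
        if chains:
            models.append(chains)

    if not models:
        raise EmptyStructureError(f"{path} contains no ATOM records")
    structure = Structure(id=path.stem, models=models, source=str(path))
    structure._validate_models()
    return structure


def extract_region(s: Structure, sel: RegionSelector) -> Structure:
    """Excise the selected region (all models) into a standalone structure.

    Residue numbering and insertion codes are retained, so the fragment keeps
    its author addressing (the convention used when corner motifs are cut out
    of their parent protein).
    """
    if sel.chain not in s.models[0]:
        raise EmptySelectionError(
            f"chain {sel.chain!r} not in structure (chains: {s.chains()})"
        )
    models: list[dict[str, list[Residue]]] = []
    for mod in s.models:
        picked = [
            copy.deepcopy(r)
            for r in mod[sel.chain]
            if sel.start <= r.seq_num <= sel.end
        ]
        models.append({sel.chain: picked})
    if not models[0][sel.chain]:
        nums = [r.seq_num for r in s.models[0][sel.chain]]
        raise EmptySelectionError(
            f"selection {sel.start}-{sel.end} matches no residues on chain "
            f"{sel.chain} (available range {min(nums)}-{max(nums)})"
        )
    return Structure(
        id=f"{s.id}_{sel.chain}{sel.start}-{sel.end}",
        models=models,
        source=s.source,
    )


def _to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.id
    for i, mod in enumerate(s.models, start=1):
        gmod = gemmi.Model(i)
        for chain_id, res_list in mod.items():
            gchain = gemmi.Chain(chain_id)
            for res in res_list:
                if res.seq_num > 9999 or res.seq_num < -999:
                    raise PDBFormatError(
                        f"residue number {res.seq_num} exceeds PDB field width"
                    )
                gres = gemmi.Residue()
                gres.name = res.res_name
                gres.seqid = gemmi.SeqId(res.seq_num, res.icode or " ")
                gres.het_flag = "A"
                for atom in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element.capitalize())
                    ga.pos = gemmi.Position(*atom.coords)
                    ga.occ = atom.occupancy
                    ga.b_iso = atom.b_factor
                    gres.add_atom(ga)
                gchain.add_residue(gres)
            gmod.add_chain(gchain)
        st.add_model(gmod)
    st.setup_entities()
    return st


def write_pdb(s: Structure, path: str | Path) -> Path:
    """Write a structure as a fixed-column PDB file.

    MODEL/ENDMDL blocks are emitted exactly when the structure has more than
    one model.  The output is reparseable by :func:`parse_pdb` with identical
    atom names, numbering and coordinates (to PDB's 3-decimal precision).
    """
    if not s.models or s.n_atoms() == 0:
        raise ValueError("cannot write an empty structure")
    path = Path(path)
    st = _to_gemmi(s)
    opts = gemmi.PdbWriteOptions(minimal=True)
    st.write_pdb(str(path), opts)
    return path
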