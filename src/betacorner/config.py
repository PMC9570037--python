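"""Default parameter sets for the analysis battery.

Everything a user might reasonably tune lives here as a frozen-by-default
dataclass; modules take these objects as optional arguments so the defaults
are visible, documented, and overridable in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Bondi-type van der Waals radii (Angstrom), heavy-atom convention.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

#: Atomic masses (unified amu) for mass-weighted radius of gyration.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
}

#: Residues counted as hydrophobic in contact analysis.  Proline is excluded
#: by default: its cyclic side chain plays a special conformational role and
#: is treated separately throughout the torsion analysis.
HYDROPHOBIC_RESIDUES: frozenset[str] = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "CYS"}
)


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond definition.

    With explicit hydrogens: donor-acceptor distance <= ``da_cutoff`` and
    D-H...A angle >= ``dha_min``.  Without hydrogens (the common case for
    crystal structures) the heavy-atom fallback is used: D...A distance
    <= ``da_cutoff`` and angle(acceptor, donor, donor-antecedent) >=
    ``antecedent_min``.
    """

    da_cutoff: float = 3.5  # Angstrom
    dha_min: float = 150.0  # degrees
    antecedent_min: float = 90.0  # degrees


@dataclass(frozen=True)
class SasaParams:
    """Shrake-Rupley solvent-accessible surface area parameters."""

    probe_radius: float = 1.4  # Angstrom, water probe
    n_sphere_points: int = 960
    ignore_hydrogens: bool = True


@dataclass(frozen=True)
class TorsionSSBoxes:
    """phi/psi boxes for the torsion-based secondary-structure assigner.

    The beta box has a wrap-around tail (psi in [-180, -170]) because the
    extended region crosses the psi = 180 seam.
    """

    beta_phi: tuple[float, float] = (-180.0, -45.0)
    beta_psi: tuple[float, float] = (45.0, 180.0)
    beta_psi_wrap: tuple[float, float] = (-180.0, -170.0)
    alpha_phi: tuple[float, float] = (-100.0, -30.0)
    alpha_psi: tuple[float, float] = (-80.0, -5.0)


@dataclass(frozen=True)
class MotifWindows:
    """Length and geometry acceptance windows for the 3beta-corner detector.

    Strands of 4-10 residues and loops of 3-12 residues, with a total motif
    span of 25-55 residues, reflect the length statistics of corners found
    in beta-barrel proteins.  The geometric windows encode "roughly
    orthogonal" hairpin packing and the ~90 degree central-strand bend; both
    are deliberately wide since the motif definition is qualitative, and are
    flagged as sensitivity parameters.
    """

    strand_min: int = 4
    strand_max: int = 10
    loop_min: int = 3
    loop_max: int = 12
    total_min: int = 25
    total_max: int = 55
    interplanar_window: tuple[float, float] = (55.0, 125.0)
    bend_window: tuple[float, float] = (50.0, 130.0)
    require_right_handed: bool = True


@dataclass(frozen=True)
class ClusterParams:
    """Adaptive conformer-clustering schedule.

    Start from ``initial_cutoff`` (nm), raise by ``step`` while the partition
    has more than ``max_clusters`` clusters, lower while it has fewer than
    ``min_clusters``, and give up after ``max_attempts`` attempts.
    """

    initial_cutoff: float = 0.3  # nm
    step: float = 0.01  # nm
    min_clusters: int = 8
    max_clusters: int = 12
    max_attempts: int = 30

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.min_clusters > self.max_clusters:
            raise ValueError("min_clusters must not exceed max_clusters")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


@dataclass(frozen=True)
class StabilityThresholds:
    """Stability verdict thresholds: mean backbone RMSD below ``rmsd_max``
    (Angstrom), relative gyration-radius change within ``rg_fraction_max``,
    and retention of allowed Ramachandran positions."""

    rmsd_max: float = 5.0  # Angstrom
    rg_fraction_max: float = 0.05
    major_cluster_occupancy: float = 0.8


@dataclass(frozen=True)
class ContactParams:
    """Hydrophobic contact extraction parameters.

    ``metric`` selects how a residue-pair distance is measured:
    ``sidechain_centroid`` (heavy side-chain atoms, CA for glycine),
    ``cb`` (CB-CB, CA for glycine) or ``closest_heavy``.
    """

    metric: str = "sidechain_centroid"
    max_distance: float = 12.0  # Angstrom
    bin_width: float = 0.2  # Angstrom
    hydrophobic: frozenset[str] = field(default_factory=lambda: HYDROPHOBIC_RESIDUES)
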