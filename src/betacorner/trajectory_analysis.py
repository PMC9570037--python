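"""Conformer-ensemble (trajectory surrogate) analysis.

Multi-model coordinate sets stand in for molecular-dynamics trajectories.
The module provides:

* GROMOS-style neighbour-counting clustering of frames by pairwise backbone
  RMSD under a distance cutoff;
* the adaptive-cutoff schedule: start at 0.3 nm, raise by 0.01 nm while the
  partition has more than 12 clusters, lower while it has fewer than 8, for
  at most 30 attempts;
* the major-cluster rule: the dominant conformer must occupy at least 80%
  of the frames for the ensemble to have a well-defined representative;
* per-frame RMSD series and replicate aggregation (mean +/- sample SD);
* metric averaging over the major cluster's frames only; and
* the stability verdict: mean backbone RMSD < 5 A, gyration-radius change
  within 5%, and retention of allowed Ramachandran positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import config as cfg
from ._geom import pairwise_rmsd_matrix, rmsd_after_superposition
from .geometry_metrics import (
    BACKBONE_SELECTION,
    RamaClass,
    StabilityMetrics,
    count_hbonds,
    radius_of_gyration,
    sasa,
)
from .structure_io import Structure

__all__ = [
    "Ensemble",
    "ClusterResult",
    "MajorCluster",
    "StabilityVerdict",
    "gromos_cluster",
    "adaptive_cluster",
    "major_cluster",
    "rmsd_series",
    "aggregate_replicates",
    "metrics_on_major",
    "stability_verdict",
]


@dataclass
class Ensemble:
    """An ordered stack of conformer frames sharing one atom selection.

    ``structure`` holds the frames as models; ``frame_coords`` caches the
    selected coordinates with shape (n_frames, n_atoms, 3).
    """

    structure: Structure
    selection: tuple[str, ...] = BACKBONE_SELECTION
    frame_times: np.ndarray | None = None
    frame_coords: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.structure.n_models < 2:
            raise ValueError("an ensemble needs at least 2 frames")
        frames = [
            self.structure.coords(model=m, atom_names=self.selection)
            for m in range(self.structure.n_models)
        ]
        counts = {f.shape[0] for f in frames}
        if len(counts) != 1:
            raise ValueError("frames differ in selected atom count")
        self.frame_coords = np.stack(frames)

    @property
    def n_frames(self) -> int:
        return self.frame_coords.shape[0]

    def frame_structure(self, index: int) -> Structure:
        """A single frame as a standalone one-model structure."""
        return Structure(
            id=f"{self.structure.id}_f{index}",
            models=[self.structure.models[index]],
            source=self.structure.source,
        )


@dataclass(frozen=True)
class ClusterResult:
    """A frame partition: clusters ordered by decreasing size, one
    representative (centre) frame per cluster, and the cutoff that produced
    it.  ``converged`` is False when the adaptive schedule exhausted its
    attempts without landing in the target cluster-count band."""

    clusters: tuple[tuple[int, ...], ...]
    centers: tuple[int, ...]
    final_cutoff: float  # nm
    attempts: int
    converged: bool = True

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


@dataclass(frozen=True)
class MajorCluster:
    cluster_index: int
    occupancy: float
    representative: int
    is_major: bool


@dataclass(frozen=True)
class StabilityVerdict:
    """The three-criterion stability call.

    ``stable`` is True iff the mean RMSD is below the threshold, the
    relative gyration-radius change is within the allowed fraction, and
    every residue allowed on the Ramachandran map in the experimental
    structure remains allowed in the simulated one."""

    mean_rmsd: float
    rg_change_fraction: float
    rama_retained: bool
    stable: bool
    rmsd_max: float = 5.0
    rg_fraction_max: float = 0.05


def gromos_cluster(e: Ensemble, cutoff_nm: float) -> ClusterResult:
    """GROMOS neighbour-counting clustering.

    The frame with the most neighbours within the cutoff becomes a cluster
    centre; it and its neighbours are removed, and the procedure repeats on
    the remainder until no frames are left.  Ties in neighbour count are
    broken by the lowest frame index, which makes the partition
    deterministic.
    """
    cutoff = cutoff_nm * 10.0  # nm -> Angstrom
    dmat = pairwise_rmsd_matrix(e.frame_coords)
    n = e.n_frames
    alive = np.ones(n, dtype=bool)
    within = dmat <= cutoff
    clusters: list[tuple[int, ...]] = []
    centers: list[int] = []
    while alive.any():
        counts = (within & alive).sum(axis=1)
        counts[~alive] = -1
        centre = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.where(within[centre] & alive)[0]
        clusters.append(tuple(int(m) for m in members))
        centers.append(centre)
        alive[members] = False
    order = sorted(range(len(clusters)), key=lambda i: (-len(clusters[i]), clusters[i][0]))
    return ClusterResult(
        clusters=tuple(clusters[i] for i in order),
        centers=tuple(centers[i] for i in order),
        final_cutoff=cutoff_nm,
        attempts=1,
    )


def adaptive_cluster(e: Ensemble, params: cfg.ClusterParams | None = None) -> ClusterResult:
    """Adaptive-cutoff clustering schedule.

    Raise the cutoff one step while the partition is too fine (> max
    clusters), lower it while too coarse (< min clusters), and accept as
    soon as the cluster count lands in [min, max].  On exhausting the
    attempt budget the attempt closest to the band is returned (ties in
    favour of fewer clusters) flagged as non-converged; the schedule also
    stops if the cutoff would drop to zero.
    """
    p = params or cfg.ClusterParams()
    cutoff = p.initial_cutoff
    tried: list[tuple[int, ClusterResult]] = []
    attempts = 0
    while attempts < p.max_attempts:
        attempts += 1
        result = gromos_cluster(e, cutoff)
        k = result.n_clusters
        if p.min_clusters <= k <= p.max_clusters:
            return ClusterResult(
                clusters=result.clusters,
                centers=result.centers,
                final_cutoff=cutoff,
                attempts=attempts,
                converged=True,
            )
        dist = (p.min_clusters - k) if k < p.min_clusters else (k - p.max_clusters)
        tried.append((dist, result))
        if k > p.max_clusters:
            cutoff += p.step
        else:
            cutoff -= p.step
            if cutoff <= 0:
                break
    dist, best = min(tried, key=lambda t: (t[0], t[1].n_clusters))
    return ClusterResult(
        clusters=best.clusters,
        centers=best.centers,
        final_cutoff=best.final_cutoff,
        attempts=attempts,
        converged=False,
    )


def major_cluster(c: ClusterResult, threshold: float = 0.8) -> MajorCluster:
    """The largest cluster with its frame occupancy and the >= 80% rule."""
    if not c.clusters:
        raise ValueError("empty cluster result")
    total = sum(len(cl) for cl in c.clusters)
    occ = len(c.clusters[0]) / total
    return MajorCluster(
        cluster_index=0,
        occupancy=occ,
        representative=c.centers[0],
        is_major=occ >= threshold,
    )


def rmsd_series(e: Ensemble, ref: Structure, selection: tuple[str, ...] | None = None):
    """Per-frame superposed RMSD to a reference structure.

    Returns ``(series, mean, sd)`` in Angstrom; the SD is the sample
    standard deviation over frames.
    """
    selection = selection or e.selection
    ref_coords = ref.coords(model=0, atom_names=selection)
    if ref_coords.shape != e.frame_coords.shape[1:]:
        raise ValueError(
            f"reference selection has {ref_coords.shape[0]} atoms, "
            f"frames have {e.frame_coords.shape[1]}"
        )
    series = np.array(
        [rmsd_after_superposition(ref_coords, f) for f in e.frame_coords]
    )
    sd = float(series.std(ddof=1)) if len(series) > 1 else 0.0
    return series, float(series.mean()), sd


def aggregate_replicates(replicate_means: list[float]):
    """Mean +/- sample SD across replicate trajectory means."""
    arr = np.asarray(replicate_means, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd


def metrics_on_major(
    e: Ensemble,
    major: MajorCluster,
    cluster_result: ClusterResult,
    sasa_params: cfg.SasaParams | None = None,
    hbond_criterion: cfg.HBondCriterion | None = None,
) -> StabilityMetrics:
    """SASA / Rg / H-bond count averaged over the major cluster's frames.

    When the largest cluster fails the occupancy rule the average is still
    computed over it (the caller sees ``major.is_major`` and can flag the
    result).
    """
    frames = cluster_result.clusters[major.cluster_index]
    sasas, rgs, hbs = [], [], []
    for f in frames:
        fs = e.frame_structure(f)
        sasas.append(sasa(fs, params=sasa_params)[1])
        rgs.append(radius_of_gyration(fs))
        hbs.append(count_hbonds(fs, criterion=hbond_criterion)[0])
    return StabilityMetrics(
        sasa=float(np.mean(sasas)),
        rg=float(np.mean(rgs)),
        n_hbonds=float(np.mean(hbs)),
    )


def mean_structure(e: Ensemble, frame_indices) -> Structure:
    """Coordinate-average of a set of frames as a standalone structure.

    Used for torsion/Ramachandran analysis of a cluster: averaging over the
    cluster's frames suppresses frame-level coordinate noise that would
    scramble individual dihedrals.
    """
    import copy as _copy

    frames = list(frame_indices)
    if not frames:
        raise ValueError("no frames to average")
    template = _copy.deepcopy(e.structure.models[frames[0]])
    stacks = [e.structure.coords(model=f) for f in frames]
    mean = np.mean(stacks, axis=0)
    k = 0
    for res_list in template.values():
        for res in res_list:
            for atom in res.atoms:
                atom.coords = mean[k]
                k += 1
    return Structure(id=f"{e.structure.id}_mean", models=[template], source=e.structure.source)


def rama_retained(exp_classes: list[RamaClass], md_classes: list[RamaClass]) -> bool:
    """True when every residue allowed in the experimental structure is
    still allowed in the simulated one."""
    if len(exp_classes) != len(md_classes):
        raise ValueError("class vectors differ in length")
    for ec, mc in zip(exp_classes, md_classes):
        if ec.region == "allowed" and mc.region == "disallowed":
            return False
    return True


def stability_verdict(
    exp: StabilityMetrics,
    mean_rmsd: float,
    md: StabilityMetrics,
    exp_rama: list[RamaClass] | None = None,
    md_rama: list[RamaClass] | None = None,
    thresholds: cfg.StabilityThresholds | None = None,
) -> StabilityVerdict:
    """Combine the three stability criteria into a verdict.

    ``mean_rmsd`` is the (replicate-averaged) mean backbone RMSD in
    Angstrom.  When Ramachandran vectors are omitted the retention criterion
    is vacuously satisfied.
    """
    t = thresholds or cfg.StabilityThresholds()
    if exp.rg <= 0:
        raise ValueError("experimental Rg must be positive")
    frac = (exp.rg - md.rg) / exp.rg
    retained = True
    if exp_rama is not None and md_rama is not None:
        retained = rama_retained(exp_rama, md_rama)
    stable = (
        mean_rmsd < t.rmsd_max and abs(frac) <= t.rg_fraction_max and retained
    )
    return StabilityVerdict(
        mean_rmsd=float(mean_rmsd),
        rg_change_fraction=float(frac),
        rama_retained=retained,
        stable=stable,
        rmsd_max=t.rmsd_max,
        rg_fraction_max=t.rg_fraction_max,
    )
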