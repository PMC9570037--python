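"""End-to-end orchestration: detect -> excise -> metrics -> cluster ->
contacts -> verdict.

The pipeline is a thin, file-oriented layer over the library modules: every
number it reports is produced by a public module function, and a run is
fully described by its :class:`RunConfig`, which is serialised (JSON) next
to the outputs so re-running the written config reproduces the reports
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import config as cfg
from ._geom import wrap_angle
from .contact_analysis import contact_histogram, hydrophobic_contacts, hydrophobic_fraction
from .geometry_metrics import (
    RamaClass,
    StabilityMetrics,
    classify_structure,
    compute_metrics,
    delta_metrics,
    rama_classify,
    residue_category,
    torsions,
)
from .motif_detection import ThreeBetaCorner, find_3b_corners
from .structure_io import RegionSelector, Structure, extract_region, parse_pdb
from .trajectory_analysis import (
    Ensemble,
    adaptive_cluster,
    aggregate_replicates,
    major_cluster,
    mean_structure,
    metrics_on_major,
    rmsd_series,
    stability_verdict,
)

__all__ = ["RunConfig", "StructureReport", "run_detect", "run_analyze", "run_contacts", "analyze_structure"]

log = logging.getLogger("betacorner")


@dataclass
class RunConfig:
    """Plain-text (JSON) serialisable description of a pipeline run."""

    inputs: list[str] = field(default_factory=list)
    output_dir: str = "betacorner_out"
    region: dict | None = None  # {"chain": ..., "start": ..., "end": ...} or None for auto-detect
    replicates: dict[str, list[str]] = field(default_factory=dict)
    assigner: str = "torsion"
    seed: int = 17
    contact_metric: str = "sidechain_centroid"
    contact_max_distance: float = 12.0
    contact_bin_width: float = 0.2
    cluster_initial_cutoff: float = 0.3
    cluster_step: float = 0.01
    cluster_min: int = 8
    cluster_max: int = 12
    cluster_attempts: int = 30
    major_threshold: float = 0.8
    rmsd_max: float = 5.0
    rg_fraction_max: float = 0.05
    sasa_sphere_points: int = 960

    def cluster_params(self) -> cfg.ClusterParams:
        return cfg.ClusterParams(
            initial_cutoff=self.cluster_initial_cutoff,
            step=self.cluster_step,
            min_clusters=self.cluster_min,
            max_clusters=self.cluster_max,
            max_attempts=self.cluster_attempts,
        )

    def contact_params(self) -> cfg.ContactParams:
        return cfg.ContactParams(
            metric=self.contact_metric,
            max_distance=self.contact_max_distance,
            bin_width=self.contact_bin_width,
        )

    def thresholds(self) -> cfg.StabilityThresholds:
        return cfg.StabilityThresholds(
            rmsd_max=self.rmsd_max,
            rg_fraction_max=self.rg_fraction_max,
            major_cluster_occupancy=self.major_threshold,
        )

    def sasa_params(self) -> cfg.SasaParams:
        return cfg.SasaParams(n_sphere_points=self.sasa_sphere_points)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class StructureReport:
    """Everything the analysis produced for one structure."""

    structure_id: str
    motif: ThreeBetaCorner | None
    exp_metrics: StabilityMetrics
    md_metrics: StabilityMetrics | None
    md_sd: dict[str, float]
    mean_rmsd: float | None
    rmsd_sd: float | None
    deltas: dict[str, float]
    rama_allowed_exp: int
    rama_allowed_md: int | None
    n_replicates: int
    verdict: dict | None


def _prepare_outdir(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "resolved_config.json")
    return out


def _motif_region(motif: ThreeBetaCorner) -> RegionSelector:
    return RegionSelector(chain=motif.chain, start=motif.strand_a.start, end=motif.strand_c.end)


def run_detect(config: RunConfig) -> pd.DataFrame:
    """Scan the configured inputs for corner motifs; write a motif table and
    a rejection log.  Unreadable inputs are reported and skipped."""
    out = _prepare_outdir(config)
    rows, rej_rows = [], []
    for path in config.inputs:
        try:
            s = parse_pdb(path)
        except Exception as exc:  # noqa: BLE001 - per-file error, run continues
            log.error("detect: cannot read %s: %s", path, exc)
            rej_rows.append({"structure": str(path), "chain": "", "reason": f"unreadable: {exc}"})
            continue
        found, rejected = find_3b_corners(s, assigner=config.assigner, return_rejections=True)
        for m in found:
            rows.append(
                {
                    "structure": s.id,
                    "chain": m.chain,
                    "strand_a": f"{m.strand_a.start}-{m.strand_a.end}",
                    "strand_b": f"{m.strand_b.start}-{m.strand_b.end}",
                    "strand_c": f"{m.strand_c.start}-{m.strand_c.end}",
                    "loop_ab_len": m.loop_ab[1] - m.loop_ab[0] + 1,
                    "loop_bc_len": m.loop_bc[1] - m.loop_bc[0] + 1,
                    "interplanar_deg": round(m.interplanar_angle, 2),
                    "bend_deg": round(m.bend_angle, 2),
                    "handedness": m.handedness,
                    "total_length": m.total_length,
                }
            )
        for r in rejected:
            rej_rows.append({"structure": s.id, "chain": r.chain, "reason": r.reason})
    columns = [
        "structure", "chain", "strand_a", "strand_b", "strand_c", "loop_ab_len",
        "loop_bc_len", "interplanar_deg", "bend_deg", "handedness", "total_length",
    ]
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(out / "motifs.tsv", sep="\t", index=False)
    pd.DataFrame(rej_rows, columns=["structure", "chain", "reason"]).to_csv(
        out / "rejections.tsv", sep="\t", index=False
    )
    return df


#: Minimum angular slack (degrees) for the Ramachandran retention check: a
#: residue whose torsions moved less than this from the reference is not
#: counted as having left its region even if it crossed a polygon edge —
#: region boundaries are configuration, and hair-width crossings are
#: classification noise rather than conformational change.  When an
#: ensemble is available the slack per residue is the larger of this floor
#: and 3 standard errors of the cluster-frame torsion mean.
RAMA_MARGIN_DEG = 10.0


def _torsion_sem(ensemble: Ensemble, frames) -> np.ndarray | None:
    """Per-residue standard error (degrees) of the mean phi/psi over a set
    of frames, via the circular standard deviation."""
    frames = list(frames)
    if len(frames) < 3:
        return None
    per_frame = [torsions(ensemble.frame_structure(f)) for f in frames]
    n_res = len(per_frame[0])
    sems = np.zeros(n_res)
    for i in range(n_res):
        worst = 0.0
        for pick in (lambda t: t.phi, lambda t: t.psi):
            vals = [pick(t[i]) for t in per_frame]
            if any(v is None for v in vals):
                continue
            rad = np.radians(vals)
            r = abs(np.mean(np.exp(1j * rad)))
            circ_sd = np.sqrt(max(-2.0 * np.log(max(r, 1e-12)), 0.0))
            worst = max(worst, np.degrees(circ_sd) / np.sqrt(len(frames)))
        sems[i] = worst
    return sems


def _rama_with_margin(
    reference: Structure, simulated: Structure, sem: np.ndarray | None = None
) -> list[RamaClass]:
    """Ramachandran classes of the simulated structure, treating residues
    whose torsions stayed within the noise margin of the reference as
    retaining the reference class."""
    ref_tors = torsions(reference)
    sim_tors = torsions(simulated)
    residues = reference.residues()
    out = []
    for i, (rt, st) in enumerate(zip(ref_tors, sim_tors)):
        nxt = residues[i + 1].res_name if i + 1 < len(residues) else None
        cat = residue_category(residues[i].res_name, nxt)
        cls = rama_classify(st, cat)
        if cls.region == "disallowed" and rt.phi is not None and st.phi is not None:
            margin = RAMA_MARGIN_DEG
            if sem is not None:
                margin = max(margin, 3.0 * float(sem[i]))
            moved = max(
                abs(wrap_angle(rt.phi - st.phi)), abs(wrap_angle(rt.psi - st.psi))
            )
            if moved <= margin:
                out.append(rama_classify(rt, cat))
                continue
        out.append(cls)
    return out


def analyze_structure(
    s: Structure,
    ensembles: list[Structure],
    config: RunConfig | None = None,
    motif: ThreeBetaCorner | None = None,
) -> StructureReport:
    """Full stability battery for one structure and its replicate ensembles.

    The experimental (reference) metrics come from the input structure; each
    replicate ensemble is clustered with the adaptive schedule, metrics are
    averaged over the major cluster's frames, and replicates are aggregated
    as mean +/- sample SD before the verdict is rendered.
    """
    config = config or RunConfig()
    if motif is None:
        motifs = find_3b_corners(s, assigner=config.assigner)
        motif = motifs[0] if motifs else None
    if motif is not None:
        region = extract_region(s, _motif_region(motif))
    else:
        region = s

    sasa_params = config.sasa_params()
    exp_metrics = compute_metrics(region, sasa_params=sasa_params)
    exp_rama = classify_structure(region)
    rama_exp_allowed = sum(1 for c in exp_rama if c.region == "allowed")

    if not ensembles:
        return StructureReport(
            structure_id=s.id,
            motif=motif,
            exp_metrics=exp_metrics,
            md_metrics=None,
            md_sd={},
            mean_rmsd=None,
            rmsd_sd=None,
            deltas={},
            rama_allowed_exp=rama_exp_allowed,
            rama_allowed_md=None,
            n_replicates=0,
            verdict=None,
        )

    rep_rmsd, rep_sasa, rep_rg, rep_hb = [], [], [], []
    md_rama_all = []
    rep_frames = []
    for ens_structure in ensembles:
        ens = Ensemble(ens_structure)
        cres = adaptive_cluster(ens, config.cluster_params())
        major = major_cluster(cres, threshold=config.major_threshold)
        md = metrics_on_major(ens, major, cres, sasa_params=sasa_params)
        _series, mean_r, _sd = rmsd_series(ens, region)
        rep_rmsd.append(mean_r)
        rep_sasa.append(md.sasa)
        rep_rg.append(md.rg)
        rep_hb.append(md.n_hbonds)
        rep_frames.append(ens.frame_structure(major.representative))
        # dihedrals are read off the major cluster's mean coordinates so
        # frame-level noise does not masquerade as conformational change
        major_frames = cres.clusters[major.cluster_index]
        md_rama_all.append(
            _rama_with_margin(
                region,
                mean_structure(ens, major_frames),
                sem=_torsion_sem(ens, major_frames),
            )
        )

    mean_rmsd, rmsd_sd = aggregate_replicates(rep_rmsd)
    sasa_m, sasa_sd = aggregate_replicates(rep_sasa)
    rg_m, rg_sd = aggregate_replicates(rep_rg)
    hb_m, hb_sd = aggregate_replicates(rep_hb)
    md_metrics = StabilityMetrics(sasa=sasa_m, rg=rg_m, n_hbonds=hb_m)
    # a residue retains its Ramachandran position when it stays allowed in
    # every replicate's major-cluster representative
    md_rama = [
        min((rep[i] for rep in md_rama_all), key=lambda c: c.region == "allowed")
        for i in range(len(exp_rama))
    ]
    rama_md_allowed = sum(1 for c in md_rama if c.region == "allowed")

    deltas = delta_metrics(exp_metrics, md_metrics)
    verdict = stability_verdict(
        exp_metrics, mean_rmsd, md_metrics, exp_rama, md_rama, thresholds=config.thresholds()
    )
    return StructureReport(
        structure_id=s.id,
        motif=motif,
        exp_metrics=exp_metrics,
        md_metrics=md_metrics,
        md_sd={"sasa": sasa_sd, "rg": rg_sd, "n_hbonds": hb_sd},
        mean_rmsd=mean_rmsd,
        rmsd_sd=rmsd_sd,
        deltas={
            "d_sasa": deltas.d_sasa,
            "d_rg": deltas.d_rg,
            "d_hb": deltas.d_hb,
            "d_rg_fraction": deltas.d_rg_fraction,
        },
        rama_allowed_exp=rama_exp_allowed,
        rama_allowed_md=rama_md_allowed,
        n_replicates=len(ensembles),
        verdict={
            "mean_rmsd": verdict.mean_rmsd,
            "rg_change_fraction": verdict.rg_change_fraction,
            "rama_retained": verdict.rama_retained,
            "stable": verdict.stable,
        },
    )


def _report_rows(rep: StructureReport):
    """Two comparison-table rows (reference structure and simulated major
    cluster) in the conventional SASA / Rg / H-bond / RMSD layout."""
    rows = [
        {
            "structure": rep.structure_id,
            "row": "reference",
            "sasa_A2": round(rep.exp_metrics.sasa, 2),
            "sasa_sd": "",
            "rg_nm": round(rep.exp_metrics.rg_nm, 3),
            "rg_sd": "",
            "hbonds": rep.exp_metrics.n_hbonds,
            "hbonds_sd": "",
            "rmsd_A": "",
            "rmsd_sd": "",
        }
    ]
    if rep.md_metrics is not None:
        rows.append(
            {
                "structure": rep.structure_id,
                "row": "simulated",
                "sasa_A2": round(rep.md_metrics.sasa, 2),
                "sasa_sd": round(rep.md_sd["sasa"], 2) if rep.n_replicates > 1 else "",
                "rg_nm": round(rep.md_metrics.rg_nm, 3),
                "rg_sd": round(rep.md_sd["rg"] / 10.0, 3) if rep.n_replicates > 1 else "",
                "hbonds": round(rep.md_metrics.n_hbonds, 1),
                "hbonds_sd": round(rep.md_sd["n_hbonds"], 1) if rep.n_replicates > 1 else "",
                "rmsd_A": round(rep.mean_rmsd, 2),
                "rmsd_sd": round(rep.rmsd_sd, 2) if rep.n_replicates > 1 else "",
            }
        )
    return rows


def run_analyze(config: RunConfig) -> list[StructureReport]:
    """Run the full battery on every input; write the comparison table and
    per-structure verdict JSON."""
    out = _prepare_outdir(config)
    reports = []
    table_rows = []
    for path in config.inputs:
        s = parse_pdb(path)
        motif = None
        if config.region is not None:
            sel = RegionSelector(**config.region)
            s = extract_region(s, sel)
        ens_paths = config.replicates.get(str(path), [])
        ensembles = [parse_pdb(p) for p in ens_paths]
        if not ensembles:
            log.warning("analyze: %s has no replicate ensembles; SD omitted", path)
        rep = analyze_structure(s, ensembles, config=config, motif=motif)
        reports.append(rep)
        table_rows.extend(_report_rows(rep))
        if rep.verdict is not None:
            (out / f"{rep.structure_id}_verdict.json").write_text(
                json.dumps(rep.verdict, indent=2, sort_keys=True) + "\n"
            )
    pd.DataFrame(table_rows).to_csv(out / "stability_table.tsv", sep="\t", index=False)
    return reports


def run_contacts(config: RunConfig) -> pd.DataFrame:
    """Per-motif hydrophobic contact records plus the pooled distance
    histogram across all inputs."""
    out = _prepare_outdir(config)
    params = config.contact_params()
    all_records = []
    rows = []
    for path in config.inputs:
        s = parse_pdb(path)
        for motif in find_3b_corners(s, assigner=config.assigner):
            recs = hydrophobic_contacts(motif, s, params=params)
            frac = hydrophobic_fraction(
                [
                    r
                    for r in s.residues(chain=motif.chain)
                    if motif.strand_a.start <= r.seq_num <= motif.strand_c.end
                ],
                params=params,
            )
            all_records.extend(recs)
            for r in recs:
                rows.append(
                    {
                        "structure": s.id,
                        "res_i": r.res_i,
                        "res_j": r.res_j,
                        "distance_A": round(r.distance, 3),
                        "class": r.contact_class,
                        "hydrophobic_fraction": round(frac, 3),
                    }
                )
    df = pd.DataFrame(rows, columns=["structure", "res_i", "res_j", "distance_A", "class", "hydrophobic_fraction"])
    df.to_csv(out / "contacts.tsv", sep="\t", index=False)
    if all_records:
        hist, modes = contact_histogram(all_records, params=params)
        hist_rows = []
        for b in range(len(hist.bin_edges) - 1):
            row = {"bin_left_A": round(float(hist.bin_edges[b]), 2)}
            for c, counts in hist.counts.items():
                row[c] = int(counts[b])
            hist_rows.append(row)
        pd.DataFrame(hist_rows).to_csv(out / "contact_histogram.tsv", sep="\t", index=False)
        (out / "contact_modes.json").write_text(json.dumps({"modes_A": modes[:5]}) + "\n")
    return df
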