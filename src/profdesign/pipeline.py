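"""End-to-end design jobs: pre-processing -> simulation -> selection.

Mirrors the three-stage job flow: (i) pre-processing (backbone
reconstruction if the scaffold is C-alpha only, feature assignment,
homolog selection, profile construction), (ii) Z-score-guided Monte Carlo
simulation in independent trajectories, and (iii) decoy pooling,
clustering and design selection with quality reports. Each stage is
logged with wall time; results carry enough provenance (config, seeds,
threshold used) to re-run bit-identically.
"""
from __future__ import annotations

import dataclasses
import logging
import time
import zipfile
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Union

from .cluster_select import (
    DesignReport,
    cluster_decoys,
    render_report_text,
    select_designs,
    summary_table,
    write_designs_fasta,
)
from .energy import DesignConfig, EnergyBaseline, calibrate_baseline
from .features import BasePredictor, PropensityPredictor
from .mcsearch import (
    DecoyPool,
    DesignConstraints,
    DesignEngine,
    Trajectory,
    pool_decoys,
    run_design,
    trajectory_rng,
    write_decoy_archive,
)
from .profile import Profile, profile_from_library, write_profile
from .structio import (
    ScaffoldFeatures,
    Structure,
    assign_features,
    is_ca_only,
    read_pdb,
    reconstruct_backbone,
)

logger = logging.getLogger("profdesign")


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage it happened in."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclasses.dataclass
class JobResult:
    reports: List[DesignReport]
    profile: Profile
    threshold_used: float
    pool: DecoyPool
    trajectories: List[Trajectory]
    scaffold: Structure
    features: ScaffoldFeatures
    provenance: dict


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %-14s done in %.2f s", name, dt)
            return False

    return _Timer()


def load_library(library_dir) -> List[Structure]:
    """Read every PDB file in a directory as a homolog-library member
    (minimum-length gate relaxed to 3 residues for library members)."""
    paths = sorted(Path(library_dir).glob("*.pdb"))
    return [read_pdb(p, min_length=3) for p in paths]


def run_job(
    scaffold: Union[Structure, str, Path],
    library: Union[Sequence[Structure], str, Path, None],
    config: Optional[DesignConfig] = None,
    constraints: Optional[DesignConstraints] = None,
    predictor: Optional[BasePredictor] = None,
    physics: Optional[Callable[[str], float]] = None,
    outdir: Union[str, Path, None] = None,
) -> JobResult:
    """Run a full design job and optionally write the output bundle.

    ``scaffold`` may be a structure or a PDB path; ``library`` a list of
    structures or a directory of PDB files (None or empty -> self-profile).
    The default predictor is the training-free propensity variant.
    """
    config = config or DesignConfig()
    config.validate()
    timings = {}

    t0 = time.perf_counter()
    try:
        if not isinstance(scaffold, Structure):
            scaffold = read_pdb(scaffold, min_length=config.min_len)
        if is_ca_only(scaffold):
            scaffold = reconstruct_backbone(scaffold)
        feats = assign_features(scaffold)
    except Exception as e:
        raise PipelineError(
            "pre-processing",
            f"{e} — check the scaffold PDB (needs >= {config.min_len} "
            "residues with CA atoms)") from e

    try:
        if library is not None and not isinstance(library, (list, tuple)):
            library = load_library(library)
        library = list(library or [])
        prof, threshold = profile_from_library(
            scaffold, library, config.tm_hi, config.tm_lo,
            config.min_homologs, config.pseudocount_strength)
    except Exception as e:
        raise PipelineError(
            "profile", f"{e} — provide a directory of homolog PDB files or "
            "run in self-profile mode with an empty library") from e
    timings["pre_processing_s"] = time.perf_counter() - t0
    logger.info("stage pre-processing done in %.2f s (threshold %.2f, "
                "%d homolog rows)", timings["pre_processing_s"], threshold,
                prof.n_homologs)

    predictor = predictor or PropensityPredictor(config.predictor_window)

    t0 = time.perf_counter()
    try:
        engine = DesignEngine(prof, feats, predictor, config,
                              scaffold.sequence, constraints,
                              physics=physics)
        physics_baseline = None
        if physics is not None:
            physics_baseline = calibrate_baseline(
                physics, len(scaffold), n=config.n_baseline,
                seed=config.seed + 20_000)
            engine.physics_baseline = physics_baseline
        trajectories = []
        for t in range(config.n_traj):
            rng = trajectory_rng(config.seed, t)
            trajectories.append(engine.run_trajectory(rng, seed_label=t))
        pool = pool_decoys(trajectories, config.burn_in)
    except Exception as e:
        raise PipelineError("simulation", str(e)) from e
    timings["simulation_s"] = time.perf_counter() - t0
    logger.info("stage simulation done in %.2f s (%d decoys pooled)",
                timings["simulation_s"], len(pool))

    t0 = time.perf_counter()
    try:
        clusters, _ = cluster_decoys(
            pool, config.cluster_frac, config.cluster_step,
            config.max_designs, config.cluster_subsample, seed=config.seed)
        reports = select_designs(
            clusters, pool, scaffold.sequence, feats, predictor,
            scaffold, config.binding_radius, config.max_designs)
    except Exception as e:
        raise PipelineError("clustering", str(e)) from e
    timings["clustering_s"] = time.perf_counter() - t0
    logger.info("stage clustering done in %.2f s (%d designs)",
                timings["clustering_s"], len(reports))

    result = JobResult(
        reports=reports,
        profile=prof,
        threshold_used=threshold,
        pool=pool,
        trajectories=trajectories,
        scaffold=scaffold,
        features=feats,
        provenance={
            "config": dataclasses.asdict(config),
            "threshold_used": threshold,
            "n_homolog_rows": prof.n_homologs,
            "baseline_mean": engine.baseline.mean,
            "baseline_std": engine.baseline.std,
            "timings": timings,
        },
    )
    if outdir is not None:
        write_job_outputs(result, outdir)
    return result


def write_job_outputs(result: JobResult, outdir) -> Path:
    """Write the output bundle: ranked designs FASTA, per-design text
    reports, summary TSV, profile export, decoy archive, and a zip of the
    text outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_designs_fasta(result.reports, outdir / "designs.fasta")
    report_paths = []
    for r in result.reports:
        p = outdir / f"design_rank{r.rank}.txt"
        p.write_text(render_report_text(
            r, result.scaffold.sequence, result.features, result.scaffold))
        report_paths.append(p)
    summary_table(result.reports).to_csv(
        outdir / "summary.tsv", sep="\t", index=False)
    write_profile(result.profile, outdir / "profile.pssm")
    write_decoy_archive(result.pool, outdir / "decoys.tsv.gz")
    with zipfile.ZipFile(outdir / "design_bundle.zip", "w",
                         zipfile.ZIP_DEFLATED) as zf:
        for p in [outdir / "designs.fasta", outdir / "summary.tsv",
                  outdir / "profile.pssm", *report_paths]:
            zf.write(p, p.name)
    return outdir
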