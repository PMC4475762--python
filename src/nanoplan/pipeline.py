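"""End-to-end pipeline: tracks -> SV counting -> ICSDs -> optimization.

The two-step workflow mirrors how nanodosimetric plans are analyzed: first,
absolute and conditional ICSDs and their descriptors are computed per
(pencil beam, voxel) for unit fluence, averaging over three scoring depths
per voxel; second, beam fluences are optimized against those unit-fluence
descriptors and the optimized plan is re-evaluated.

Every stage is seeded explicitly (no hidden global RNG): per-cell seeds are
derived from the run seed with ``numpy.random.SeedSequence`` keyed on the
(voxel, depth, beam) coordinates, so any cell can be regenerated in
isolation and full runs are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .geometry import DEPTH_TAGS, PlanGeometry, plan_from_config
from .icsd import ICSD, DescriptorSet, average_depths, descriptor_set, icsd_from_samples
from .optimize import (
    DescriptorMatrix,
    OptimizationResult,
    build_descriptor_matrix,
    evaluate_plan,
    optimize_uniform_m1,
    optimize_uniform_yields,
)
from .sampling import count_ensemble, sample_svs
from .tracks import (
    PRESET_MODELS,
    BraggQualityModel,
    QualityParams,
    ScoringRegion,
    TrackEnsemble,
    depth_quality,
    ensemble_from_quality,
    generate_ensemble,
)

__all__ = [
    "RunConfig",
    "load_run_config",
    "simulate_plan",
    "compute_descriptors",
    "descriptors_from_ensembles",
    "run_plan",
    "sample_quality_descriptors",
]


@dataclass
class RunConfig:
    """One fully specified pipeline run."""

    plan: dict  # plan-geometry config mapping
    preset: str = "proton_like"
    model_overrides: dict = field(default_factory=dict)
    n_primaries: int = 10_000
    n_svs: int = 10_000
    seed: int = 0
    strategy: str = "uniform_yields"
    prescriptions: dict = field(default_factory=dict)
    sv_diameter: float = 2.0
    sv_length: float = 16.0
    region_diameter: float = 500.0
    region_height: float = 500.0
    uniformity_tol: float = 2.0
    output_dir: str = "nanoplan_out"

    def plan_geometry(self) -> PlanGeometry:
        return plan_from_config(self.plan)

    def quality_model(self) -> BraggQualityModel:
        model = PRESET_MODELS[self.preset]
        if self.model_overrides:
            from dataclasses import replace

            model = replace(model, **self.model_overrides)
        return model

    def region(self) -> ScoringRegion:
        return ScoringRegion(self.region_diameter, self.region_height)


_REQUIRED_KEYS = ("plan",)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in _REQUIRED_KEYS:
        if key not in raw:
            raise KeyError(f"run config missing key: {key!r}")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise KeyError(f"unknown run config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _cell_seed(seed: int, voxel_index: int, tag: str, pb_id: int) -> np.random.SeedSequence:
    return np.random.SeedSequence((seed, voxel_index, DEPTH_TAGS.index(tag), pb_id))


_SV_STREAM = 1_000_003  # pb_id slot reserved for SV placement streams


def simulate_plan(
    plan: PlanGeometry,
    model: BraggQualityModel,
    n_primaries: int,
    region: ScoringRegion,
    seed: int,
) -> list[TrackEnsemble]:
    """Generate every (beam, voxel, depth) ensemble of a plan (materialized;
    intended for event-file export at small history counts)."""
    out = []
    for vox in plan.voxels:
        for tag in DEPTH_TAGS:
            for beam in plan.beams:
                rng = np.random.default_rng(_cell_seed(seed, vox.index, tag, beam.id))
                out.append(
                    generate_ensemble(plan, beam, vox, tag, n_primaries, region, rng, model)
                )
    return out


def descriptors_from_ensembles(
    plan: PlanGeometry,
    ensembles: list[TrackEnsemble],
    n_svs: int,
    seed: int,
    *,
    sv_diameter: float = 2.0,
    sv_length: float = 16.0,
) -> tuple[DescriptorMatrix, dict[tuple[int, int], ICSD]]:
    """Unit-fluence descriptors from pre-generated (or imported) ensembles.

    One random SV set is drawn per (voxel, depth) scoring location and shared
    by all beams (the scoring cylinder is a property of the location, not of
    the beam); per-(beam, voxel) ICSDs are averaged over the three depths.
    """
    by_cell = {(e.pb_id, e.voxel_id, e.depth_tag): e for e in ensembles}
    region = ensembles[0].region if ensembles else ScoringRegion()
    store: dict[tuple[int, int], ICSD] = {}
    descriptors: dict[tuple[int, int], DescriptorSet] = {}
    for vox in plan.voxels:
        per_tag_svs = {}
        for tag in DEPTH_TAGS:
            rng = np.random.default_rng(_cell_seed(seed, vox.index, tag, _SV_STREAM))
            per_tag_svs[tag] = sample_svs(
                region, n_svs, rng, diameter=sv_diameter, length=sv_length
            )
        for beam in plan.beams:
            per_depth = []
            for tag in DEPTH_TAGS:
                ens = by_cell.get((beam.id, vox.index, tag))
                if ens is None:
                    raise ValueError(
                        f"missing ensemble for pencil beam {beam.id}, "
                        f"voxel {vox.index}, depth {tag}"
                    )
                table = count_ensemble(ens, per_tag_svs[tag])
                per_depth.append(icsd_from_samples(table))
            rep = average_depths(per_depth)
            store[(beam.id, vox.index)] = rep
            descriptors[(beam.id, vox.index)] = descriptor_set(rep)
    return build_descriptor_matrix(plan, descriptors), store


def compute_descriptors(
    plan: PlanGeometry,
    model: BraggQualityModel,
    *,
    n_primaries: int,
    n_svs: int,
    region: ScoringRegion | None = None,
    seed: int = 0,
    sv_diameter: float = 2.0,
    sv_length: float = 16.0,
    progress: bool = False,
) -> tuple[DescriptorMatrix, dict[tuple[int, int], ICSD]]:
    """Streaming unit-fluence descriptor computation for a whole plan.

    Ensembles are generated, counted and discarded one cell at a time, so
    memory stays bounded even at large history counts.
    """
    region = region or ScoringRegion()
    store: dict[tuple[int, int], ICSD] = {}
    descriptors: dict[tuple[int, int], DescriptorSet] = {}
    for vox in plan.voxels:
        per_beam_depth: dict[int, list[ICSD]] = {b.id: [] for b in plan.beams}
        for tag in DEPTH_TAGS:
            rng = np.random.default_rng(_cell_seed(seed, vox.index, tag, _SV_STREAM))
            svs = sample_svs(region, n_svs, rng, diameter=sv_diameter, length=sv_length)
            for beam in plan.beams:
                rng_b = np.random.default_rng(_cell_seed(seed, vox.index, tag, beam.id))
                ens = generate_ensemble(
                    plan, beam, vox, tag, n_primaries, region, rng_b, model
                )
                table = count_ensemble(ens, svs)
                per_beam_depth[beam.id].append(icsd_from_samples(table))
        for beam in plan.beams:
            rep = average_depths(per_beam_depth[beam.id])
            store[(beam.id, vox.index)] = rep
            descriptors[(beam.id, vox.index)] = descriptor_set(rep)
        if progress:
            print(f"voxel {vox.index}: descriptors done")
    return build_descriptor_matrix(plan, descriptors), store


def run_plan(config: RunConfig, progress: bool = False) -> dict:
    """Full pipeline: descriptors, optimization and plan evaluation."""
    plan = config.plan_geometry()
    dm, store = compute_descriptors(
        plan,
        config.quality_model(),
        n_primaries=config.n_primaries,
        n_svs=config.n_svs,
        region=config.region(),
        seed=config.seed,
        sv_diameter=config.sv_diameter,
        sv_length=config.sv_length,
        progress=progress,
    )
    if config.strategy == "uniform_m1":
        result = optimize_uniform_m1(
            dm,
            config.prescriptions.get("m1", "auto"),
            uniformity_tol=config.uniformity_tol,
        )
    elif config.strategy == "uniform_yields":
        result = optimize_uniform_yields(
            dm,
            config.prescriptions.get("y_sc", "auto"),
            config.prescriptions.get("y_lc", "auto"),
            uniformity_tol=config.uniformity_tol,
        )
    else:
        raise ValueError(f"unknown strategy {config.strategy!r}")
    evaluation = evaluate_plan(
        dm, result.fluences, store, uniformity_tol=config.uniformity_tol,
        objective=result.objective,
    )
    evaluation.residual_norm = result.residual_norm
    evaluation.prescription.update(result.prescription)
    evaluation.converged = result.converged
    return {"plan": plan, "matrix": dm, "store": store, "result": evaluation}


# -- fixed-quality sampling (statistical-precision studies) -------------------


def sample_quality_descriptors(
    quality: QualityParams,
    *,
    n_primaries: int,
    n_svs: int,
    n_positions: int = 3,
    region: ScoringRegion | None = None,
    seed: int | np.random.SeedSequence = 0,
    sv_diameter: float = 2.0,
    sv_length: float = 16.0,
) -> tuple[DescriptorSet, dict[str, int]]:
    """Descriptors of one fixed radiation quality, averaged over several
    independent scoring positions.

    Emulates scoring one ensemble in `n_positions` scoring cylinders along
    its path, each sampled with `n_svs` random SVs.  Returns the
    depth-averaged descriptors and the pooled nonzero-sample tallies per
    cluster-size class (diagnostics for statistical sufficiency).
    """
    region = region or ScoringRegion()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_positions)
    per_position = []
    tallies = {"nonzero": 0, "nu_1": 0, "nu_2_3": 0, "nu_4_10": 0}
    for k in range(n_positions):
        ens = ensemble_from_quality(
            quality, n_primaries, region, np.random.default_rng(children[2 * k])
        )
        svs = sample_svs(
            region, n_svs, np.random.default_rng(children[2 * k + 1]),
            diameter=sv_diameter, length=sv_length,
        )
        table = count_ensemble(ens, svs)
        tallies["nonzero"] += len(table)
        tallies["nu_1"] += int((table.nu == 1).sum())
        tallies["nu_2_3"] += int(((table.nu >= 2) & (table.nu <= 3)).sum())
        tallies["nu_4_10"] += int(((table.nu >= 4) & (table.nu <= 10)).sum())
        per_position.append(icsd_from_samples(table))
    rep = average_depths(per_position)
    return descriptor_set(rep), tallies
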