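"""Synthetic ionization track generator.

Stand-in for a full track-structure Monte Carlo transport: each primary
particle crossing a nanodosimetric scoring cylinder deposits a clustered
ionization point cloud drawn from an explicit parametric point process.
Primary-ionization sites form a Poisson process along an axis-parallel chord;
each site spawns ``1 + Poisson(cluster_mean)`` ionizations displaced
isotropically with an exponential radial distance.  Depth dependence of the
"radiation quality" (plateau vs. Bragg peak) is modeled by
:func:`depth_quality`, which maps a pencil beam and a depth to the point
process parameters.

All lengths in this module are nanometers unless noted; depths along the beam
are millimeters.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .geometry import PencilBeam, PlanGeometry, Voxel

__all__ = [
    "QualityParams",
    "ScoringRegion",
    "Track",
    "TrackEnsemble",
    "BraggQualityModel",
    "PRESET_MODELS",
    "depth_quality",
    "generate_track",
    "generate_ensemble",
    "ensemble_from_quality",
    "write_events",
    "read_events",
]


@dataclass(frozen=True)
class QualityParams:
    """Point-process parameters of one radiation quality Q.

    lambda_primary : ionizations/nm, mean linear density of primary-ionization
        sites along the track axis.
    cluster_mean : mean number of extra ionizations per site (short-range
        secondary-electron cluster), dimensionless.
    radial_scale : nm, mean radial displacement of ionizations from the site.
    fluence_factor : relative number of primaries reaching this depth.
    """

    lambda_primary: float
    cluster_mean: float
    radial_scale: float
    fluence_factor: float = 1.0

    def __post_init__(self) -> None:
        if min(self.lambda_primary, self.cluster_mean, self.radial_scale,
               self.fluence_factor) < 0:
            raise ValueError("quality parameters must be non-negative")
        if self.fluence_factor > 0 and self.lambda_primary <= 0:
            raise ValueError("lambda_primary must be positive where fluence is")


@dataclass(frozen=True)
class ScoringRegion:
    """Cylindrical scoring region (track sampling volume), axis along z."""

    diameter: float = 500.0  # nm
    height: float = 500.0  # nm

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.height <= 0:
            raise ValueError("scoring region dimensions must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        r2 = points[:, 0] ** 2 + points[:, 1] ** 2
        return (r2 <= self.radius**2 + 1e-9) & (
            np.abs(points[:, 2]) <= self.height / 2.0 + 1e-9
        )


@dataclass
class Track:
    """Ionization events of one primary particle inside the scoring region."""

    primary_id: int
    points: np.ndarray  # (n, 3) nm, scoring-region frame (origin at center)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)


@dataclass
class TrackEnsemble:
    """Ionization point clouds of ``n_primaries`` primaries in one cell.

    ``n_primaries`` includes primaries contributing zero points (attenuated
    fluence), so it is the denominator of the absolute cluster-size
    distribution.  Points are stored concatenated with a parallel
    ``primary_index`` array (sorted, 0-based) for speed; :meth:`tracks`
    materializes per-primary views.
    """

    n_primaries: int
    points: np.ndarray  # (N, 3)
    primary_index: np.ndarray  # (N,) int64, non-decreasing
    region: ScoringRegion = field(default_factory=ScoringRegion)
    quality: QualityParams | None = None
    pb_id: int = 0
    voxel_id: int = 0
    depth_tag: str = "central"

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.primary_index = np.ascontiguousarray(self.primary_index, dtype=np.int64)
        if len(self.points) != len(self.primary_index):
            raise ValueError("points and primary_index length mismatch")
        if self.n_primaries < 1:
            raise ValueError("n_primaries must be positive")
        if len(self.primary_index) and self.primary_index.max() >= self.n_primaries:
            raise ValueError("primary_index out of range")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def tracks(self) -> list[Track]:
        """Materialize per-primary tracks (all primaries, including empty)."""
        out = []
        for pid in range(self.n_primaries):
            out.append(Track(pid, self.points[self.primary_index == pid]))
        return out

    @classmethod
    def from_tracks(
        cls,
        tracks: list[Track],
        n_primaries: int | None = None,
        region: ScoringRegion | None = None,
        **kw,
    ) -> "TrackEnsemble":
        region = region or ScoringRegion()
        n_primaries = n_primaries if n_primaries is not None else len(tracks)
        pts = [t.points for t in tracks if len(t.points)]
        idx = [np.full(len(t.points), t.primary_id) for t in tracks if len(t.points)]
        points = np.concatenate(pts) if pts else np.empty((0, 3))
        index = np.concatenate(idx) if idx else np.empty(0, dtype=np.int64)
        order = np.argsort(index, kind="stable")
        if len(index) and not np.all(region.contains(points)):
            raise ValueError("track points outside the scoring region")
        return cls(
            n_primaries=n_primaries,
            points=points[order],
            primary_index=index[order],
            region=region,
            **kw,
        )


# -- depth-dependent radiation quality ---------------------------------------


@dataclass(frozen=True)
class BraggQualityModel:
    """Toy depth-quality model replacing transport physics.

    The primary-ionization density rises from a plateau value to a peak value
    as ``(depth/range)**rise_power``, stays at the peak across a distal
    falloff of width ``falloff_mm`` (stopping particles), and beyond that only
    an optional fragment tail with plateau-like quality remains.  The fluence
    factor decays exponentially (nuclear attenuation) and drops linearly to
    zero across the falloff.
    """

    lambda_plateau: float
    lambda_peak: float
    rise_power: float
    falloff_mm: float
    cluster_plateau: float
    cluster_peak: float
    radial_scale: float
    attenuation_per_mm: float = 0.0
    fragment_tail: float = 0.0


#: Preset quality models.  ``carbon_like`` is denser at every depth and rises
#: more steeply towards the peak than ``proton_like``; only carbon carries a
#: fragment tail beyond the Bragg peak.
PRESET_MODELS: dict[str, BraggQualityModel] = {
    "proton_like": BraggQualityModel(
        lambda_plateau=0.05,
        lambda_peak=0.35,
        rise_power=8.0,
        falloff_mm=4.5,
        cluster_plateau=0.5,
        cluster_peak=1.8,
        radial_scale=8.0,
        attenuation_per_mm=0.0008,
        fragment_tail=0.0,
    ),
    "carbon_like": BraggQualityModel(
        lambda_plateau=0.12,
        lambda_peak=0.8,
        rise_power=12.0,
        falloff_mm=2.0,
        cluster_plateau=0.8,
        cluster_peak=2.5,
        radial_scale=5.0,
        attenuation_per_mm=0.0015,
        fragment_tail=0.06,
    ),
}


def depth_quality(
    beam: PencilBeam, depth: float, model: BraggQualityModel | None = None
) -> QualityParams:
    """Radiation quality of `beam` after `depth` mm of water path."""
    if depth < 0:
        raise ValueError("depth must be non-negative")
    if model is None:
        model = PRESET_MODELS[beam.particle]
    r = beam.nominal_range
    w = model.falloff_mm
    atten = np.exp(-model.attenuation_per_mm * depth)
    if depth <= r:
        x = (depth / r) ** model.rise_power
        lam = model.lambda_plateau + (model.lambda_peak - model.lambda_plateau) * x
        clus = model.cluster_plateau + (model.cluster_peak - model.cluster_plateau) * x
        f = atten
    else:
        tail_f = model.fragment_tail * atten
        if depth <= r + w and w > 0:
            stop_f = np.exp(-model.attenuation_per_mm * r) * (1.0 - (depth - r) / w)
        else:
            stop_f = 0.0
        if stop_f >= tail_f:
            lam, clus, f = model.lambda_peak, model.cluster_peak, stop_f
        else:
            lam, clus, f = model.lambda_plateau, model.cluster_plateau, tail_f
    if f <= 0.0:
        # quality irrelevant, but keep parameters valid
        return QualityParams(model.lambda_plateau, clus, model.radial_scale, 0.0)
    return QualityParams(lam, clus, model.radial_scale, float(f))


# -- point generation --------------------------------------------------------


@njit(cache=True)
def _displace_and_clip(ex, ey, sz, site_of_ion, prim_of_ion, dist, uz, uphi,
                       radius, half_height, out_pts, out_prim):
    """Fused displacement of ionizations around their sites, clipping to the
    region.  Returns the number of surviving points."""
    n = 0
    r2max = radius * radius
    for i in range(dist.shape[0]):
        s = np.sqrt(1.0 - uz[i] * uz[i])
        j = site_of_ion[i]
        p = prim_of_ion[i]
        x = ex[p] + dist[i] * s * np.cos(uphi[i])
        y = ey[p] + dist[i] * s * np.sin(uphi[i])
        z = sz[j] + dist[i] * uz[i]
        if x * x + y * y <= r2max and -half_height <= z <= half_height:
            out_pts[n, 0] = x
            out_pts[n, 1] = y
            out_pts[n, 2] = z
            out_prim[n] = p
            n += 1
    return n


def _generate_points(
    q: QualityParams, region: ScoringRegion, rng: np.random.Generator, n_primaries: int
) -> tuple[np.ndarray, np.ndarray]:
    """Clustered ionization point clouds for `n_primaries` chords.

    Chords are axis-parallel with entry points uniform over the region face.
    Returns (points (N,3), primary_index (N,)) with primary_index sorted.
    """
    if n_primaries == 0 or q.lambda_primary == 0:
        return np.empty((0, 3)), np.empty(0, dtype=np.int64)
    H = region.height
    R = region.radius
    n_sites = rng.poisson(q.lambda_primary * H, n_primaries)
    tot_sites = int(n_sites.sum())
    rr = R * np.sqrt(rng.random(n_primaries))
    th = rng.random(n_primaries) * 2.0 * np.pi
    ex, ey = rr * np.cos(th), rr * np.sin(th)
    prim_of_site = np.repeat(np.arange(n_primaries, dtype=np.int64), n_sites)
    sz = rng.uniform(-H / 2.0, H / 2.0, tot_sites)
    n_ions = 1 + rng.poisson(q.cluster_mean, tot_sites)
    tot = int(n_ions.sum())
    site_of_ion = np.repeat(np.arange(tot_sites, dtype=np.int64), n_ions)
    prim_of_ion = prim_of_site[site_of_ion]
    dist = rng.exponential(q.radial_scale, tot) if q.radial_scale > 0 else np.zeros(tot)
    uz = rng.uniform(-1.0, 1.0, tot)
    uphi = rng.uniform(0.0, 2.0 * np.pi, tot)
    out_pts = np.empty((tot, 3))
    out_prim = np.empty(tot, dtype=np.int64)
    n = _displace_and_clip(
        ex, ey, sz, site_of_ion, prim_of_ion, dist, uz, uphi, R, H / 2.0,
        out_pts, out_prim,
    )
    # contiguous views into the kernel buffers; avoids copying ~100s of MB
    return out_pts[:n], out_prim[:n]


def generate_track(
    q: QualityParams,
    region: ScoringRegion | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> Track:
    """Generate one primary's ionization point cloud (deterministic per seed).

    The chord is axis-parallel with its entry point uniform over the region
    face; sites are Poisson with density ``lambda_primary`` along the chord
    and each spawns ``1 + Poisson(cluster_mean)`` ionizations displaced
    isotropically with exponential radial distance.
    """
    region = region or ScoringRegion()
    rng = np.random.default_rng(rng_seed)
    points, _ = _generate_points(q, region, rng, 1)
    return Track(0, points)


def ensemble_from_quality(
    q: QualityParams,
    n_primaries: int,
    region: ScoringRegion | None = None,
    rng_seed: int | np.random.Generator = 0,
    **meta,
) -> TrackEnsemble:
    """Generate an ensemble at fixed quality parameters.

    Only ``round(n_primaries * fluence_factor)`` primaries produce points; the
    remainder are recorded implicitly as empty tracks so that the absolute
    cluster-size distribution reflects the attenuated fluence.
    """
    if n_primaries <= 0:
        raise ValueError("n_primaries must be positive")
    region = region or ScoringRegion()
    rng = np.random.default_rng(rng_seed)
    n_eff = int(round(n_primaries * q.fluence_factor))
    n_eff = min(n_eff, n_primaries)
    points, index = _generate_points(q, region, rng, n_eff)
    return TrackEnsemble(
        n_primaries=n_primaries,
        points=points,
        primary_index=index,
        region=region,
        quality=q,
        **meta,
    )


def generate_ensemble(
    plan: PlanGeometry,
    beam: PencilBeam,
    voxel: Voxel,
    depth_tag: str,
    n_primaries: int,
    region: ScoringRegion | None = None,
    rng_seed: int | np.random.Generator = 0,
    model: BraggQualityModel | None = None,
) -> TrackEnsemble:
    """Generate the ensemble of `beam` at one scoring position of `voxel`."""
    z = voxel.scoring_depth(depth_tag)
    q = depth_quality(beam, plan.path_depth(beam, z), model)
    return ensemble_from_quality(
        q,
        n_primaries,
        region,
        rng_seed,
        pb_id=beam.id,
        voxel_id=voxel.index,
        depth_tag=depth_tag,
    )


# -- event-file bridge (import/export of external track-structure output) ----

_EVENT_COLUMNS = ("pb_id", "voxel_id", "depth_tag", "primary_id", "x_nm", "y_nm", "z_nm")


def write_events(path, ensembles: list[TrackEnsemble]) -> None:
    """Write ensembles as a tab-separated event table.

    One row per ionization; sidecar comment lines record ``n_primaries`` per
    (pb_id, voxel_id, depth_tag) cell so empty cells round-trip.
    """
    with open(path, "w") as fh:
        for ens in ensembles:
            fh.write(
                f"# n_primaries\t{ens.pb_id}\t{ens.voxel_id}\t{ens.depth_tag}"
                f"\t{ens.n_primaries}\n"
            )
        fh.write("\t".join(_EVENT_COLUMNS) + "\n")
        for ens in ensembles:
            buf = io.StringIO()
            for (x, y, z), pid in zip(ens.points, ens.primary_index):
                buf.write(
                    f"{ens.pb_id}\t{ens.voxel_id}\t{ens.depth_tag}\t{pid}"
                    f"\t{x:.6f}\t{y:.6f}\t{z:.6f}\n"
                )
            fh.write(buf.getvalue())


def read_events(path, region: ScoringRegion | None = None) -> list[TrackEnsemble]:
    """Read an event table written by :func:`write_events` (or an external
    track-structure post-processor using the same format)."""
    import pandas as pd

    region = region or ScoringRegion()
    cells: dict[tuple[int, int, str], int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            if parts and parts[0] == "n_primaries":
                cells[(int(parts[1]), int(parts[2]), parts[3])] = int(parts[4])
    table = pd.read_csv(path, sep="\t", comment="#")
    out = []
    grouped = dict(iter(table.groupby(["pb_id", "voxel_id", "depth_tag"]))) if len(table) else {}
    for (pb, vox, tag), n_prim in cells.items():
        sub = grouped.get((pb, vox, tag))
        if sub is None:
            points = np.empty((0, 3))
            index = np.empty(0, dtype=np.int64)
        else:
            points = sub[["x_nm", "y_nm", "z_nm"]].to_numpy()
            index = sub["primary_id"].to_numpy(dtype=np.int64)
            order = np.argsort(index, kind="stable")
            points, index = points[order], index[order]
        out.append(
            TrackEnsemble(
                n_primaries=n_prim,
                points=points,
                primary_index=index,
                region=region,
                pb_id=pb,
                voxel_id=vox,
                depth_tag=tag,
            )
        )
    return out
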