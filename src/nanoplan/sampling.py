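"""Nanocylinder sensitive-volume sampling of track ensembles.

Cylindrical sensitive volumes (SVs, default 2 nm diameter x 16 nm length,
roughly 50 DNA base pairs) are placed at random position and orientation
inside the scoring region, and the number of ionizations of each primary
falling inside each SV is counted.  Every (SV, primary) pair is one
realization of the ionization cluster size; zero-count pairs are implicit,
so the sample denominator is ``n_SV * n_primaries``.

SV centers are restricted so the whole SV lies inside the scoring region (no
boundary clipping, which would bias clusters truncated at the edge).  The
containment predicate uses closed inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
from numba import njit

from .tracks import ScoringRegion, TrackEnsemble

__all__ = [
    "CylinderSV",
    "SVSet",
    "CountSample",
    "CountTable",
    "sample_sv",
    "sample_svs",
    "point_in_sv",
    "count_ensemble",
    "count_ensemble_bruteforce",
]


@dataclass(frozen=True)
class CylinderSV:
    """A single sensitive volume: a finite cylinder in the region frame."""

    center: tuple[float, float, float]
    axis: tuple[float, float, float]
    diameter: float = 2.0
    length: float = 16.0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError("SV dimensions must be positive")
        if abs(float(np.linalg.norm(self.axis)) - 1.0) > 1e-9:
            raise ValueError("axis must be a unit vector")


@dataclass
class SVSet:
    """A batch of SVs sharing one geometry (vectorized storage)."""

    centers: np.ndarray  # (n, 3)
    axes: np.ndarray  # (n, 3) unit vectors
    diameter: float = 2.0
    length: float = 16.0
    region: ScoringRegion = field(default_factory=ScoringRegion)

    def __post_init__(self) -> None:
        self.centers = np.ascontiguousarray(self.centers, dtype=float).reshape(-1, 3)
        self.axes = np.ascontiguousarray(self.axes, dtype=float).reshape(-1, 3)
        if self.centers.shape != self.axes.shape:
            raise ValueError("centers and axes shape mismatch")

    def __len__(self) -> int:
        return len(self.centers)

    def __getitem__(self, i: int) -> CylinderSV:
        return CylinderSV(
            tuple(self.centers[i]), tuple(self.axes[i]), self.diameter, self.length
        )

    def __iter__(self) -> Iterator[CylinderSV]:
        return (self[i] for i in range(len(self)))

    @property
    def bounding_radius(self) -> float:
        """Radius of the sphere circumscribing one SV."""
        return float(np.hypot(self.length / 2.0, self.diameter / 2.0))

    @classmethod
    def from_svs(cls, svs: list[CylinderSV], region: ScoringRegion | None = None) -> "SVSet":
        if not svs:
            raise ValueError("empty SV list")
        d, ln = svs[0].diameter, svs[0].length
        if any(s.diameter != d or s.length != ln for s in svs):
            raise ValueError("mixed SV dimensions in one set")
        return cls(
            centers=np.array([s.center for s in svs]),
            axes=np.array([s.axis for s in svs]),
            diameter=d,
            length=ln,
            region=region or ScoringRegion(),
        )


class CountSample(NamedTuple):
    """Ionization count of one primary inside one SV (only nu >= 1 stored)."""

    sv_index: int
    primary_id: int
    nu: int


@dataclass
class CountTable:
    """Sparse per-(SV, primary) ionization counts of one ensemble.

    Only pairs with ``nu >= 1`` are materialized; the total number of pairs
    (``n_svs * n_primaries``) supplies the implicit zeros.
    """

    sv_index: np.ndarray  # (m,) int64
    primary_id: np.ndarray  # (m,) int64
    nu: np.ndarray  # (m,) int64, all >= 1
    n_svs: int
    n_primaries: int

    @property
    def n_total_pairs(self) -> int:
        return self.n_svs * self.n_primaries

    def __len__(self) -> int:
        return len(self.nu)

    def __iter__(self) -> Iterator[CountSample]:
        return (
            CountSample(int(s), int(p), int(n))
            for s, p, n in zip(self.sv_index, self.primary_id, self.nu)
        )

    def sorted(self) -> "CountTable":
        order = np.lexsort((self.primary_id, self.sv_index))
        return CountTable(
            self.sv_index[order], self.primary_id[order], self.nu[order],
            self.n_svs, self.n_primaries,
        )

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"sv_index": self.sv_index, "primary_id": self.primary_id, "nu": self.nu}
        ).to_csv(path, sep="\t", index=False)


# -- SV placement ------------------------------------------------------------


def _axis_extents(axes: np.ndarray, diameter: float, length: float):
    """Exact z half-extent and conservative radial half-extent of tilted SVs."""
    az = np.abs(axes[:, 2])
    axy = np.hypot(axes[:, 0], axes[:, 1])
    ez = length / 2.0 * az + diameter / 2.0 * np.sqrt(np.maximum(1.0 - az**2, 0.0))
    er = length / 2.0 * axy + diameter / 2.0
    return ez, er


def sample_svs(
    region: ScoringRegion,
    n: int,
    rng_seed: int | np.random.Generator = 0,
    *,
    diameter: float = 2.0,
    length: float = 16.0,
    axis: tuple[float, float, float] | None = None,
    max_rounds: int = 1000,
) -> SVSet:
    """Draw `n` SVs with axes uniform on the sphere and centers uniform over
    the admissible sub-volume (whole SV inside the region); deterministic per
    seed.

    If `axis` is given, all SVs share that fixed orientation.  When the
    admissible interval along an axis degenerates to a point (e.g. SV length
    equals region height for an axis-aligned SV), the corresponding center
    coordinate is forced to the region mid-plane.
    """
    rng = np.random.default_rng(rng_seed)
    R, H = region.radius, region.height
    fits_axial = length <= H and diameter <= 2.0 * R
    fits_transverse = diameter <= H and length + diameter <= 2.0 * R
    if not (fits_axial or fits_transverse):
        raise ValueError("SV larger than scoring region in every orientation")
    axes = np.empty((n, 3))
    filled = 0
    for _ in range(max_rounds):
        need = n - filled
        if need == 0:
            break
        if axis is not None:
            a = np.broadcast_to(np.asarray(axis, dtype=float), (need, 3)).copy()
            norm = np.linalg.norm(a, axis=1, keepdims=True)
            a /= norm
        else:
            # uniform on the sphere: z ~ U(-1,1), phi ~ U(0,2pi)
            z = rng.uniform(-1.0, 1.0, need)
            phi = rng.uniform(0.0, 2.0 * np.pi, need)
            s = np.sqrt(1.0 - z**2)
            a = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
        ez, er = _axis_extents(a, diameter, length)
        ok = (ez <= H / 2.0 + 1e-12) & (er <= R + 1e-12)
        n_ok = int(ok.sum())
        axes[filled : filled + n_ok] = a[ok]
        filled += n_ok
        if axis is not None and n_ok < need:
            raise ValueError("requested SV orientation does not fit in the region")
    if filled < n:
        raise ValueError("SV does not fit in the region for sampled orientations")
    ez, er = _axis_extents(axes, diameter, length)
    hz = np.maximum(H / 2.0 - ez, 0.0)
    rad = np.maximum(R - er, 0.0)
    cz = rng.uniform(-hz, hz)
    rr = rad * np.sqrt(rng.random(n))
    th = rng.random(n) * 2.0 * np.pi
    centers = np.column_stack([rr * np.cos(th), rr * np.sin(th), cz])
    return SVSet(centers, axes, diameter, length, region)


def sample_sv(
    region: ScoringRegion,
    rng_seed: int | np.random.Generator = 0,
    **kw,
) -> CylinderSV:
    """Draw a single random SV (see :func:`sample_svs`)."""
    return sample_svs(region, 1, rng_seed, **kw)[0]


def point_in_sv(point, sv: CylinderSV) -> bool:
    """True iff `point` lies inside the cylinder (closed boundaries)."""
    d = np.asarray(point, dtype=float) - np.asarray(sv.center, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite point coordinates")
    a = np.asarray(sv.axis, dtype=float)
    proj = float(d @ a)
    if abs(proj) > sv.length / 2.0:
        return False
    perp2 = float(d @ d) - proj**2
    return perp2 <= (sv.diameter / 2.0) ** 2 + 1e-12


# -- counting ----------------------------------------------------------------


@njit(cache=True)
def _count_kernel(pts, prim, ctr, ax, sv_order, starts, ox, oy, oz, nx, ny, nz,
                  cell, half_len, rad2, rb2, out_sv, out_prim, cap):
    """Grid candidate search + exact point-in-cylinder predicate.

    Emits one (sv, primary) record per contained ionization; returns the
    number of records (may exceed `cap`, in which case the caller reruns with
    a larger buffer).
    """
    n = 0
    for ip in range(pts.shape[0]):
        px, py, pz = pts[ip, 0], pts[ip, 1], pts[ip, 2]
        cx = int((px - ox) // cell)
        cy = int((py - oy) // cell)
        cz = int((pz - oz) // cell)
        for dx in range(-1, 2):
            x = cx + dx
            if x < 0 or x >= nx:
                continue
            for dy in range(-1, 2):
                y = cy + dy
                if y < 0 or y >= ny:
                    continue
                for dz in range(-1, 2):
                    z = cz + dz
                    if z < 0 or z >= nz:
                        continue
                    c = (x * ny + y) * nz + z
                    for k in range(starts[c], starts[c + 1]):
                        j = sv_order[k]
                        ddx = px - ctr[j, 0]
                        ddy = py - ctr[j, 1]
                        ddz = pz - ctr[j, 2]
                        d2 = ddx * ddx + ddy * ddy + ddz * ddz
                        if d2 > rb2:
                            continue
                        pr = ddx * ax[j, 0] + ddy * ax[j, 1] + ddz * ax[j, 2]
                        if pr > half_len or pr < -half_len:
                            continue
                        if d2 - pr * pr > rad2:
                            continue
                        if n < cap:
                            out_sv[n] = j
                            out_prim[n] = prim[ip]
                        n += 1
    return n


def _empty_table(svs: SVSet, ensemble: TrackEnsemble) -> CountTable:
    e = np.empty(0, dtype=np.int64)
    return CountTable(e, e.copy(), e.copy(), len(svs), ensemble.n_primaries)


def count_ensemble(ensemble: TrackEnsemble, svs: SVSet) -> CountTable:
    """Count each primary's ionizations inside each SV.

    A uniform spatial grid over the SV centers prunes candidates to those
    within the SV circumscribing-sphere radius; the exact cylinder predicate
    is then applied.  Output rows are sorted by (sv_index, primary_id).
    """
    if isinstance(svs, list):
        svs = SVSet.from_svs(svs, ensemble.region)
    if ensemble.n_points == 0 or len(svs) == 0:
        return _empty_table(svs, ensemble)
    pts = ensemble.points
    rb = svs.bounding_radius + 1e-9
    lo = pts.min(axis=0)
    lo = np.minimum(lo, svs.centers.min(axis=0)) - 1.0
    hi = pts.max(axis=0)
    hi = np.maximum(hi, svs.centers.max(axis=0)) + 1.0
    dims = np.maximum(np.ceil((hi - lo) / rb).astype(np.int64), 1)
    sv_cell = ((svs.centers - lo) // rb).astype(np.int64)
    lin = (sv_cell[:, 0] * dims[1] + sv_cell[:, 1]) * dims[2] + sv_cell[:, 2]
    order = np.argsort(lin, kind="stable")
    ncells = int(dims.prod())
    starts = np.searchsorted(lin[order], np.arange(ncells + 1))
    cap = max(4096, ensemble.n_points // 16)
    while True:
        out_sv = np.empty(cap, dtype=np.int64)
        out_prim = np.empty(cap, dtype=np.int64)
        m = _count_kernel(
            pts, ensemble.primary_index, svs.centers, svs.axes, order, starts,
            lo[0], lo[1], lo[2], int(dims[0]), int(dims[1]), int(dims[2]),
            rb, svs.length / 2.0, (svs.diameter / 2.0) ** 2 + 1e-12, rb * rb,
            out_sv, out_prim, cap,
        )
        if m <= cap:
            break
        cap = m
    if m == 0:
        return _empty_table(svs, ensemble)
    key = out_sv[:m] * np.int64(ensemble.n_primaries) + out_prim[:m]
    uniq, counts = np.unique(key, return_counts=True)
    return CountTable(
        sv_index=uniq // ensemble.n_primaries,
        primary_id=uniq % ensemble.n_primaries,
        nu=counts.astype(np.int64),
        n_svs=len(svs),
        n_primaries=ensemble.n_primaries,
    )


def count_ensemble_bruteforce(ensemble: TrackEnsemble, svs: SVSet) -> CountTable:
    """Exhaustive O(points x SVs) counting oracle (no spatial index)."""
    if isinstance(svs, list):
        svs = SVSet.from_svs(svs, ensemble.region)
    if ensemble.n_points == 0 or len(svs) == 0:
        return _empty_table(svs, ensemble)
    pts = ensemble.points
    sv_idx, prim_idx, nus = [], [], []
    for i in range(len(svs)):
        d = pts - svs.centers[i]
        proj = d @ svs.axes[i]
        perp2 = np.einsum("ij,ij->i", d, d) - proj**2
        inside = (np.abs(proj) <= svs.length / 2.0) & (
            perp2 <= (svs.diameter / 2.0) ** 2 + 1e-12
        )
        if not inside.any():
            continue
        counts = np.bincount(ensemble.primary_index[inside])
        pids = np.nonzero(counts)[0]
        sv_idx.append(np.full(len(pids), i, dtype=np.int64))
        prim_idx.append(pids.astype(np.int64))
        nus.append(counts[pids].astype(np.int64))
    if not sv_idx:
        return _empty_table(svs, ensemble)
    return CountTable(
        np.concatenate(sv_idx), np.concatenate(prim_idx), np.concatenate(nus),
        len(svs), ensemble.n_primaries,
    )
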