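"""Constrained linear least-squares pencil-beam fluence optimization.

Because the absolute ICSD of the composite field is a fluence-weighted
mixture of the per-beam distributions, the composite descriptors M1, Y_SC and
Y_LC are *linear* in the fluence vector w.  Equalizing a descriptor across
the target voxels is therefore a non-negative linear least-squares problem

    min_w || A w - p 1 ||_2   subject to  w >= 0,

with A the (target voxels x beams) unit-fluence descriptor matrix and p the
prescription level.  Two strategies are provided: uniform mean cluster size
(``uniform_m1``, the nanodosimetric analog of a uniform-dose plan) and
uniform small- and large-cluster yields (``uniform_yields``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sciopt

from .geometry import PlanGeometry
from .icsd import ICSD, DescriptorSet, conditionalize, m1_bio, mix_absolute

__all__ = [
    "DescriptorMatrix",
    "FluenceVector",
    "OptimizationResult",
    "build_descriptor_matrix",
    "solve_bounded_ls",
    "optimize_uniform_m1",
    "optimize_uniform_yields",
    "uniformity_spread",
    "evaluate_plan",
]


@dataclass
class DescriptorMatrix:
    """Unit-fluence descriptors per (voxel, pencil beam)."""

    m1_mat: np.ndarray  # (n_voxels, n_pbs)
    ysc_mat: np.ndarray
    ylc_mat: np.ndarray
    voxel_ids: np.ndarray  # (n_voxels,)
    pb_ids: np.ndarray  # (n_pbs,)
    target_mask: np.ndarray  # (n_voxels,) bool

    def __post_init__(self) -> None:
        self.m1_mat = np.asarray(self.m1_mat, dtype=float)
        self.ysc_mat = np.asarray(self.ysc_mat, dtype=float)
        self.ylc_mat = np.asarray(self.ylc_mat, dtype=float)
        self.voxel_ids = np.asarray(self.voxel_ids)
        self.pb_ids = np.asarray(self.pb_ids)
        self.target_mask = np.asarray(self.target_mask, dtype=bool)
        shape = self.m1_mat.shape
        if self.ysc_mat.shape != shape or self.ylc_mat.shape != shape:
            raise ValueError("descriptor matrices must share one shape")
        if shape != (len(self.voxel_ids), len(self.pb_ids)):
            raise ValueError("matrix shape does not match voxel/beam ids")
        if len(self.target_mask) != len(self.voxel_ids):
            raise ValueError("target mask length mismatch")
        if not self.target_mask.any():
            raise ValueError("at least one target voxel required")
        for mat in (self.m1_mat, self.ysc_mat, self.ylc_mat):
            if np.any(mat < 0):
                raise ValueError("descriptor entries must be non-negative")


@dataclass
class FluenceVector:
    """Non-negative per-beam fluence weights (the optimization unknowns)."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < 0):
            raise ValueError("fluences must be non-negative")


@dataclass
class OptimizationResult:
    """Optimized fluences and the recomputed plan-quality report."""

    fluences: FluenceVector
    objective: str
    residual_norm: float
    achieved: dict[str, np.ndarray]  # per-voxel composite descriptors
    converged: bool
    uniformity: dict[str, float]  # percent (max-min)/min spreads over target
    prescription: dict = field(default_factory=dict)


def build_descriptor_matrix(
    plan: PlanGeometry, descriptors: dict[tuple[int, int], DescriptorSet]
) -> DescriptorMatrix:
    """Assemble per-(voxel, beam) unit-fluence descriptors into matrices.

    `descriptors` maps (pb_id, voxel_index) to a depth-averaged
    :class:`~nanoplan.icsd.DescriptorSet`.  Normal-tissue voxels are included
    with ``target_mask`` False.
    """
    voxel_ids = np.array([v.index for v in plan.voxels])
    pb_ids = np.array([b.id for b in plan.beams])
    shape = (len(voxel_ids), len(pb_ids))
    m1_mat = np.zeros(shape)
    ysc_mat = np.zeros(shape)
    ylc_mat = np.zeros(shape)
    for j, vox in enumerate(plan.voxels):
        for i, beam in enumerate(plan.beams):
            try:
                d = descriptors[(beam.id, vox.index)]
            except KeyError:
                raise ValueError(
                    f"missing descriptors for pencil beam {beam.id}, voxel {vox.index}"
                ) from None
            m1_mat[j, i] = d.m1
            ysc_mat[j, i] = d.y_sc
            ylc_mat[j, i] = d.y_lc
    return DescriptorMatrix(
        m1_mat, ysc_mat, ylc_mat, voxel_ids, pb_ids,
        np.array([v.is_target for v in plan.voxels]),
    )


def solve_bounded_ls(A, b, lower: float = 0.0, upper: float = np.inf) -> np.ndarray:
    """argmin ||Aw - b||_2 subject to lower <= w <= upper (deterministic).

    The default non-negativity-only problem uses the Lawson-Hanson active-set
    solver; general bounds fall back to a trust-region solver.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    if A.ndim != 2 or A.shape[0] < 1 or A.shape[1] < 1:
        raise ValueError("A must be a non-empty 2-D matrix")
    if b.shape != (A.shape[0],):
        raise ValueError(f"b has shape {b.shape}, expected ({A.shape[0]},)")
    if lower == 0.0 and np.isposinf(upper):
        w, _ = sciopt.nnls(A, b)
        return w
    res = sciopt.lsq_linear(A, b, bounds=(lower, upper), tol=1e-14)
    return res.x


#: Relative ridge weight selecting the minimum-norm solution among exact
#: fits of underdetermined fluence problems (deterministic tie-break; the
#: residual perturbation is O(ridge^2)).
_RIDGE = 1e-6


def _solve_min_norm(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Bounded LS with a tiny Tikhonov term: picks the minimum-norm
    non-negative solution when the fit is degenerate (e.g. more beams than
    target constraints), instead of an arbitrary sparse vertex."""
    eps = _RIDGE * float(np.abs(A).mean())
    A_aug = np.vstack([A, eps * np.eye(A.shape[1])])
    b_aug = np.concatenate([b, np.zeros(A.shape[1])])
    return solve_bounded_ls(A_aug, b_aug)


def uniformity_spread(values, mask=None) -> float:
    """Percent spread 100 * (max - min) / min over the masked entries."""
    values = np.asarray(values, dtype=float)
    if mask is not None:
        values = values[np.asarray(mask, dtype=bool)]
    if len(values) == 0:
        raise ValueError("no values to compare")
    vmin, vmax = values.min(), values.max()
    if vmin <= 0:
        raise ValueError("spread undefined for non-positive minimum")
    return float(100.0 * (vmax - vmin) / vmin)


def _composites(dm: DescriptorMatrix, w: np.ndarray) -> dict[str, np.ndarray]:
    out = {
        "m1": dm.m1_mat @ w,
        "y_sc": dm.ysc_mat @ w,
        "y_lc": dm.ylc_mat @ w,
    }
    tot = out["y_sc"] + out["y_lc"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["rel_y_sc"] = np.where(tot > 0, out["y_sc"] / tot, np.nan)
        out["rel_y_lc"] = np.where(tot > 0, out["y_lc"] / tot, np.nan)
    return out


def _spreads(achieved: dict[str, np.ndarray], mask: np.ndarray) -> dict[str, float]:
    out = {}
    for key in ("m1", "y_sc", "y_lc"):
        try:
            out[key] = uniformity_spread(achieved[key], mask)
        except ValueError:
            out[key] = float("nan")
    return out


def optimize_uniform_m1(
    dm: DescriptorMatrix,
    prescription: float | str = "auto",
    uniformity_tol: float = 2.0,
) -> OptimizationResult:
    """Equalize the composite mean cluster size M1 over the target voxels.

    The ``auto`` prescription is the target-voxel mean of the unit-fluence
    composite M1, making the optimization a pure re-balancing of the field.
    """
    A = dm.m1_mat[dm.target_mask]
    if not A.any():
        raise ValueError("no beam reaches any target voxel (all-zero target rows)")
    if np.any(~A.any(axis=1)):
        bad = dm.voxel_ids[dm.target_mask][~A.any(axis=1)]
        raise ValueError(f"target voxel(s) {bad.tolist()} unreachable by any beam")
    p = float(A.sum(axis=1).mean()) if prescription == "auto" else float(prescription)
    b = np.full(A.shape[0], p)
    w = _solve_min_norm(A, b)
    achieved = _composites(dm, w)
    spreads = _spreads(achieved, dm.target_mask)
    return OptimizationResult(
        fluences=FluenceVector(w),
        objective="uniform_m1",
        residual_norm=float(np.linalg.norm(A @ w - b)),
        achieved=achieved,
        converged=bool(spreads["m1"] < uniformity_tol),
        uniformity=spreads,
        prescription={"m1": p},
    )


def optimize_uniform_yields(
    dm: DescriptorMatrix,
    p_sc: float | str = "auto",
    p_lc: float | str = "auto",
    balance: tuple[float, float] = (1.0, 1.0),
    uniformity_tol: float = 2.0,
) -> OptimizationResult:
    """Equalize the small- and large-cluster yields simultaneously.

    The two row blocks are scaled by the mean unit-fluence composite yields so
    neither cluster class dominates the residual purely by magnitude;
    `balance` applies optional extra weighting.  ``converged`` requires both
    achieved spreads below `uniformity_tol` percent.
    """
    Asc = dm.ysc_mat[dm.target_mask]
    Alc = dm.ylc_mat[dm.target_mask]
    if not Asc.any() or not Alc.any():
        raise ValueError("all-zero target yield rows")
    s_sc = float(Asc.sum(axis=1).mean())
    s_lc = float(Alc.sum(axis=1).mean())
    p_sc_v = s_sc if p_sc == "auto" else float(p_sc)
    p_lc_v = s_lc if p_lc == "auto" else float(p_lc)
    bsc, blc = balance
    A = np.vstack([bsc * Asc / s_sc, blc * Alc / s_lc])
    b = np.concatenate([
        np.full(Asc.shape[0], bsc * p_sc_v / s_sc),
        np.full(Alc.shape[0], blc * p_lc_v / s_lc),
    ])
    w = _solve_min_norm(A, b)
    achieved = _composites(dm, w)
    spreads = _spreads(achieved, dm.target_mask)
    converged = bool(
        spreads["y_sc"] < uniformity_tol and spreads["y_lc"] < uniformity_tol
    )
    return OptimizationResult(
        fluences=FluenceVector(w),
        objective="uniform_yields",
        residual_norm=float(np.linalg.norm(A @ w - b)),
        achieved=achieved,
        converged=converged,
        uniformity=spreads,
        prescription={"y_sc": p_sc_v, "y_lc": p_lc_v},
    )


def evaluate_plan(
    dm: DescriptorMatrix,
    fluences: FluenceVector | np.ndarray,
    icsd_store: dict[tuple[int, int], ICSD] | None = None,
    m1_star_mode: str = "physical",
    uniformity_tol: float = 2.0,
    objective: str = "evaluation",
) -> OptimizationResult:
    """Recompute composite descriptors of a plan for a given fluence vector.

    M1/Y_SC/Y_LC come from linear mixing of the unit-fluence matrices;
    M1*/M1_bio come from the fluence-mixed absolute ICSDs in `icsd_store`
    (keyed by (pb_id, voxel_index)) when provided.
    """
    w = fluences.w if isinstance(fluences, FluenceVector) else np.asarray(fluences, float)
    if np.any(w < 0):
        raise ValueError("fluences must be non-negative")
    if w.sum() <= 0:
        raise ValueError("zero fluence vector: no field to evaluate")
    achieved = _composites(dm, w)
    if icsd_store is not None:
        stars, bios = [], []
        for vox in dm.voxel_ids:
            per_pb = [icsd_store[(int(pb), int(vox))] for pb in dm.pb_ids]
            mixed = mix_absolute(per_pb, w)
            if mixed.probs[1:].sum() <= 1e-12:
                stars.append(np.nan)
                bios.append(np.nan)
                continue
            cond = conditionalize(mixed)
            if m1_star_mode == "paper_literal":
                conds, weights = [], []
                for p in per_pb:
                    if p.probs[1:].sum() > 1e-12:
                        conds.append(conditionalize(p))
                        weights.append(1.0)
                stars.append(
                    float(np.mean([c.nu @ c.probs for c in conds])) if conds else np.nan
                )
            else:
                stars.append(float(cond.nu @ cond.probs))
            bios.append(m1_bio(cond) if cond.probs[2:11].sum() > 0 else np.nan)
        achieved["m1_star"] = np.asarray(stars)
        achieved["m1_bio"] = np.asarray(bios)
    spreads = _spreads(achieved, dm.target_mask)
    return OptimizationResult(
        fluences=FluenceVector(w),
        objective=objective,
        residual_norm=0.0,
        achieved=achieved,
        converged=bool(
            max(spreads[k] for k in ("y_sc", "y_lc")) < uniformity_tol
        ) if np.isfinite(spreads["y_sc"]) and np.isfinite(spreads["y_lc"]) else False,
        uniformity=spreads,
        prescription={"m1_star_mode": m1_star_mode},
    )
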