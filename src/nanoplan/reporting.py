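"""CSV/JSON serialization and figure-style reports of pipeline outputs."""

from __future__ import annotations

import hashlib
import json
import pathlib

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .icsd import ICSD, conditionalize, dose_from_m1, mix_absolute  # noqa: E402
from .optimize import DescriptorMatrix, OptimizationResult  # noqa: E402

__all__ = [
    "provenance",
    "write_descriptor_matrices",
    "read_descriptor_matrices",
    "write_icsd_store",
    "read_icsd_store",
    "write_result",
    "plot_icsd_panels",
    "plot_descriptor_profiles",
]


def provenance(config_like: dict) -> dict:
    """Provenance record (config hash + fields) embedded in every output."""
    blob = json.dumps(config_like, sort_keys=True, default=str)
    return {"config_sha1": hashlib.sha1(blob.encode()).hexdigest(), "config": config_like}


def _matrix_frame(mat: np.ndarray, dm: DescriptorMatrix) -> pd.DataFrame:
    return pd.DataFrame(
        mat,
        index=pd.Index(dm.voxel_ids, name="voxel"),
        columns=[f"pb_{i}" for i in dm.pb_ids],
    )


def write_descriptor_matrices(dm: DescriptorMatrix, outdir) -> None:
    """One CSV per descriptor (voxels x beams) plus the target mask."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, mat in (("m1", dm.m1_mat), ("y_sc", dm.ysc_mat), ("y_lc", dm.ylc_mat)):
        _matrix_frame(mat, dm).to_csv(outdir / f"{name}_matrix.csv")
    pd.DataFrame(
        {"voxel": dm.voxel_ids, "is_target": dm.target_mask.astype(int)}
    ).to_csv(outdir / "voxels.csv", index=False)


def read_descriptor_matrices(outdir) -> DescriptorMatrix:
    outdir = pathlib.Path(outdir)
    mats = {}
    for name in ("m1", "y_sc", "y_lc"):
        frame = pd.read_csv(outdir / f"{name}_matrix.csv", index_col="voxel")
        mats[name] = frame
    vox = pd.read_csv(outdir / "voxels.csv")
    frame = mats["m1"]
    pb_ids = np.array([int(c.split("_", 1)[1]) for c in frame.columns])
    return DescriptorMatrix(
        mats["m1"].to_numpy(),
        mats["y_sc"].to_numpy(),
        mats["y_lc"].to_numpy(),
        frame.index.to_numpy(),
        pb_ids,
        vox["is_target"].to_numpy(dtype=bool),
    )


def write_icsd_store(store: dict[tuple[int, int], ICSD], path) -> None:
    """Long-format CSV of per-(beam, voxel) absolute ICSDs."""
    rows = []
    for (pb, vox), icsd in sorted(store.items()):
        for nu, p in enumerate(icsd.probs):
            rows.append((pb, vox, nu, p, icsd.n_samples))
    pd.DataFrame(
        rows, columns=["pb_id", "voxel", "nu", "prob", "n_samples"]
    ).to_csv(path, index=False)


def read_icsd_store(path) -> dict[tuple[int, int], ICSD]:
    table = pd.read_csv(path)
    store = {}
    for (pb, vox), sub in table.groupby(["pb_id", "voxel"]):
        sub = sub.sort_values("nu")
        store[(int(pb), int(vox))] = ICSD(
            sub["prob"].to_numpy(), "absolute", int(sub["n_samples"].iloc[0])
        )
    return store


def write_result(result: OptimizationResult, dm: DescriptorMatrix, outdir,
                 extra_meta: dict | None = None) -> None:
    """Fluences, per-voxel achieved descriptors and a JSON run summary."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"pb_id": dm.pb_ids, "fluence": result.fluences.w}
    ).to_csv(outdir / "fluences.csv", index=False)
    achieved = pd.DataFrame({"voxel": dm.voxel_ids, "is_target": dm.target_mask})
    for key, vals in result.achieved.items():
        achieved[key] = vals
    achieved["dose_Gy"] = [dose_from_m1(v) for v in result.achieved["m1"]]
    achieved.to_csv(outdir / "achieved.csv", index=False)
    summary = {
        "objective": result.objective,
        "residual_norm": result.residual_norm,
        "converged": result.converged,
        "uniformity_percent": result.uniformity,
        "prescription": result.prescription,
    }
    if extra_meta:
        summary.update(extra_meta)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)


def plot_icsd_panels(
    store: dict[tuple[int, int], ICSD],
    voxel_ids,
    weights,
    pb_ids,
    path,
    nu_show: int = 12,
) -> None:
    """Composite absolute and conditional ICSD panels, one curve per voxel.

    The zero bin of the absolute panel is suppressed (its frequency dwarfs
    every cluster bin).
    """
    fig, (ax_abs, ax_cond) = plt.subplots(1, 2, figsize=(10, 4))
    for vox in voxel_ids:
        per_pb = [store[(int(pb), int(vox))] for pb in pb_ids]
        mixed = mix_absolute(per_pb, weights)
        nu = np.arange(1, nu_show + 1)
        ax_abs.plot(nu, mixed.probs[1 : nu_show + 1], marker="o", label=f"voxel {vox}")
        if mixed.probs[1:].sum() > 1e-12:
            cond = conditionalize(mixed)
            star = float(cond.nu @ cond.probs)
            ax_cond.plot(
                nu, cond.probs[1 : nu_show + 1], marker="o",
                label=f"voxel {vox} (M1*={star:.2f})",
            )
    for ax, title in ((ax_abs, "absolute (zero bin not shown)"), (ax_cond, "conditional")):
        ax.set_yscale("log")
        ax.set_xlabel(r"cluster size $\nu$")
        ax.set_ylabel(r"P($\nu$)")
        ax.set_title(title)
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_descriptor_profiles(result: OptimizationResult, dm: DescriptorMatrix, path) -> None:
    """Composite descriptors versus voxel index for an optimized plan."""
    keys = [k for k in ("m1", "y_sc", "y_lc", "rel_y_sc", "rel_y_lc", "m1_star", "m1_bio")
            if k in result.achieved]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    x = dm.voxel_ids
    axes[0].plot(x, result.achieved["m1"], marker="s")
    axes[0].set_ylabel("composite M1")
    axes[1].plot(x, result.achieved["y_sc"], marker="s", label="Y_SC")
    axes[1].plot(x, result.achieved["y_lc"], marker="^", label="Y_LC")
    if np.any(result.achieved["y_sc"] > 0) or np.any(result.achieved["y_lc"] > 0):
        axes[1].set_yscale("log")
    axes[1].legend()
    if "rel_y_sc" in keys:
        axes[2].plot(x, result.achieved["rel_y_sc"], marker="s", label="Y_SC / (Y_SC+Y_LC)")
        axes[2].plot(x, result.achieved["rel_y_lc"], marker="^", label="Y_LC / (Y_SC+Y_LC)")
        axes[2].legend()
    for ax in axes:
        ax.set_xlabel("voxel")
    fig.suptitle(f"{result.objective} (converged={result.converged})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
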