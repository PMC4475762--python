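"""Ionization cluster-size distributions (ICSDs) and nanodosimetric descriptors.

The ICSD is the probability distribution P(nu|Q) of the number of ionizations
nu produced in one sensitive volume per primary particle of radiation quality
Q.  The *absolute* ICSD is normalized to all primaries (nu >= 0 included);
the *conditional* ICSD is restricted to primaries producing at least one
ionization.

Descriptors:

* ``M1``      -- first moment of the absolute ICSD (mean cluster size).
* ``Y_SC``    -- yield of small clusters, P(2) + P(3) (simple-DSB surrogate).
* ``Y_LC``    -- yield of large clusters, sum of P(4..10) (complex-DSB
  surrogate); clusters above ten ionizations are excluded.
* ``M1*``     -- first moment of the composite conditional ICSD.
* ``M1_bio``  -- conditional mean restricted to nu in [2, 10].
* ``D = M1 * W / m`` converts mean cluster size to absorbed dose, with W the
  mean energy per ion pair and m the SV mass.

Distributions are stored on a fixed grid nu = 0..nu_max (default 30) with
overflow pooled into the top bin; no descriptor reads nu > 10, so pooling is
harmless for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sampling import CountTable

__all__ = [
    "NU_MAX",
    "ICSD",
    "DescriptorSet",
    "DoseConstants",
    "icsd_from_samples",
    "conditionalize",
    "m1",
    "y_sc",
    "y_lc",
    "mix_absolute",
    "m1_star",
    "m1_bio",
    "dose_from_m1",
    "average_depths",
    "descriptor_set",
    "WATER_SV_MASS_KG",
]

NU_MAX = 30
_NORM_TOL = 1e-12

#: Mass (kg) of a 2 nm diameter x 16 nm length liquid-water cylinder.
WATER_SV_MASS_KG = float(np.pi * (1e-9) ** 2 * 16e-9 * 1000.0)

_EV_TO_J = 1.602176634e-19


@dataclass
class ICSD:
    """A discrete cluster-size distribution on nu = 0..nu_max."""

    probs: np.ndarray
    kind: str  # "absolute" or "conditional"
    n_samples: int = 0
    quality_tag: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1 or len(self.probs) < 11:
            raise ValueError("probs must be a 1-D vector covering nu >= 10")
        if np.any(self.probs < -_NORM_TOL):
            raise ValueError("negative probabilities")
        if self.kind not in ("absolute", "conditional"):
            raise ValueError(f"unknown ICSD kind {self.kind!r}")
        total = self.probs.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ICSD not normalized (sum = {total})")
        # exact renormalization keeps the invariant at 1e-12 after chained ops
        self.probs = self.probs / total
        if self.kind == "conditional" and self.probs[0] != 0.0:
            raise ValueError("conditional ICSD must have probs[0] == 0")

    @property
    def nu_max(self) -> int:
        return len(self.probs) - 1

    @property
    def nu(self) -> np.ndarray:
        return np.arange(len(self.probs))


@dataclass
class DescriptorSet:
    """Per-cell nanodosimetric descriptors (unit fluence unless noted)."""

    m1: float
    y_sc: float
    y_lc: float
    m1_star: float | None = None
    m1_bio: float | None = None

    def __post_init__(self) -> None:
        if self.m1 < 0 or not (0 <= self.y_sc <= 1) or not (0 <= self.y_lc <= 1):
            raise ValueError("descriptor out of range")
        if self.m1_star is not None and self.m1_star < 1 - 1e-12:
            raise ValueError("m1_star must be >= 1")
        if self.m1_bio is not None and not (2 - 1e-12 <= self.m1_bio <= 10 + 1e-12):
            raise ValueError("m1_bio must lie in [2, 10]")


@dataclass(frozen=True)
class DoseConstants:
    """Constants converting mean cluster size to absorbed dose."""

    W_eV: float = 30.0  # mean energy per ion pair
    sv_mass_kg: float = WATER_SV_MASS_KG

    def __post_init__(self) -> None:
        if self.W_eV <= 0 or self.sv_mass_kg <= 0:
            raise ValueError("dose constants must be positive")


# -- construction ------------------------------------------------------------


def icsd_from_samples(
    samples: CountTable | np.ndarray | list,
    n_total_pairs: int | None = None,
    nu_max: int = NU_MAX,
    quality_tag: str = "",
) -> ICSD:
    """Absolute ICSD from per-(SV, primary) cluster sizes.

    `samples` is a :class:`~nanoplan.sampling.CountTable` or an array of nu
    values (zeros may be implicit); `n_total_pairs` supplies the absolute
    normalization (defaults to the CountTable's pair count).  Cluster sizes
    above `nu_max` are pooled into the top bin.
    """
    if isinstance(samples, CountTable):
        nu = samples.nu
        if n_total_pairs is None:
            n_total_pairs = samples.n_total_pairs
    else:
        nu = np.asarray(
            [s.nu if hasattr(s, "nu") else s for s in samples]
            if isinstance(samples, list)
            else samples,
            dtype=np.int64,
        )
    if not n_total_pairs:
        raise ValueError("n_total_pairs must be a positive integer")
    nu = nu[nu > 0]
    if len(nu) > n_total_pairs:
        raise ValueError("more samples than total pairs")
    counts = np.bincount(np.minimum(nu, nu_max), minlength=nu_max + 1).astype(float)
    counts[0] = n_total_pairs - len(nu)
    return ICSD(counts / n_total_pairs, "absolute", int(n_total_pairs), quality_tag)


def conditionalize(p: ICSD) -> ICSD:
    """Conditional ICSD: renormalize to primaries with at least one
    ionization (idempotent)."""
    if p.kind == "conditional":
        return p
    probs = p.probs.copy()
    probs[0] = 0.0
    # normalize by the explicit tail mass: algebraically 1 - P(0), but immune
    # to cancellation when P(0) is within float epsilon of 1
    tail = probs.sum()
    if tail <= 1e-12:
        raise ValueError("no ionizing events: P(0) = 1 has no conditional ICSD")
    return ICSD(probs / tail, "conditional", p.n_samples, p.quality_tag)


# -- descriptors -------------------------------------------------------------


def _require(p: ICSD, kind: str) -> None:
    if p.kind != kind:
        raise ValueError(f"expected {kind} ICSD, got {p.kind}")


def m1(p: ICSD) -> float:
    """Mean absolute cluster size: first moment of the absolute ICSD."""
    _require(p, "absolute")
    return float(p.nu @ p.probs)


def y_sc(p: ICSD) -> float:
    """Yield of small clusters (nu = 2 or 3)."""
    _require(p, "absolute")
    return float(p.probs[2] + p.probs[3])


def y_lc(p: ICSD) -> float:
    """Yield of large clusters (nu = 4..10; larger clusters excluded)."""
    _require(p, "absolute")
    return float(p.probs[4:11].sum())


def mix_absolute(icsds: list[ICSD], weights) -> ICSD:
    """Fluence-weighted mixture of absolute ICSDs.

    The composite-field distribution: probs = sum_i w_i p_i / sum_i w_i.
    Distributions of different lengths are zero-padded to a common grid.
    """
    if not icsds:
        raise ValueError("empty ICSD list")
    for p in icsds:
        _require(p, "absolute")
    w = np.asarray(weights, dtype=float)
    if len(w) != len(icsds):
        raise ValueError("weights length mismatch")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    width = max(len(p.probs) for p in icsds)
    probs = np.zeros(width)
    for wi, p in zip(w, icsds):
        probs[: len(p.probs)] += wi * p.probs
    n = int(sum(p.n_samples for p in icsds))
    return ICSD(probs / w.sum(), "absolute", n)


def m1_star(
    conditionals: list[ICSD],
    weights=None,
    mode: str = "paper_literal",
    zero_fractions=None,
) -> float:
    """First moment of the composite conditional ICSD.

    ``paper_literal`` sums the per-beam conditional ICSDs with the given
    weights (unit weights by default) and normalizes by the summed mass.
    ``physical`` instead weights each conditional by ``w_i * (1 - P_i(0))``
    (requires `zero_fractions`), which equals the conditional of the
    fluence-mixed absolute ICSD.
    """
    if not conditionals:
        raise ValueError("empty ICSD list")
    for p in conditionals:
        _require(p, "conditional")
    w = np.ones(len(conditionals)) if weights is None else np.asarray(weights, float)
    if mode == "physical":
        if zero_fractions is None:
            raise ValueError("physical mode requires zero_fractions (per-beam P(0))")
        w = w * (1.0 - np.asarray(zero_fractions, dtype=float))
    elif mode != "paper_literal":
        raise ValueError(f"unknown m1_star mode {mode!r}")
    if np.any(w < 0):
        raise ValueError("negative effective weights")
    if w.sum() <= 0:
        raise ValueError("all-zero effective weights")
    num = sum(wi * float(p.nu @ p.probs) for wi, p in zip(w, conditionals))
    return float(num / w.sum())


def m1_bio(composite_conditional: ICSD) -> float:
    """Biologically effective mean cluster size: conditional mean over
    nu in [2, 10]."""
    _require(composite_conditional, "conditional")
    p = composite_conditional.probs
    window = p[2:11]
    mass = window.sum()
    if mass <= 0:
        raise ValueError("no probability mass in the nu = 2..10 window")
    return float(np.arange(2, 11) @ window / mass)


def dose_from_m1(m1_value: float, constants: DoseConstants | None = None) -> float:
    """Absorbed dose (Gy) deposited per mean cluster size: D = M1 * W / m."""
    constants = constants or DoseConstants()
    return float(m1_value * constants.W_eV * _EV_TO_J / constants.sv_mass_kg)


def average_depths(per_depth):
    """Unweighted arithmetic mean over scoring depths.

    Accepts floats, ICSDs (averaged bin-wise, then renormalized against
    numerical drift) or DescriptorSets (averaged field-wise).
    """
    items = list(per_depth)
    if not items:
        raise ValueError("nothing to average")
    first = items[0]
    if isinstance(first, ICSD):
        kinds = {p.kind for p in items}
        if len(kinds) != 1:
            raise ValueError("cannot average mixed ICSD kinds")
        width = max(len(p.probs) for p in items)
        probs = np.zeros(width)
        for p in items:
            probs[: len(p.probs)] += p.probs
        probs /= len(items)
        return ICSD(probs, first.kind, int(np.mean([p.n_samples for p in items])))
    if isinstance(first, DescriptorSet):
        def _mean(attr):
            vals = [getattr(d, attr) for d in items]
            return None if any(v is None for v in vals) else float(np.mean(vals))

        return DescriptorSet(
            m1=float(np.mean([d.m1 for d in items])),
            y_sc=float(np.mean([d.y_sc for d in items])),
            y_lc=float(np.mean([d.y_lc for d in items])),
            m1_star=_mean("m1_star"),
            m1_bio=_mean("m1_bio"),
        )
    return float(np.mean(items))


def descriptor_set(absolute: ICSD) -> DescriptorSet:
    """All descriptors derivable from one absolute ICSD.

    ``m1_star``/``m1_bio`` are None when undefined (no ionizing events, or no
    mass in the 2..10 window).
    """
    _require(absolute, "absolute")
    star = bio = None
    if absolute.probs[1:].sum() > 1e-12:
        cond = conditionalize(absolute)
        star = float(cond.nu @ cond.probs)
        if cond.probs[2:11].sum() > 0:
            bio = m1_bio(cond)
    return DescriptorSet(
        m1=m1(absolute), y_sc=y_sc(absolute), y_lc=y_lc(absolute),
        m1_star=star, m1_bio=bio,
    )
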