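"""Phantom, target and pencil-beam geometry for spread-out Bragg peak plans.

The reference layout is a 20 cm cubic water phantom containing a row of five
cubic target voxels of 5 mm side, flanked by one normal-tissue voxel on each
side.  The target center is shifted 3.75 cm upstream of the phantom center so
that the proximal target face lies 5 cm from the near phantom face.  Each
field consists of monoenergetic Gaussian pencil beams whose Bragg peaks tile
the target in depth.

Coordinates: the beam axis is ``z``; depth is measured in mm from the near
(``z = 0``) phantom face.  Voxel indices are 1-based, increasing with depth.
The plan works directly in range (peak depth) space; no energy-range
calibration is performed.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field
from importlib import resources

import yaml

PARTICLES = ("proton_like", "carbon_like")
ARRANGEMENTS = ("single_field", "opposed_fields")

#: Scoring-position tags inside each voxel, ordered by depth.
DEPTH_TAGS = ("proximal", "central", "distal")


@dataclass(frozen=True)
class Voxel:
    """A cubic scoring voxel on the beam axis."""

    index: int
    center_depth: float  # mm from the near phantom face
    side: float  # mm
    is_target: bool

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("voxel side must be positive")

    @property
    def proximal_face(self) -> float:
        return self.center_depth - self.side / 2.0

    @property
    def distal_face(self) -> float:
        return self.center_depth + self.side / 2.0

    def scoring_depth(self, tag: str) -> float:
        """Depth of one of the three scoring positions (mm).

        The proximal/central/distal scoring slabs sit at 1/6, 1/2 and 5/6 of
        the voxel depth extent.
        """
        offset = {"proximal": -1.0, "central": 0.0, "distal": 1.0}[tag]
        return self.center_depth + offset * self.side / 3.0


@dataclass(frozen=True)
class PencilBeam:
    """A monoenergetic Gaussian pencil beam identified by its peak range."""

    id: int
    field_id: int
    direction: int  # +1 or -1 along the beam (z) axis
    nominal_range: float  # mm of water path to the Bragg peak
    sigma: float  # mm, lateral Gaussian size
    particle: str

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.sigma <= 0 or self.nominal_range <= 0:
            raise ValueError("sigma and nominal_range must be positive")


@dataclass
class PlanGeometry:
    """Phantom, voxel row and pencil-beam arrangement of one plan."""

    phantom_side: float  # mm
    voxels: tuple[Voxel, ...]
    beams: tuple[PencilBeam, ...] = field(default_factory=tuple)
    arrangement: str = "single_field"
    peak_spacing: float = 2.5  # mm

    def __post_init__(self) -> None:
        if self.arrangement not in ARRANGEMENTS:
            raise ValueError(
                f"unsupported arrangement {self.arrangement!r}; "
                f"expected one of {ARRANGEMENTS}"
            )
        depths = [v.center_depth for v in self.voxels]
        if sorted(depths) != depths or len(set(depths)) != len(depths):
            raise ValueError("voxel centers must be strictly increasing in depth")
        if self.phantom_side < self.target_extent:
            raise ValueError("phantom smaller than target extent")

    # -- target bookkeeping -------------------------------------------------

    @property
    def target_voxels(self) -> tuple[Voxel, ...]:
        return tuple(v for v in self.voxels if v.is_target)

    @property
    def target_proximal_face(self) -> float:
        return min(v.proximal_face for v in self.target_voxels)

    @property
    def target_distal_face(self) -> float:
        return max(v.distal_face for v in self.target_voxels)

    @property
    def target_extent(self) -> float:
        return self.target_distal_face - self.target_proximal_face

    # -- beam/depth conversions ---------------------------------------------

    def peak_depth(self, beam: PencilBeam) -> float:
        """Depth (mm, global z) of a beam's Bragg peak."""
        if beam.direction == +1:
            return beam.nominal_range
        return self.phantom_side - beam.nominal_range

    def path_depth(self, beam: PencilBeam, z: float) -> float:
        """Water path traveled by `beam` to reach global depth ``z``."""
        if beam.direction == +1:
            return z
        return self.phantom_side - z


def _valid_spacings(extent: float, max_peaks: int = 20) -> list[float]:
    return [round(extent / k, 6) for k in range(1, max_peaks + 1)]


def assign_bragg_depths(geometry: PlanGeometry, spacing: float) -> PlanGeometry:
    """Return a copy of `geometry` with beams whose peaks tile the target.

    For each field the peaks run from (proximal target face + spacing/2) to
    (distal face - spacing/2); opposed fields place the same peak depths but
    approach from the far phantom face.  `spacing` must divide the target
    extent into an integer number of peaks.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    extent = geometry.target_extent
    n_float = extent / spacing
    n = round(n_float)
    if n < 1 or abs(n_float - n) > 1e-9:
        raise ValueError(
            f"spacing {spacing} mm does not divide the {extent} mm target; "
            f"valid spacings include {_valid_spacings(extent)}"
        )
    particle = geometry.beams[0].particle if geometry.beams else "proton_like"
    sigma = geometry.beams[0].sigma if geometry.beams else 3.0
    z_peaks = [
        geometry.target_proximal_face + spacing / 2.0 + k * spacing for k in range(n)
    ]
    beams: list[PencilBeam] = []
    directions = (+1,) if geometry.arrangement == "single_field" else (+1, -1)
    bid = 1
    for field_id, direction in enumerate(directions, start=1):
        for z in z_peaks:
            rng_mm = z if direction == +1 else geometry.phantom_side - z
            beams.append(
                PencilBeam(
                    id=bid,
                    field_id=field_id,
                    direction=direction,
                    nominal_range=rng_mm,
                    sigma=sigma,
                    particle=particle,
                )
            )
            bid += 1
    return PlanGeometry(
        phantom_side=geometry.phantom_side,
        voxels=geometry.voxels,
        beams=tuple(beams),
        arrangement=geometry.arrangement,
        peak_spacing=spacing,
    )


def build_reference_plan(
    particle: str,
    arrangement: str,
    *,
    phantom_side: float = 200.0,
    voxel_side: float = 5.0,
    n_target_voxels: int = 5,
    target_shift: float = 37.5,
    peak_spacing: float = 2.5,
    sigma: float = 3.0,
) -> PlanGeometry:
    """Build the reference plan: 7 voxels, 10 pencil beams per field.

    Five 5 mm target voxels sit with their proximal face 50 mm deep in a
    200 mm water phantom (center shifted `target_shift` mm upstream of the
    phantom center); one normal-tissue voxel flanks the target on each side.
    """
    if particle not in PARTICLES:
        raise ValueError(f"unsupported particle {particle!r}; expected one of {PARTICLES}")
    if arrangement not in ARRANGEMENTS:
        raise ValueError(
            f"unsupported arrangement {arrangement!r}; expected one of {ARRANGEMENTS}"
        )
    target_center = phantom_side / 2.0 - target_shift
    extent = n_target_voxels * voxel_side
    proximal_face = target_center - extent / 2.0
    voxels: list[Voxel] = []
    # flanking normal-tissue voxel, targets, flanking normal-tissue voxel
    centers = [proximal_face - voxel_side / 2.0] + [
        proximal_face + voxel_side / 2.0 + k * voxel_side for k in range(n_target_voxels)
    ] + [proximal_face + extent + voxel_side / 2.0]
    for i, c in enumerate(centers, start=1):
        voxels.append(
            Voxel(
                index=i,
                center_depth=c,
                side=voxel_side,
                is_target=1 < i < len(centers),
            )
        )
    geometry = PlanGeometry(
        phantom_side=phantom_side,
        voxels=tuple(voxels),
        beams=(
            PencilBeam(
                id=0,
                field_id=1,
                direction=+1,
                nominal_range=target_center,
                sigma=sigma,
                particle=particle,
            ),
        ),
        arrangement=arrangement,
        peak_spacing=peak_spacing,
    )
    return assign_bragg_depths(geometry, peak_spacing)


# -- configuration files ----------------------------------------------------


def plan_from_config(config: dict | str | pathlib.Path) -> PlanGeometry:
    """Build a plan from a YAML config file or an equivalent mapping.

    Recognized keys: phantom_side_cm, voxel_side_mm, n_target_voxels,
    target_shift_cm, arrangement, particle, peak_spacing_mm, pb_sigma_mm.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    required = {"particle", "arrangement"}
    missing = required - set(config)
    if missing:
        raise KeyError(f"plan config missing keys: {sorted(missing)}")
    return build_reference_plan(
        config["particle"],
        config["arrangement"],
        phantom_side=10.0 * config.get("phantom_side_cm", 20.0),
        voxel_side=config.get("voxel_side_mm", 5.0),
        n_target_voxels=config.get("n_target_voxels", 5),
        target_shift=10.0 * config.get("target_shift_cm", 3.75),
        peak_spacing=config.get("peak_spacing_mm", 2.5),
        sigma=config.get("pb_sigma_mm", 3.0),
    )


def reference_config(name: str) -> dict:
    """Load a packaged reference plan config (``reference_proton`` or
    ``reference_carbon``)."""
    ref = resources.files("nanoplan.configs").joinpath(f"{name}.yaml")
    return yaml.safe_load(ref.read_text())
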