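"""Virtual cutting-plane margin analysis.

The core quantitative idea of the study: a tracked pointer defines a
virtual cutting plane; a 30 x 11 mm area starting at the pointer tip is
isolated from that plane; every sampled point is scored by its minimal
(signed) distance to the tumor and to the internal carotid artery (ICA)
and assigned one of nine zone codes; the per-plane zone distribution and
a set of plane-level flags (intratumoral, ICA damaged, danger zone) are
the analysis units that the group statistics compare.

Zone codes and boundaries (distances in mm; d <= 0 means inside):

==== ============================  =========================
code ICA distance                   tumor distance
==== ============================  =========================
R    d_ica <= 0                     any
O1   0 < d_ica <= 2                 d_t <= 0
O2   0 < d_ica <= 2                 0 < d_t < 5
O3   0 < d_ica <= 2                 5 <= d_t <= 10
O4   0 < d_ica <= 2                 d_t > 10
Y1   d_ica > 2                      d_t <= 0
Y2   d_ica > 2                      0 < d_t < 5
G    d_ica > 2                      5 <= d_t <= 10
B    d_ica > 2                      d_t > 10
==== ============================  =========================

Boundary convention: an adequate ICA distance is strictly greater than
2 mm (so d_ica = 2 is still orange), and the 5-10 mm tumor band is
closed (d_t = 5 and d_t = 10 are both G).  One convention, applied
everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import DistanceField

__all__ = [
    "ZONE_CODES",
    "PointerPose",
    "PlaneSamplingSpec",
    "ZoneRule",
    "MarginPlaneMap",
    "ZoneSummary",
    "classify_point",
    "classify_points",
    "isolate_area",
    "evaluate_plane",
    "summarize_plane",
    "evaluate_alert",
    "render_colormap",
]

ZONE_CODES = ("R", "O1", "O2", "O3", "O4", "Y1", "Y2", "G", "B")

ANGULATIONS = (0, 30, 45, 60, 90)


@dataclass(frozen=True)
class PointerPose:
    """Tracked-tool pose defining the virtual cutting plane.

    The plane contains ``tip`` and ``shaft_axis``; ``roll`` (degrees,
    about the shaft) fixes the in-plane lateral direction and hence the
    plane normal.
    """

    tip: np.ndarray
    shaft_axis: np.ndarray
    roll: float = 0.0
    angulation: int = 45
    approach: str = "bilateral"
    scope: str = "0"
    breach_unresolved: bool = False

    def __post_init__(self):
        tip = np.asarray(self.tip, dtype=float)
        axis = np.asarray(self.shaft_axis, dtype=float)
        if tip.shape != (3,) or axis.shape != (3,):
            raise ValueError("tip and shaft_axis must be 3-vectors")
        n = np.linalg.norm(axis)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("shaft_axis must be a unit vector")
        if self.angulation not in ANGULATIONS:
            raise ValueError(f"angulation must be one of {ANGULATIONS}")
        object.__setattr__(self, "tip", tip)
        object.__setattr__(self, "shaft_axis", axis / n)

    @property
    def lateral_axis(self) -> np.ndarray:
        """In-plane axis orthogonal to the shaft, set by ``roll``.

        ``roll = 0`` picks the reference direction obtained by projecting
        a fixed world seed onto the plane orthogonal to the shaft;
        rotating ``roll`` by 180 degrees negates it.
        """
        seed = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(seed, self.shaft_axis)) > 0.9:
            seed = np.array([1.0, 0.0, 0.0])
        ref = seed - np.dot(seed, self.shaft_axis) * self.shaft_axis
        ref /= np.linalg.norm(ref)
        other = np.cross(self.shaft_axis, ref)
        a = np.deg2rad(self.roll)
        return np.cos(a) * ref + np.sin(a) * other

    @property
    def plane_normal(self) -> np.ndarray:
        return np.cross(self.shaft_axis, self.lateral_axis)


@dataclass(frozen=True)
class PlaneSamplingSpec:
    """Sampling lattice of the isolated area (defaults 30 x 11 mm, 0.5 mm)."""

    length: float = 30.0
    half_width: float = 5.5
    step: float = 0.5

    def __post_init__(self):
        if min(self.length, self.half_width, self.step) <= 0:
            raise ValueError("length, half_width and step must be positive")
        if self.step > min(self.length, self.half_width):
            raise ValueError("step must not exceed length or half_width")

    @property
    def n_length(self) -> int:
        return int(np.floor(self.length / self.step)) + 1

    @property
    def n_width(self) -> int:
        return 2 * int(np.floor(self.half_width / self.step)) + 1


@dataclass(frozen=True)
class ZoneRule:
    """Distance thresholds of the nine-way classification (mm)."""

    ica_danger: float = 2.0  # adequate ICA distance is > this
    tumor_near: float = 5.0  # clear band lower edge (closed)
    tumor_far: float = 10.0  # clear band upper edge (closed)

    def __post_init__(self):
        if not (0 < self.ica_danger and 0 < self.tumor_near < self.tumor_far):
            raise ValueError("thresholds must be positive and ordered")


def classify_points(d_ica, d_tumor, rule: ZoneRule = ZoneRule()) -> np.ndarray:
    """Vectorized zone assignment; every finite pair maps to exactly one code."""
    shape = np.shape(d_ica)
    di = np.atleast_1d(np.asarray(d_ica, dtype=float)).ravel()
    dt = np.atleast_1d(np.asarray(d_tumor, dtype=float)).ravel()
    if np.any(~np.isfinite(di)) or np.any(~np.isfinite(dt)):
        raise ValueError("distances must be finite")
    tumor_band = np.select(
        [dt <= 0.0, dt < rule.tumor_near, dt <= rule.tumor_far],
        [0, 1, 2],
        default=3,
    )
    out = np.array(["Y1", "Y2", "G", "B"])[tumor_band]
    orange = (di > 0.0) & (di <= rule.ica_danger)
    out[orange] = np.array(["O1", "O2", "O3", "O4"])[tumor_band[orange]]
    out[di <= 0.0] = "R"
    return out.reshape(shape)


def classify_point(d_ica: float, d_tumor: float, rule: ZoneRule = ZoneRule()) -> str:
    return str(classify_points(np.array(d_ica), np.array(d_tumor), rule)[()])


def isolate_area(pose: PointerPose, spec: PlaneSamplingSpec = PlaneSamplingSpec()) -> np.ndarray:
    """Coplanar lattice of the isolated area, shape (n_length, n_width, 3).

    Axis 0 runs from the tip along the shaft (0..length); axis 1 spans
    the lateral direction (-half_width..+half_width).
    """
    u = np.arange(spec.n_length) * spec.step
    half_n = (spec.n_width - 1) // 2
    v = (np.arange(spec.n_width) - half_n) * spec.step
    return (
        pose.tip[None, None, :]
        + u[:, None, None] * pose.shaft_axis[None, None, :]
        + v[None, :, None] * pose.lateral_axis[None, None, :]
    )


@dataclass
class MarginPlaneMap:
    """Per-point distances and zone codes over the isolated area."""

    grid: np.ndarray  # (n_l, n_w, 3) world mm
    d_tumor: np.ndarray  # (n_l, n_w) mm
    d_ica: np.ndarray  # (n_l, n_w) mm
    zone: np.ndarray  # (n_l, n_w) codes
    rule: ZoneRule = field(default_factory=ZoneRule)

    def to_frame(self):
        """Long-format table (i, j, x, y, z, d_tumor, d_ica, zone)."""
        import pandas as pd

        nl, nw = self.d_tumor.shape
        ii, jj = np.meshgrid(np.arange(nl), np.arange(nw), indexing="ij")
        return pd.DataFrame(
            {
                "i": ii.ravel(),
                "j": jj.ravel(),
                "x": self.grid[..., 0].ravel(),
                "y": self.grid[..., 1].ravel(),
                "z": self.grid[..., 2].ravel(),
                "d_tumor": self.d_tumor.ravel(),
                "d_ica": self.d_ica.ravel(),
                "zone": self.zone.ravel(),
            }
        )


def evaluate_plane(
    pose: PointerPose,
    tumor_field: DistanceField,
    ica_field: DistanceField,
    spec: PlaneSamplingSpec = PlaneSamplingSpec(),
    rule: ZoneRule = ZoneRule(),
) -> MarginPlaneMap:
    """Sample both distance fields over the isolated area and classify.

    Distances are trilinear interpolations of the voxel signed-distance
    fields; any sample outside a field's voxel-center lattice raises,
    naming the offending point (no silent truncation).
    """
    grid = isolate_area(pose, spec)
    flat = grid.reshape(-1, 3)
    d_t = tumor_field.sample(flat).reshape(grid.shape[:2])
    d_i = ica_field.sample(flat).reshape(grid.shape[:2])
    return MarginPlaneMap(grid=grid, d_tumor=d_t, d_ica=d_i, zone=classify_points(d_i, d_t, rule), rule=rule)


@dataclass(frozen=True)
class ZoneSummary:
    """Zone fractions plus the study's plane-level flags."""

    fractions: dict
    intratumoral: bool
    ica_damaged: bool
    danger_zone: bool

    @property
    def adequate_margin(self) -> bool:
        return not self.intratumoral

    @property
    def ica_adequate(self) -> bool:
        return not (self.ica_damaged or self.danger_zone)


def summarize_plane(plane_map: MarginPlaneMap) -> ZoneSummary:
    """Zone fractions (sum to 1) and flags for one delineation.

    intratumoral: any point with d_tumor <= 0; ica_damaged: any point
    with d_ica <= 0; danger_zone: some point with 0 < d_ica <= 2 mm and
    none at <= 0.  Exactly one of damaged / danger / adequate holds.
    """
    n = plane_map.zone.size
    if n == 0:
        raise ValueError("empty plane map")
    fractions = {code: float(np.sum(plane_map.zone == code)) / n for code in ZONE_CODES}
    damaged = bool(np.any(plane_map.d_ica <= 0.0))
    danger = (not damaged) and bool(np.any(plane_map.d_ica <= plane_map.rule.ica_danger))
    return ZoneSummary(
        fractions=fractions,
        intratumoral=bool(np.any(plane_map.d_tumor <= 0.0)),
        ica_damaged=damaged,
        danger_zone=danger,
    )


def evaluate_alert(tip, ica_field: DistanceField, margin: float = 2.0) -> str:
    """Alert state at the pointer tip: 'breach', 'proximity' or 'clear'.

    breach if d_ica <= 0, proximity if 0 < d_ica <= margin, else clear;
    this is the value-level counterpart of the study's sonic alarms.
    """
    d = float(ica_field.sample(np.asarray(tip, dtype=float))[0])
    if d <= 0.0:
        return "breach"
    if d <= margin:
        return "proximity"
    return "clear"


ZONE_COLORS = {
    "R": "#d62728",
    "O1": "#8c3d00",
    "O2": "#b35a00",
    "O3": "#e07b00",
    "O4": "#ffa040",
    "Y1": "#b8a400",
    "Y2": "#ffe34d",
    "G": "#2ca02c",
    "B": "#1f77b4",
}


def render_colormap(plane_map: MarginPlaneMap, path, dpi: int = 150) -> None:
    """Color-scaled 30 x 11 mm image of the zone map (PNG, byte-stable).

    One raster cell per grid point; fixed zone-color table with legend
    and mm axes.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    codes = list(ZONE_CODES)
    idx = np.zeros(plane_map.zone.shape, dtype=int)
    for k, code in enumerate(codes):
        idx[plane_map.zone == code] = k
    cmap = ListedColormap([ZONE_COLORS[c] for c in codes])

    nl, nw = plane_map.zone.shape
    length = (nl - 1) * np.linalg.norm(plane_map.grid[1, 0] - plane_map.grid[0, 0]) if nl > 1 else 1.0
    width = (nw - 1) * np.linalg.norm(plane_map.grid[0, 1] - plane_map.grid[0, 0]) if nw > 1 else 1.0

    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.imshow(
        idx.T,
        cmap=cmap,
        vmin=0,
        vmax=len(codes) - 1,
        origin="lower",
        extent=(0, length, -width / 2, width / 2),
        interpolation="nearest",
        aspect="equal",
    )
    ax.set_xlabel("along shaft from tip (mm)")
    ax.set_ylabel("lateral (mm)")
    handles = [Patch(color=ZONE_COLORS[c], label=c) for c in codes]
    ax.legend(handles=handles, loc="center left", bbox_to_anchor=(1.01, 0.5), fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=dpi, metadata={"Software": None})
    plt.close(fig)
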