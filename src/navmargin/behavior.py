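"""Stochastic surgeon behavior for the simulated delineation study.

The study asked eight surgeons to delineate the posterior margin (PM)
in three settings: unguided (cross-sectional images only), tumor-guided
(real-time tracked pointer with 3D tumor/carotid rendering) and
carotid-guided (tumor-guided plus a 2-mm proximity alert around the
vessel).  Human placement is emulated as an *ideal* cutting plane --
the mid-gap plane of the local tumor-to-carotid corridor in the
requested PM portion -- perturbed by Gaussian rotational and
translational error whose spread encodes how much guidance the setting
provides.  The carotid-guided alarm becomes a resampling rule: poses
whose sampled area would breach the vessel are redrawn a limited number
of times.

The noise calibration is a stated default, not a claim of fidelity to
human performance; everything asserted about simulated behavior
downstream is ordinal (guided better than unguided), never numeric.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .margins import (
    MarginPlaneMap,
    PlaneSamplingSpec,
    PointerPose,
    ZoneRule,
    classify_points,
    isolate_area,
    summarize_plane,
)
from .phantoms import PhantomModel

__all__ = [
    "BehaviorModel",
    "DEFAULT_BEHAVIORS",
    "TrialRecord",
    "ideal_pose",
    "sample_pointer_pose",
    "evaluate_plane_analytic",
    "simulate_study",
]

SETTINGS = ("unguided", "tumor_guided", "carotid_guided")
PORTIONS = ("superior", "inferior")

# z-band (mm) of the posterior-margin portions; the split plane stands in
# for the inferior aspect of the nasopharyngeal vault, which has no
# synthetic counterpart.
PORTION_SPLIT_Z = 0.0
PORTION_BAND_MM = 18.0


@dataclass(frozen=True)
class BehaviorModel:
    """Placement-noise model for one guidance setting.

    rot_sd in degrees (about the two in-plane axes), trans_sd in mm
    (along the plane normal).  ``max_resample`` only applies to the
    carotid-guided setting, where it models the breach alarm.
    """

    setting: str
    rot_sd: float
    trans_sd: float
    angulation_choices: tuple = (30, 45, 60, 90)
    max_resample: int = 0

    def __post_init__(self):
        if self.setting not in SETTINGS:
            raise ValueError(f"setting must be one of {SETTINGS}")
        if self.rot_sd < 0 or self.trans_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if not set(self.angulation_choices) <= {0, 30, 45, 60, 90}:
            raise ValueError("angulation_choices must be a subset of {0,30,45,60,90}")

    def scaled(self, factor: float) -> "BehaviorModel":
        return replace(self, rot_sd=self.rot_sd * factor, trans_sd=self.trans_sd * factor)


# Default calibration: unguided placement is twice as noisy as guided;
# the carotid-guided setting adds the alarm-driven resampling.
DEFAULT_BEHAVIORS = {
    "unguided": BehaviorModel("unguided", rot_sd=8.0, trans_sd=3.0),
    "tumor_guided": BehaviorModel("tumor_guided", rot_sd=4.0, trans_sd=1.5),
    "carotid_guided": BehaviorModel("carotid_guided", rot_sd=4.0, trans_sd=1.5, max_resample=5),
}


def _portion_band(portion: str):
    if portion == "superior":
        return PORTION_SPLIT_Z, PORTION_SPLIT_Z + PORTION_BAND_MM
    if portion == "inferior":
        return PORTION_SPLIT_Z - PORTION_BAND_MM, PORTION_SPLIT_Z
    raise ValueError(f"portion must be one of {PORTIONS}")


def _pose_from_frame(tip, shaft, normal, angulation=45) -> PointerPose:
    """PointerPose whose plane has the given shaft direction and normal."""
    shaft = np.asarray(shaft, float)
    shaft = shaft / np.linalg.norm(shaft)
    lateral = np.cross(np.asarray(normal, float), shaft)
    lateral /= np.linalg.norm(lateral)
    probe = PointerPose(tip=tip, shaft_axis=shaft, roll=0.0, angulation=angulation)
    ref = probe.lateral_axis
    other = np.cross(shaft, ref)
    roll = np.rad2deg(np.arctan2(np.dot(lateral, other), np.dot(lateral, ref)))
    return PointerPose(tip=tip, shaft_axis=shaft, roll=float(roll), angulation=angulation)


def ideal_pose(model: PhantomModel, portion: str, angulation: int = 45) -> PointerPose:
    """Noise-free reference plane: mid-gap plane of the local corridor.

    Within the portion's z-band, find the carotid centerline point whose
    tumor clearance is smallest, take the common normal direction of the
    two surfaces there, and place the plane halfway across the gap with
    its normal along that direction; the shaft runs in-plane toward the
    portion (superior or inferior).
    """
    cache = getattr(model, "_ideal_pose_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(model, "_ideal_pose_cache", cache)
    if (portion, angulation) in cache:
        return cache[(portion, angulation)]

    lo, hi = _portion_band(portion)
    axis = model.ica_centerline.sample(0.2)
    band = axis[(axis[:, 2] >= lo) & (axis[:, 2] <= hi)]
    if len(band) == 0:
        raise ValueError(f"no carotid centerline in the {portion} portion band")
    d_surf = model.tumor_distance(band)
    k = int(np.argmin(d_surf))
    c = band[k]

    # outward direction of the tumor distance (points from tumor to ICA)
    eps = 1e-3
    grad = np.array(
        [
            (model.tumor_distance(c + e)[0] - model.tumor_distance(c - e)[0]) / (2 * eps)
            for e in np.eye(3) * eps
        ]
    )
    u = grad / np.linalg.norm(grad)
    q_tumor = c - d_surf[k] * u
    q_ica = c - model.ica_radius * u
    tip = 0.5 * (q_tumor + q_ica)

    z_dir = 1.0 if portion == "superior" else -1.0
    shaft = z_dir * np.array([0.0, 0.0, 1.0])
    shaft = shaft - np.dot(shaft, u) * u  # project into the plane
    shaft /= np.linalg.norm(shaft)
    pose = _pose_from_frame(tip, shaft, u, angulation)
    cache[(portion, angulation)] = pose
    return pose


def evaluate_plane_analytic(
    pose: PointerPose,
    model: PhantomModel,
    spec: PlaneSamplingSpec = PlaneSamplingSpec(),
    rule: ZoneRule = ZoneRule(),
) -> MarginPlaneMap:
    """Plane map with distances taken from the analytic phantom geometry.

    Bypasses volume synthesis entirely; used by the behavior sampler and
    wherever the exact geometry (rather than the imaging pipeline) is
    the appropriate reference.
    """
    grid = isolate_area(pose, spec)
    flat = grid.reshape(-1, 3)
    d_t = model.tumor_distance(flat).reshape(grid.shape[:2])
    d_i = model.ica_distance(flat).reshape(grid.shape[:2])
    return MarginPlaneMap(grid=grid, d_tumor=d_t, d_ica=d_i, zone=classify_points(d_i, d_t, rule), rule=rule)


def _perturb(pose: PointerPose, behavior: BehaviorModel, rng) -> PointerPose:
    alpha, beta = np.deg2rad(rng.normal(0.0, behavior.rot_sd, 2))
    shift = rng.normal(0.0, behavior.trans_sd)
    shaft, lateral = pose.shaft_axis, pose.lateral_axis
    rot = Rotation.from_rotvec(alpha * shaft) * Rotation.from_rotvec(beta * lateral)
    new_shaft = rot.apply(shaft)
    new_normal = rot.apply(pose.plane_normal)
    tip = pose.tip + shift * new_normal
    return _pose_from_frame(tip, new_shaft, new_normal, pose.angulation)


def sample_pointer_pose(
    model: PhantomModel,
    behavior: BehaviorModel,
    portion: str,
    rng,
    spec: PlaneSamplingSpec = PlaneSamplingSpec(),
) -> PointerPose:
    """One simulated delineation attempt.

    The ideal mid-gap plane is perturbed by the behavior's rotational
    and translational noise; an angulation is drawn from the behavior's
    choices.  In the carotid-guided setting, poses whose sampled area
    would breach the vessel (any d_ica <= 0: the beeping alarm) are
    redrawn up to ``max_resample`` times; if the budget is exhausted the
    last pose is returned flagged ``breach_unresolved``.
    """
    rng = np.random.default_rng(rng)
    base = ideal_pose(model, portion)
    attempts = behavior.max_resample + 1 if behavior.setting == "carotid_guided" else 1
    pose = None
    for _ in range(attempts):
        angulation = int(rng.choice(behavior.angulation_choices))
        pose = replace(_perturb(base, behavior, rng), angulation=angulation)
        if behavior.setting != "carotid_guided":
            return pose
        d_i = model.ica_distance(isolate_area(pose, spec).reshape(-1, 3))
        if not np.any(d_i <= 0.0):
            return pose
    return replace(pose, breach_unresolved=True)


@dataclass(frozen=True)
class TrialRecord:
    """One delineation: surgeon x preset x setting x portion (x replicate)."""

    surgeon_id: int
    preset_id: str
    setting: str
    portion: str
    replicate: int
    summary: object  # ZoneSummary
    pose: PointerPose

    def to_row(self) -> dict:
        row = {
            "surgeon_id": self.surgeon_id,
            "preset_id": self.preset_id,
            "setting": self.setting,
            "portion": self.portion,
            "replicate": self.replicate,
            "intratumoral": self.summary.intratumoral,
            "ica_damaged": self.summary.ica_damaged,
            "danger_zone": self.summary.danger_zone,
            "angulation": self.pose.angulation,
        }
        for code, frac in self.summary.fractions.items():
            row[f"frac_{code}"] = frac
        return row


def simulate_study(
    models: dict,
    n_surgeons: int = 8,
    behaviors: dict = None,
    seed: int = 0,
    n_replicates: int = 1,
    spec: PlaneSamplingSpec = PlaneSamplingSpec(),
    fields: dict = None,
    surgeon_sd: float = 0.25,
) -> list:
    """Factorial delineation study: surgeon x preset x setting x portion.

    Parameters
    ----------
    models : dict preset_id -> PhantomModel
    behaviors : dict setting -> BehaviorModel (defaults to the package
        calibration)
    fields : optional dict preset_id -> (tumor DistanceField, ica
        DistanceField); when given, plane maps are evaluated against the
        voxel fields (the imaging pipeline route), otherwise against the
        analytic geometry.
    surgeon_sd : sigma of the per-surgeon LogNormal(0, sigma^2) noise
        multiplier emulating heterogeneous experience.

    The run is deterministic under a fixed seed: one named substream per
    (surgeon, preset, setting, portion, replicate) cell, so changing the
    surgeon count does not perturb other cells.
    """
    if not models:
        raise ValueError("need at least one phantom model")
    if n_surgeons < 1:
        raise ValueError("n_surgeons must be >= 1")
    behaviors = behaviors or DEFAULT_BEHAVIORS
    root = np.random.SeedSequence(seed)
    surgeon_rng = np.random.default_rng(root.spawn(1)[0])
    factors = np.exp(surgeon_rng.normal(0.0, surgeon_sd, n_surgeons))

    from .margins import evaluate_plane

    preset_order = sorted(models)
    records = []
    for s in range(n_surgeons):
        for pid in preset_order:
            model = models[pid]
            for setting, behavior in behaviors.items():
                b = behavior.scaled(factors[s])
                for portion in PORTIONS:
                    for rep in range(n_replicates):
                        key = np.random.SeedSequence(
                            entropy=root.entropy,
                            spawn_key=(2, s, preset_order.index(pid), SETTINGS.index(setting), PORTIONS.index(portion), rep),
                        )
                        rng = np.random.default_rng(key)
                        pose = sample_pointer_pose(model, b, portion, rng, spec)
                        if fields is not None:
                            tumor_field, ica_field = fields[pid]
                            plane = evaluate_plane(pose, tumor_field, ica_field, spec)
                        else:
                            plane = evaluate_plane_analytic(pose, model, spec)
                        records.append(
                            TrialRecord(
                                surgeon_id=s,
                                preset_id=pid,
                                setting=setting,
                                portion=portion,
                                replicate=rep,
                                summary=summarize_plane(plane),
                                pose=pose,
                            )
                        )
    return records


def records_to_frame(records):
    import pandas as pd

    return pd.DataFrame([r.to_row() for r in records])
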