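"""Synthetic 6-DOF robotic knee-rig experiment generator.

Emulates the porcine protocol the analysis expects: 14 specimens, axial
loading to 300 N under force control at four flexion angles (30, 60, 90,
120 deg), four medial-meniscal states (intact and 30/60/90 % width inner
resection), three loading cycles per cell, and — after total
meniscectomy — a position-controlled replay of every previously recorded
path while forces are re-measured.  The superposition principle holds by
construction: the recorded minus replayed force at any sample equals the
injected meniscal force vector plus bounded rig noise, and the equality
is exact when all noise terms are disabled.

The rig noise model uses the robot's stated precision as hard bounds:
path reproducibility ±0.006 mm / ±0.03 deg (drawn with magnitude uniform
on [0, bound] and an isotropic random direction, so the bound is never
exceeded), force sensor resolution 0.02 N (quantization), and axial
force-control fluctuation strictly below 5 N (uniform at 80 % of the
bound).

The tissue model is phenomenological: the medial meniscus carries a
fixed share of the axial load (0.373, so that 0.373 x 300 N = 111.9 N
for the intact meniscus), each resection retains a fraction of the
intact meniscal force, and the lost meniscal support tilts the loaded
tibia into additional varus and (at 30 deg flexion) additional external
rotation.  Only the calibration anchors of that model are empirically
grounded; the remaining shape parameters are configuration, not ground
truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .pipeline import STATES, TrialRecording

__all__ = ["RigConfig", "TissueModel", "simulate_experiment", "meniscal_force_vector"]


@dataclass(frozen=True)
class RigConfig:
    """Rig geometry-free protocol and noise configuration.

    Noise parameters are bounds in the units stated by the robot's
    calibration: ``path_noise_trans`` mm, ``path_noise_rot`` degrees,
    ``force_resolution`` N (sensor quantization step), and
    ``control_fluctuation`` N (strict bound on axial force-control
    error).  ``ramp_duration``/``hold_duration``/``sample_rate`` define
    the loading profile: a linear ramp to ``target_load`` followed by a
    hold.
    """

    n_specimens: int = 14
    flexion_angles: tuple[float, ...] = (30.0, 60.0, 90.0, 120.0)
    states: tuple[str, ...] = STATES
    cycles: int = 3
    target_load: float = 300.0
    path_noise_trans: float = 0.006
    path_noise_rot: float = 0.03
    force_resolution: float = 0.02
    control_fluctuation: float = 5.0
    ramp_duration: float = 2.0
    hold_duration: float = 1.0
    sample_rate: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specimens < 2:
            raise ValueError("n_specimens must be >= 2")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.target_load <= 0:
            raise ValueError("target_load must be positive")
        for name in ("path_noise_trans", "path_noise_rot", "force_resolution",
                     "control_fluctuation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ramp_duration <= 0 or self.hold_duration <= 0 or self.sample_rate <= 0:
            raise ValueError("loading profile durations and rate must be positive")
        unknown = set(self.states) - set(STATES)
        if unknown:
            raise ValueError(f"unknown meniscal states: {sorted(unknown)}")

    def no_noise(self) -> "RigConfig":
        """Copy with every rig noise source disabled."""
        return dataclasses.replace(
            self, path_noise_trans=0.0, path_noise_rot=0.0,
            force_resolution=0.0, control_fluctuation=0.0,
        )


@dataclass(frozen=True)
class TissueModel:
    """Phenomenological medial-meniscus load-sharing model.

    Parameters
    ----------
    intact_share
        Fraction of the axial load borne by the intact medial meniscus
        (all flexion angles).  Default 0.373 so the intact in situ force
        under 300 N is 111.9 N.
    retention
        Fraction of the intact meniscal force remaining per state; must
        be non-increasing over the protocol's state order.  The 90 %
        resection retains ~20 % of the intact force; the 30/60 values
        are interpolating defaults.
    varus_gain
        Additional varus (deg) of the loaded tibia at zero retention;
        the increment for a state scales with (1 - retention).
    extrot_offset
        External-rotation shift (deg) of any resected state under load,
        state-width independent.
    extrot_gain_30
        Width-dependent external-rotation gain (deg at zero retention)
        active at 30 deg flexion only.
    specimen_sd
        Between-specimen multiplicative SD on the load share (log-normal
        with unit mean); 0.10 gives an intact-force CV matching the
        ~10 % seen in pilot data.
    trial_sd
        Within-specimen trial-to-trial multiplicative SD on the meniscal
        force magnitude (biological variation, not rig noise).
    align_trial_sd
        Multiplicative trial-to-trial SD on the alignment increments.
    conditioning_drift
        Fractional excess of the meniscal force during conditioning:
        cycles 1 and 2 read high by 2x and 1x this fraction; cycle 3 is
        the settled value.
    intact_varus, intact_extrot, intact_medial, intact_anterior
        Loaded intact alignment relative to the 30-deg-flexion zero
        position (deg / mm); defaults are the pilot's intact values.
    intact_compression
        Joint compression (mm) at full load.
    force_direction
        Direction cosines of the meniscal reaction in the sensor frame
        (normalized at use); predominantly axial with a small medial
        component.  Only the norm is consumed downstream.
    """

    intact_share: float = 0.373
    retention: Mapping[str, float] = field(
        default_factory=lambda: {"intact": 1.0, "w30": 0.85, "w60": 0.50, "w90": 0.20}
    )
    varus_gain: float = 2.0
    extrot_offset: float = 1.5
    extrot_gain_30: float = 1.0
    specimen_sd: float = 0.10
    trial_sd: float = 0.08
    align_trial_sd: float = 0.25
    conditioning_drift: float = 0.004
    intact_varus: float = 6.7
    intact_extrot: float = 7.4
    intact_medial: float = 2.8
    intact_anterior: float = 11.4
    intact_compression: float = 0.3
    force_direction: tuple[float, float, float] = (0.1, 0.0, -0.995)
    shear_fractions: tuple[float, float] = (0.02, -0.01)

    def __post_init__(self) -> None:
        if not 0.0 < self.intact_share < 1.0:
            raise ValueError("intact_share must lie in (0, 1)")
        r = [self.retention[s] for s in STATES if s in self.retention]
        if any(b > a for a, b in zip(r, r[1:])):
            raise ValueError("retention must be non-increasing over state order")
        for name in ("specimen_sd", "trial_sd", "align_trial_sd", "conditioning_drift"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def no_noise(self) -> "TissueModel":
        """Copy with biological variability disabled (deterministic tissue)."""
        return dataclasses.replace(
            self, specimen_sd=0.0, trial_sd=0.0, align_trial_sd=0.0
        )


def meniscal_force_vector(
    state: str,
    angle: float,
    axial_load: float | np.ndarray,
    tissue: TissueModel,
    specimen_effect: float = 1.0,
    trial_effect: float = 1.0,
) -> np.ndarray:
    """Latent meniscal reaction force vector(s), sensor frame, N.

    Magnitude = intact_share x retention(state) x axial_load x
    specimen_effect x trial_effect; direction is the fixed unit vector of
    the tissue model.  ``axial_load`` may be scalar (returns shape (3,))
    or an array of loads (returns shape (n, 3)).
    """
    if state not in tissue.retention:
        raise ValueError(f"unknown meniscal state {state!r}")
    load = np.asarray(axial_load, dtype=float)
    if np.any(load < 0):
        raise ValueError("axial_load must be non-negative")
    direction = np.asarray(tissue.force_direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    mag = (
        tissue.intact_share * tissue.retention[state]
        * load * specimen_effect * trial_effect
    )
    return np.multiply.outer(mag, direction)


def _lognormal_unit_mean(rng: np.random.Generator, sigma: float, size=None):
    """Multiplicative effect with unit mean: exp(sigma z - sigma^2 / 2)."""
    if sigma == 0.0:
        return np.ones(size) if size is not None else 1.0
    return np.exp(sigma * rng.standard_normal(size) - 0.5 * sigma**2)


def _rodrigues(axes: np.ndarray, angles_rad: np.ndarray) -> np.ndarray:
    """Batch rotation matrices from unit axes (n,3) and angles (n,)."""
    n = axes.shape[0]
    K = np.zeros((n, 3, 3))
    K[:, 0, 1], K[:, 0, 2] = -axes[:, 2], axes[:, 1]
    K[:, 1, 0], K[:, 1, 2] = axes[:, 2], -axes[:, 0]
    K[:, 2, 0], K[:, 2, 1] = -axes[:, 1], axes[:, 0]
    s = np.sin(angles_rad)[:, None, None]
    c = (1.0 - np.cos(angles_rad))[:, None, None]
    return np.eye(3) + s * K + c * (K @ K)


def _random_bounded_rotations(
    rng: np.random.Generator, n: int, max_deg: float
) -> np.ndarray:
    """Random small rotations with geodesic angle uniform on [0, max_deg]."""
    if max_deg == 0.0:
        return np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    axes = rng.standard_normal((n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = np.deg2rad(rng.uniform(0.0, max_deg, n))
    return _rodrigues(axes, angles)


def _random_bounded_vectors(
    rng: np.random.Generator, n: int, max_norm: float
) -> np.ndarray:
    """Random vectors with norm uniform on [0, max_norm]."""
    if max_norm == 0.0:
        return np.zeros((n, 3))
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * rng.uniform(0.0, max_norm, n)[:, None]


def _poses_from_jcs_batch(
    flexion: np.ndarray, varus: np.ndarray, ext_rot: np.ndarray,
    medial: np.ndarray, anterior: np.ndarray, distraction: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pose_from_jcs with an identity reference.

    Mirrors kinematics.pose_from_jcs: R = Rx(flex) Ry(-varus) Rz(-ext),
    t = medial e1 - anterior e2 + distraction e3 on the JCS basis.
    """
    a = np.deg2rad(flexion)
    b = np.deg2rad(-varus)
    c = np.deg2rad(-ext_rot)
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    n = a.shape[0]
    R = np.empty((n, 3, 3))
    # R = Rx(a) @ Ry(b) @ Rz(c)
    R[:, 0, 0] = cb * cc
    R[:, 0, 1] = -cb * sc
    R[:, 0, 2] = sb
    R[:, 1, 0] = ca * sc + sa * sb * cc
    R[:, 1, 1] = ca * cc - sa * sb * sc
    R[:, 1, 2] = -sa * cb
    R[:, 2, 0] = sa * sc - ca * sb * cc
    R[:, 2, 1] = sa * cc + ca * sb * sc
    R[:, 2, 2] = ca * cb
    e1 = np.zeros((n, 3))
    e1[:, 0] = 1.0
    e3 = R[:, :, 2]
    e2 = np.cross(e3, e1)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    t = medial[:, None] * e1 - anterior[:, None] * e2 + distraction[:, None] * e3
    return R, t


def _trial_rng(seed: int, s_idx: int, angle: float, st_idx: int, cycle: int,
               phase_tag: int) -> np.random.Generator:
    # keyed stream: independent of how many specimens/angles are simulated
    return np.random.default_rng([seed, 7, s_idx, int(round(angle)), st_idx,
                                  cycle, phase_tag])


def simulate_experiment(
    config: RigConfig, tissue: TissueModel | None = None
) -> list[TrialRecording]:
    """Simulate the full protocol grid and its post-meniscectomy replays.

    For every specimen x flexion angle x state x cycle a force-controlled
    ``recorded`` trial is emitted, together with a position-controlled
    ``replayed`` trial on the identical path with the meniscal force
    removed.  Identical configuration and seed give bit-identical output;
    each trial draws from its own seed-keyed stream, so enlarging the
    grid never perturbs previously generated trials.
    """
    if tissue is None:
        tissue = TissueModel()
    seed = int(config.seed)

    n = int(round((config.ramp_duration + config.hold_duration) * config.sample_rate)) + 1
    times = np.arange(n) / config.sample_rate
    load_frac = np.minimum(times / config.ramp_duration, 1.0)
    commanded = config.target_load * load_frac
    hold = times >= config.ramp_duration

    direction = np.asarray(tissue.force_direction, dtype=float)
    direction /= np.linalg.norm(direction)
    taux, tauy = tissue.shear_fractions
    lever = np.array([0.005, 0.005, 0.0])  # m; sensor offset for moment bookkeeping

    recordings: list[TrialRecording] = []
    for s_idx in range(config.n_specimens):
        specimen = f"S{s_idx + 1:02d}"
        share_eff = float(
            _lognormal_unit_mean(
                np.random.default_rng([seed, 3, s_idx]), tissue.specimen_sd
            )
        )
        for angle in config.flexion_angles:
            for st_idx, state in enumerate(config.states):
                retention = tissue.retention[state]
                lost = 1.0 - retention
                for cycle in range(1, config.cycles + 1):
                    rng = _trial_rng(seed, s_idx, angle, st_idx, cycle, 0)
                    trial_eff = float(_lognormal_unit_mean(rng, tissue.trial_sd))
                    varus_eps = float(_lognormal_unit_mean(rng, tissue.align_trial_sd))
                    extrot_eps = float(_lognormal_unit_mean(rng, tissue.align_trial_sd))
                    drift = 1.0 + tissue.conditioning_drift * (3 - cycle)

                    # loaded alignment for this state/trial (relative to zero position)
                    varus_full = tissue.intact_varus + tissue.varus_gain * lost * varus_eps
                    ext_full = tissue.intact_extrot
                    if state != "intact":
                        ext_full += tissue.extrot_offset
                        if angle == 30.0:
                            ext_full += tissue.extrot_gain_30 * lost * extrot_eps

                    R, t = _poses_from_jcs_batch(
                        np.full(n, angle - 30.0),
                        varus_full * load_frac,
                        ext_full * load_frac,
                        tissue.intact_medial * load_frac,
                        tissue.intact_anterior * load_frac,
                        -tissue.intact_compression * load_frac,
                    )
                    # recorded pose carries the rig's pose-measurement noise
                    R_rec = _random_bounded_rotations(rng, n, config.path_noise_rot) @ R
                    t_rec = t + _random_bounded_vectors(rng, n, config.path_noise_trans)

                    # force-controlled axial load: strictly within the
                    # fluctuation bound (80 % amplitude, uniform)
                    fluct = rng.uniform(
                        -0.8 * config.control_fluctuation,
                        0.8 * config.control_fluctuation, n,
                    ) if config.control_fluctuation > 0 else np.zeros(n)
                    axial = commanded + fluct

                    f_men = meniscal_force_vector(
                        state, angle, commanded, tissue, share_eff, trial_eff
                    ) * drift
                    # non-meniscal structures: shear fractions of the load plus
                    # whatever axial remainder closes the force balance
                    f_other = np.column_stack([
                        taux * commanded, tauy * commanded, -axial
                    ])
                    f_other[:, 2] -= f_men[:, 2]

                    f_recorded = _quantize(f_other + f_men, config.force_resolution)
                    m_recorded = np.cross(lever, f_recorded)
                    recordings.append(TrialRecording(
                        specimen=specimen, flexion_angle=angle, state=state,
                        cycle=cycle, phase="recorded", times=times.copy(),
                        rotations=R_rec, translations=t_rec,
                        wrenches=np.hstack([f_recorded, m_recorded]),
                        target_load=config.target_load,
                        control_fluctuation=config.control_fluctuation,
                    ))

                    # position-controlled replay after total meniscectomy:
                    # identical path within the robot's reproducibility,
                    # meniscal force vector absent
                    rng_rep = _trial_rng(seed, s_idx, angle, st_idx, cycle, 1)
                    R_rep = _random_bounded_rotations(
                        rng_rep, n, config.path_noise_rot) @ R_rec
                    t_rep = t_rec + _random_bounded_vectors(
                        rng_rep, n, config.path_noise_trans)
                    f_replayed = _quantize(f_other, config.force_resolution)
                    m_replayed = np.cross(lever, f_replayed)
                    recordings.append(TrialRecording(
                        specimen=specimen, flexion_angle=angle, state=state,
                        cycle=cycle, phase="replayed", times=times.copy(),
                        rotations=R_rep, translations=t_rep,
                        wrenches=np.hstack([f_replayed, m_replayed]),
                        target_load=config.target_load,
                        control_fluctuation=config.control_fluctuation,
                    ))
    return recordings


def _quantize(forces: np.ndarray, resolution: float) -> np.ndarray:
    if resolution <= 0.0:
        return forces
    return np.round(forces / resolution) * resolution
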