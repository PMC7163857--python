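"""Turns rig recordings into the two study outcomes.

* **In situ force** per specimen x flexion angle x meniscal state, from
  the superposition principle applied to a recorded trial and its
  path-replayed counterpart (structure removed).
* **Alignment change** (varus/valgus, internal/external rotation) of
  each resected state against the intact state under the same axial
  load, from Grood–Suntay decomposition of the peak-load poses.

Protocol conventions honoured here: only the third of the three loading
cycles enters the analysis; outcomes are evaluated at the midpoint of
the force-controlled hold phase (the contiguous window in which the
axial force stays within the controller fluctuation bound of the
commanded load).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kinematics import Pose, ReferencePose, jcs_from_pose
from .mechanics import InSituResult, Wrench, in_situ_force

__all__ = [
    "STATES",
    "RESECTION_STATES",
    "TrialRecording",
    "AlignmentChange",
    "PairingError",
    "select_analysis_cycle",
    "peak_load_sample",
    "compute_insitu",
    "compute_alignment_change",
    "analyze_dataset",
]

#: Meniscal states in protocol order: intact, then 30/60/90 % width inner resection.
STATES: tuple[str, ...] = ("intact", "w30", "w60", "w90")
#: States compared against intact for the alignment-change outcome.
RESECTION_STATES: tuple[str, ...] = ("w30", "w60", "w90")

ANALYSIS_CYCLE = 3


class PairingError(ValueError):
    """Recorded/replayed trials do not belong to the same path."""


@dataclass
class TrialRecording:
    """One loading cycle: synchronized pose + wrench samples.

    ``phase`` is ``"recorded"`` for force-controlled loading with the
    tissue state present, ``"replayed"`` for the position-controlled
    reproduction of the same path after total meniscectomy (``state``
    then names the state whose path is being replayed).

    Sample storage is columnar for efficiency: ``times`` (n,), rotation
    matrices ``rotations`` (n, 3, 3), ``translations`` (n, 3) mm and
    ``wrenches`` (n, 6) as [fx, fy, fz, mx, my, mz].  The sensor z axis
    points proximally, so axial compression reads as negative ``fz``;
    :meth:`axial_force` returns the (positive) applied axial load.
    """

    specimen: str
    flexion_angle: float
    state: str
    cycle: int
    phase: str
    times: np.ndarray
    rotations: np.ndarray
    translations: np.ndarray
    wrenches: np.ndarray
    target_load: float = 300.0
    control_fluctuation: float = 5.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        self.wrenches = np.asarray(self.wrenches, dtype=float)
        n = self.times.shape[0]
        if n == 0:
            raise ValueError("recording has no samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.rotations.shape != (n, 3, 3) or self.translations.shape != (n, 3):
            raise ValueError("pose arrays inconsistent with sample count")
        if self.wrenches.shape != (n, 6):
            raise ValueError("wrench array must be (n, 6)")
        if self.state not in STATES:
            raise ValueError(f"unknown meniscal state {self.state!r}")
        if self.phase not in ("recorded", "replayed"):
            raise ValueError(f"unknown phase {self.phase!r}")

    @property
    def n_samples(self) -> int:
        return self.times.shape[0]

    def pose(self, i: int) -> Pose:
        return Pose(self.rotations[i], self.translations[i])

    def wrench(self, i: int) -> Wrench:
        w = self.wrenches[i]
        return Wrench(*w)

    def axial_force(self) -> np.ndarray:
        """Applied axial load per sample, N (positive in compression)."""
        return -self.wrenches[:, 2]

    def key(self) -> tuple:
        return (self.specimen, self.flexion_angle, self.state, self.cycle)


@dataclass(frozen=True)
class AlignmentChange:
    """Alignment change of a resected state against intact, under load."""

    specimen: str
    flexion_angle: float
    state: str
    d_varus: float
    d_extrot: float

    def __post_init__(self) -> None:
        if self.state not in RESECTION_STATES:
            raise ValueError("alignment change is defined for resection states only")
        if not (np.isfinite(self.d_varus) and np.isfinite(self.d_extrot)):
            raise ValueError("alignment change must be finite")


def select_analysis_cycle(
    recordings: Iterable[TrialRecording], cycle: int = ANALYSIS_CYCLE
) -> list[TrialRecording]:
    """Keep only the analysis cycle (the third loading cycle by protocol).

    Raises ``ValueError`` naming the specimen/angle/state/phase group if
    a group does not contain the analysis cycle.
    """
    recordings = list(recordings)
    groups: dict[tuple, set[int]] = {}
    for rec in recordings:
        groups.setdefault(
            (rec.specimen, rec.flexion_angle, rec.state, rec.phase), set()
        ).add(rec.cycle)
    for key, cycles in groups.items():
        if cycle not in cycles:
            raise ValueError(
                f"group specimen={key[0]} angle={key[1]} state={key[2]} "
                f"phase={key[3]} has cycles {sorted(cycles)}; analysis cycle "
                f"{cycle} missing"
            )
    return [rec for rec in recordings if rec.cycle == cycle]


def peak_load_sample(rec: TrialRecording) -> int:
    """Index of the hold-phase midpoint sample.

    The hold phase is identified as the longest contiguous run of samples
    whose axial force lies within ``control_fluctuation`` of
    ``target_load``; the midpoint of that run is returned.  A recording
    that never reaches the commanded load raises ``ValueError``.
    """
    within = np.abs(rec.axial_force() - rec.target_load) <= rec.control_fluctuation
    if not np.any(within):
        raise ValueError(
            f"axial load never reaches {rec.target_load} N within "
            f"{rec.control_fluctuation} N ({rec.specimen}, {rec.flexion_angle} deg, "
            f"{rec.state}, cycle {rec.cycle})"
        )
    # longest contiguous True run
    padded = np.concatenate([[0], within.astype(int), [0]])
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    i = int(np.argmax(ends - starts))
    return int((starts[i] + ends[i] - 1) // 2)


def _check_pairing(
    recorded: TrialRecording,
    replayed: TrialRecording,
    max_trans_discrepancy: float,
    max_rot_discrepancy_deg: float,
) -> None:
    if recorded.phase != "recorded" or replayed.phase != "replayed":
        raise PairingError("expected a (recorded, replayed) pair in that order")
    if recorded.key() != replayed.key():
        raise PairingError(
            f"provenance mismatch: {recorded.key()} vs {replayed.key()}"
        )
    if recorded.n_samples != replayed.n_samples:
        raise PairingError("sample counts differ; not the same path")
    dt = np.linalg.norm(recorded.translations - replayed.translations, axis=1)
    if np.max(dt) > max_trans_discrepancy:
        raise PairingError(
            f"max path translation discrepancy {np.max(dt):.4g} mm exceeds "
            f"{max_trans_discrepancy:.4g} mm"
        )
    # rotation discrepancy as geodesic angle of R_rec^T R_rep
    rel = np.einsum("nij,nik->njk", recorded.rotations, replayed.rotations)
    tr = np.clip((np.trace(rel, axis1=1, axis2=2) - 1.0) / 2.0, -1.0, 1.0)
    ang = np.rad2deg(np.arccos(tr))
    if np.max(ang) > max_rot_discrepancy_deg:
        raise PairingError(
            f"max path rotation discrepancy {np.max(ang):.4g} deg exceeds "
            f"{max_rot_discrepancy_deg:.4g} deg"
        )


def compute_insitu(
    recorded: TrialRecording,
    replayed: TrialRecording,
    max_trans_discrepancy: float = 0.06,
    max_rot_discrepancy_deg: float = 0.3,
) -> InSituResult:
    """In situ force at the recorded trial's peak-load sample.

    Path identity is asserted (same provenance key, equal sample counts,
    pose discrepancy within 10x the robot's path-reproduction noise by
    default); violations raise :class:`PairingError` rather than being
    silently tolerated.
    """
    _check_pairing(recorded, replayed, max_trans_discrepancy, max_rot_discrepancy_deg)
    i = peak_load_sample(recorded)
    force = in_situ_force(recorded.wrench(i), replayed.wrench(i))
    return InSituResult(
        specimen=recorded.specimen,
        flexion_angle=recorded.flexion_angle,
        state=recorded.state,
        force=force,
    )


def compute_alignment_change(
    state_rec: TrialRecording,
    intact_rec: TrialRecording,
    reference: ReferencePose,
) -> AlignmentChange:
    """Varus and external-rotation change of a resected state vs intact.

    Both trials must be recorded-phase trials of the same specimen and
    flexion angle; each is evaluated at its own peak-load sample.
    """
    if state_rec.phase != "recorded" or intact_rec.phase != "recorded":
        raise PairingError("alignment changes are computed from recorded paths only")
    if state_rec.specimen != intact_rec.specimen:
        raise PairingError("specimen mismatch")
    if state_rec.flexion_angle != intact_rec.flexion_angle:
        raise PairingError(
            f"flexion angle mismatch: {state_rec.flexion_angle} vs "
            f"{intact_rec.flexion_angle}"
        )
    if intact_rec.state != "intact":
        raise PairingError("baseline trial must be the intact state")
    jcs_state = jcs_from_pose(state_rec.pose(peak_load_sample(state_rec)), reference)
    jcs_intact = jcs_from_pose(intact_rec.pose(peak_load_sample(intact_rec)), reference)
    return AlignmentChange(
        specimen=state_rec.specimen,
        flexion_angle=state_rec.flexion_angle,
        state=state_rec.state,
        d_varus=jcs_state.varus - jcs_intact.varus,
        d_extrot=jcs_state.ext_rot - jcs_intact.ext_rot,
    )


def analyze_dataset(
    recordings: Sequence[TrialRecording],
    reference: ReferencePose | None = None,
) -> pd.DataFrame:
    """Full analysis: tidy outcome table, one row per specimen x angle x state.

    Columns: ``specimen, flexion_angle, state, insitu_force, varus,
    ext_rot, d_varus, d_extrot`` — the alignment-change columns are NaN
    for the intact rows (intact is the zero baseline).  Poses in the
    recording schema are expressed relative to each specimen's zero
    position, so the default reference is the identity pose.
    """
    if reference is None:
        reference = ReferencePose()
    cycle3 = select_analysis_cycle(recordings)
    recorded = {r.key(): r for r in cycle3 if r.phase == "recorded"}
    replayed = {r.key(): r for r in cycle3 if r.phase == "replayed"}
    rows = []
    for key, rec in sorted(recorded.items()):
        rep = replayed.get(key)
        if rep is None:
            raise PairingError(f"no replayed counterpart for {key}")
        res = compute_insitu(rec, rep)
        jcs = jcs_from_pose(rec.pose(peak_load_sample(rec)), reference)
        row = {
            "specimen": rec.specimen,
            "flexion_angle": rec.flexion_angle,
            "state": rec.state,
            "insitu_force": res.force,
            "varus": jcs.varus,
            "ext_rot": jcs.ext_rot,
            "d_varus": np.nan,
            "d_extrot": np.nan,
        }
        if rec.state in RESECTION_STATES:
            intact_key = (rec.specimen, rec.flexion_angle, "intact", rec.cycle)
            if intact_key not in recorded:
                raise PairingError(f"no intact baseline for {key}")
            change = compute_alignment_change(rec, recorded[intact_key], reference)
            row["d_varus"] = change.d_varus
            row["d_extrot"] = change.d_extrot
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df["state"] = pd.Categorical(df["state"], categories=STATES, ordered=True)
        df = df.sort_values(["specimen", "flexion_angle", "state"]).reset_index(drop=True)
    return df
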