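"""Model/Results facade for a full precision-grip analysis.

:class:`GripInverseDynamics` binds a hand model to one recorded (or
synthetic) grip trial; :meth:`fit` runs the estimation pipeline — marker
filtering, model-based registration, differentiation, Newton-Euler inverse
dynamics and cubed-stress static optimization — and returns a
:class:`GripResults` carrying the estimated muscle forces with their
diagnostics (matching bias, torque-balance residuals, solver statuses), a
``summary()`` table, EMG validation and plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dynamics import PartitionedTorques, TorqueTrajectory, inverse_dynamics, partition_torques
from .forces import MuscleForceSolution, solve_trial
from .kinematics import (
    JointTrajectory,
    MarkerTrajectorySet,
    RegistrationResult,
    differentiate_trajectory,
    filter_markers,
    index_finger_length,
    register_trial,
    scale_model,
)
from .model import HandModel
from .signals import ValidationReport, build_validation_report


@dataclass
class GripTrial:
    """One grip-hold-release sequence: marker trajectories plus thumb/index
    lever-force magnitude series (columns time_s, thumb_N, index_N)."""

    markers: MarkerTrajectorySet
    lever_forces: pd.DataFrame
    name: str = "trial"
    emg: list = field(default_factory=list)

    def __post_init__(self):
        need = {"time_s", "thumb_N", "index_N"}
        if not need.issubset(self.lever_forces.columns):
            raise ValueError(f"lever forces must have columns {sorted(need)}")
        if len(self.lever_forces) != self.markers.n_frames:
            raise ValueError(
                "lever-force and marker series must be frame-aligned "
                f"({len(self.lever_forces)} vs {self.markers.n_frames})"
            )


class GripInverseDynamics:
    """Muscle-force estimation model for one grip trial.

    Parameters
    ----------
    model : HandModel
        The musculoskeletal model (scaled or generic).
    trial : GripTrial
        Markers and lever forces.
    filter_cutoff_hz : float or None
        Zero-phase low-pass cutoff applied to the markers (default 5 Hz);
        None disables filtering.
    scale_to_index_length_mm : float or None
        If given, the model is uniformly scaled to this index-finger length
        before registration.
    differentiation : str
        "central" (default) or "polynomial".
    gravity : array or None
        Override for the model's gravity vector (m/s^2).
    """

    def __init__(
        self,
        model: HandModel,
        trial: GripTrial,
        filter_cutoff_hz: Optional[float] = 5.0,
        scale_to_index_length_mm: Optional[float] = None,
        differentiation: str = "central",
        gravity=None,
    ):
        self.trial = trial
        self.filter_cutoff_hz = filter_cutoff_hz
        self.differentiation = differentiation
        self.gravity = gravity
        if scale_to_index_length_mm is not None:
            model = scale_model(model, scale_to_index_length_mm)
        self.model = model

    def fit(self) -> "GripResults":
        markers = self.trial.markers
        if self.filter_cutoff_hz:
            markers = filter_markers(markers, self.filter_cutoff_hz)
        registration = register_trial(self.model, markers)
        trajectory = differentiate_trajectory(
            registration.trajectory, mode=self.differentiation
        )
        loads = []
        for digit, col in (("thumb", "thumb_N"), ("index", "index_N")):
            lv = self.model.levers[digit]
            from .dynamics import lever_load_from_gauge

            loads.append(
                lever_load_from_gauge(
                    self.trial.lever_forces[col].to_numpy(), lv.direction, lv
                )
            )
        torques = inverse_dynamics(self.model, trajectory, loads=loads, gravity=self.gravity)
        solution = solve_trial(self.model, trajectory, torques)
        return GripResults(
            model=self.model,
            trial=self.trial,
            registration=registration,
            trajectory=trajectory,
            torques=torques,
            solution=solution,
        )


@dataclass
class GripResults:
    """Fitted muscle forces and diagnostics for one grip trial."""

    model: HandModel
    trial: GripTrial
    registration: RegistrationResult
    trajectory: JointTrajectory
    torques: TorqueTrajectory
    solution: MuscleForceSolution

    @property
    def forces(self) -> pd.DataFrame:
        """Muscle tensions (N), one column per muscle path."""
        return pd.DataFrame(
            self.solution.forces_N,
            columns=self.solution.muscle_names,
            index=self.solution.times,
        )

    @property
    def partitioned_torques(self) -> PartitionedTorques:
        return partition_torques(self.torques, self.model)

    def peak_forces(self) -> pd.Series:
        return self.forces.max(axis=0)

    def validate(self, emg_records=None, channels: Optional[dict] = None) -> ValidationReport:
        """Zero-lag cross-correlation of predicted forces against EMG
        envelopes (with the effectively-zero / 0.3 N skip rules)."""
        records = emg_records if emg_records is not None else self.trial.emg
        if channels is None:
            from .synth import DEFAULT_EMG_CHANNELS

            channels = DEFAULT_EMG_CHANNELS
        predicted = {}
        envelopes = {}
        for rec in records:
            muscles = channels.get(rec.channel, [rec.channel])
            cols = [m for m in muscles if m in self.solution.muscle_names]
            if not cols:
                continue
            predicted[rec.channel] = sum(self.solution.force(m) for m in cols)
            env = rec.envelope_mV
            if env is None:
                env = rec.process().envelope_mV
            envelopes[rec.channel] = env
        return build_validation_report(predicted, envelopes)

    def summary(self) -> str:
        reg = self.registration
        lev = self.trial.lever_forces
        part = self.partitioned_torques
        peaks = self.peak_forces()
        active = peaks[peaks >= 0.3].sort_values(ascending=False)
        lines = [
            "Precision-grip inverse dynamics",
            "=" * 47,
            f"Trial: {self.trial.name}   frames: {self.solution.n_frames}"
            f" @ {self.trajectory.frame_rate:g} Hz",
            f"Model: {self.model.n_segments} segments / {self.model.n_links} links,"
            f" {self.model.n_paths} muscle paths",
            f"Matching bias (mm): {reg.mean_bias_mm:.2f} +/- {reg.sd_bias_mm:.2f}",
            f"Peak lever force (N): thumb {lev['thumb_N'].max():.2f},"
            f" index {lev['index_N'].max():.2f}",
            f"Muscle-balanced axes: {part.free_Nm.shape[1]}"
            f" (reaction axes: {part.reaction_Nm.shape[1]})",
            f"Torque-balance residual (N*m): max"
            f" {self.solution.residual_Nm.max():.2e}",
            f"Solver: {sum(s == 'optimal' for s in self.solution.statuses)}"
            f"/{self.solution.n_frames} frames optimal",
            "",
            "Peak muscle forces >= 0.3 N:",
        ]
        for name, val in active.items():
            lines.append(f"  {name:6s} {val:8.2f} N")
        return "\n".join(lines)

    def plot_forces(self, muscles=None, ax=None):
        """Time course of predicted muscle forces (N)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        peaks = self.peak_forces()
        if muscles is None:
            muscles = list(peaks[peaks >= 0.3].sort_values(ascending=False).index)
        t = self.solution.times
        for m in muscles:
            ax.plot(t, self.solution.force(m), label=m)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("muscle force (N)")
        ax.legend(fontsize=8, ncol=2)
        return ax
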