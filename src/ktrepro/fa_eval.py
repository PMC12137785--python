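"""Flip-angle prediction and per-scan evaluation metrics.

Two simulators are provided. :func:`predict_fa_sta` evaluates the
small-tip-angle closed form

    FA(r) = c0 * | sum_k sum_c b1_c(r) w_{c,k} exp(i k_k . r) |   (degrees)

on the full grid. :func:`bloch_simulate` applies the hard-pulse
approximation exactly: each kT-point subpulse is a constant complex RF
rotation (axis in the transverse plane, exact axis-angle rotation), and the
inter-point gradient blips appear as the position-dependent phase
``k_k . r`` of each rotation axis; relaxation is neglected. The two agree in
the small-tip limit and the Bloch result is exact for piecewise-constant
fields.

Evaluation metrics: coefficient of variation of the flip angle inside the
heart ROI (population standard deviation over mean, percent), order
statistics of the FA distribution, and RF voltage/power summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .b1_synth import B1MapSet, ROIMask
from .exceptions import DesignError, NormalizationError, ROIError
from .grids import GridSpec
from .pulse_design import KTPointsPulse


@dataclass
class FAMap:
    """Flip-angle map in degrees on a regular grid."""

    grid: GridSpec
    fa: np.ndarray  # degrees, shape grid.shape
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.fa = np.asarray(self.fa, dtype=float)
        if self.fa.shape != self.grid.shape:
            raise ValueError("FA map shape does not match grid")
        if not np.all(np.isfinite(self.fa)):
            raise ValueError("FA map must be finite")
        if np.any(self.fa < 0):
            raise ValueError("flip angles must be non-negative")


@dataclass(frozen=True)
class RFMetrics:
    """Voltage/power summaries of a pulse (arbitrary relative units)."""

    peak_voltage: float
    mean_power: float
    per_channel_power: tuple[float, ...]


@dataclass(frozen=True)
class FASummary:
    """Order statistics of the FA distribution inside the ROI (degrees)."""

    median: float
    q1: float
    q3: float
    min: float
    max: float
    mean: float


def _check_pair(maps: B1MapSet, pulse: KTPointsPulse):
    if not maps.normalized:
        raise NormalizationError("maps must be normalized before FA prediction")
    if maps.n_channels != pulse.n_channels:
        raise DesignError(
            f"channel mismatch: maps have {maps.n_channels}, pulse has "
            f"{pulse.n_channels}"
        )


def _channel_drive(maps: B1MapSet, pulse: KTPointsPulse) -> np.ndarray:
    """Per-kT-point complex drive b_k(r) = sum_c b1_c(r) w_{c,k}; (K, *grid)."""
    return np.tensordot(pulse.weights.T, maps.data, axes=([1], [0]))


def predict_fa_sta(maps: B1MapSet, pulse: KTPointsPulse) -> FAMap:
    """Small-tip-angle flip-angle prediction over the full grid."""
    _check_pair(maps, pulse)
    drive = _channel_drive(maps, pulse)  # (K, *grid)
    pos = maps.grid.positions_mm() / 1000.0  # (n, 3) metres
    phases = np.exp(1j * (pos @ pulse.k_locations.T))  # (n, K)
    m = np.einsum("kn,nk->n", drive.reshape(pulse.n_kt, -1), phases)
    fa = pulse.target_fa_deg * np.abs(m).reshape(maps.grid.shape)
    return FAMap(
        grid=maps.grid,
        fa=fa,
        provenance={"simulator": "sta", "method": pulse.method},
    )


def bloch_simulate(maps: B1MapSet, pulse: KTPointsPulse) -> FAMap:
    """Hard-pulse Bloch simulation; FA(r) = arccos(Mz_final) in degrees.

    Each subpulse rotates the magnetization by the exact axis-angle
    rotation with angle ``deg2rad(c0 * |b_k(r)|)`` about the transverse axis
    at phase ``angle(b_k(r)) + k_k . r``; rotations are composed per voxel
    with quaternions.
    """
    _check_pair(maps, pulse)
    drive = _channel_drive(maps, pulse).reshape(pulse.n_kt, -1)  # (K, n)
    pos = maps.grid.positions_mm() / 1000.0
    blip_phase = pos @ pulse.k_locations.T  # (n, K)

    n = drive.shape[1]
    # Quaternion (w, x, y, z) accumulated over subpulses; identity start.
    qw = np.ones(n)
    qx = np.zeros(n)
    qy = np.zeros(n)
    qz = np.zeros(n)
    for k in range(pulse.n_kt):
        theta = np.deg2rad(pulse.target_fa_deg * np.abs(drive[k]))
        phi = np.angle(drive[k]) + blip_phase[:, k]
        half = 0.5 * theta
        rw = np.cos(half)
        s = np.sin(half)
        rx = s * np.cos(phi)
        ry = s * np.sin(phi)
        # rz = 0 (axis lies in the transverse plane)
        nw = rw * qw - rx * qx - ry * qy
        nx = rw * qx + rx * qw + ry * qz
        ny = rw * qy + ry * qw - rx * qz
        nz = rw * qz + rx * qy - ry * qx
        qw, qx, qy, qz = nw, nx, ny, nz
    mz = 1.0 - 2.0 * (qx**2 + qy**2)
    fa = np.degrees(np.arccos(np.clip(mz, -1.0, 1.0))).reshape(maps.grid.shape)
    return FAMap(
        grid=maps.grid,
        fa=fa,
        provenance={"simulator": "bloch", "method": pulse.method},
    )


def compute_cv(fa: FAMap, roi: ROIMask) -> float:
    """Coefficient of variation (%) of the flip angle inside the ROI.

    Population (ddof=0) standard deviation over mean, times 100.
    """
    if roi.voxel_count == 0:
        raise ROIError("ROI is empty")
    vals = fa.fa[roi.mask]
    mean = float(vals.mean())
    if mean <= 0:
        raise ValueError(f"mean ROI flip angle must be positive, got {mean}")
    return 100.0 * float(vals.std(ddof=0)) / mean


def fa_distribution(fa: FAMap, roi: ROIMask) -> FASummary:
    """Median/quartiles/extremes of the FA distribution inside the ROI."""
    if roi.voxel_count == 0:
        raise ROIError("ROI is empty")
    vals = fa.fa[roi.mask]
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return FASummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=float(vals.min()),
        max=float(vals.max()),
        mean=float(vals.mean()),
    )


def rf_metrics(pulse: KTPointsPulse) -> RFMetrics:
    """Peak voltage, mean power, per-channel power of the pulse weights.

    Subpulse durations are identical, so duty weighting reduces to plain
    means over channels and kT-points.
    """
    w = pulse.weights
    mags2 = np.abs(w) ** 2
    return RFMetrics(
        peak_voltage=float(np.abs(w).max()),
        mean_power=float(mags2.mean()),
        per_channel_power=tuple(float(p) for p in mags2.mean(axis=1)),
    )
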