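"""Synthetic multi-channel transmit (B1+) field maps of a torso with a heart ROI.

The generator emulates an 8-channel parallel-transmit body array wrapped
around an ellipsoidal torso: four elements on an anterior plate, four on a
posterior plate. Each channel's complex sensitivity decays with distance
``d`` from its element centre as ``1 / (d + d0)``, is attenuated inside
tissue, and carries a propagation phase ``k * d`` plus a fixed per-channel
offset. The short RF wavelength at ultrahigh field makes the channels
interfere destructively in places, which is exactly the flip-angle dropout
problem pTx pulse design exists to fix.

Longitudinal structure: a *subject* fixes the baseline anatomy (torso/heart
ellipsoids, tissue attenuation); a *session* carries (i) a coil placement —
translation + rotation about z with a per-operator systematic bias and
per-session jitter, (ii) an anatomy state — the subject's geometry drifted
along a population-systematic plus subject-specific direction by an amount
growing with the elapsed time since baseline (sessions acquired on the same
date share the state exactly), and (iii) a small per-session complex
"loading screen" per channel. Everything is a pure function of the recorded
seeds.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import GridError, ROIError
from .grids import DEFAULT_GRID, GridSpec

GAMMA_RAD_PER_S_PER_T = 2 * np.pi * 42.577478518e6  # proton gyromagnetic ratio

# Fixed coil constants (relative units; absolute scale is removed by
# normalize_b1, so only the spatial structure matters).
DEFAULT_D0_MM = 60.0
DEFAULT_WAVELENGTH_MM = 140.0  # effective in-tissue RF wavelength at 7 T
_CHANNEL_PHASE_OFFSETS = np.array(
    [0.0, 0.9, 1.7, 2.6, 3.4, 4.2, 5.1, 5.9]
)  # rad, fixed cabling offsets


def default_element_positions(
    torso_semiaxes_mm: Sequence[float], standoff_mm: float = 25.0
) -> np.ndarray:
    """Nominal 8-element layout: 2x2 anterior plate (+y) and posterior (-y)."""
    ax, ay, az = torso_semiaxes_mm
    xs = (-0.55 * ax, 0.55 * ax)
    zs = (-70.0, 70.0)
    y_plate = ay + standoff_mm
    pos = []
    for y in (y_plate, -y_plate):  # anterior ring then posterior ring
        for x in xs:
            for z in zs:
                pos.append((x, y, z))
    return np.asarray(pos, dtype=float)


@dataclass(frozen=True)
class SubjectParams:
    """Anatomy of one synthetic subject (mm; attenuation is unitless)."""

    torso_semiaxes_mm: tuple[float, float, float] = (105.0, 85.0, 150.0)
    heart_center_mm: tuple[float, float, float] = (12.0, 25.0, 10.0)
    heart_semiaxes_mm: tuple[float, float, float] = (42.0, 45.0, 50.0)
    attenuation: float = 1.2
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.torso_semiaxes_mm, dtype=float)
        h = np.asarray(self.heart_semiaxes_mm, dtype=float)
        c = np.asarray(self.heart_center_mm, dtype=float)
        if np.any(t <= 0) or np.any(h <= 0):
            raise ValueError("ellipsoid semi-axes must be positive")
        # Sufficient condition for the heart ellipsoid to sit strictly inside
        # the torso ellipsoid: ||c / t|| + max(h_i / t_i) < 1.
        if np.linalg.norm(c / t) + np.max(h / t) >= 1.0:
            raise ValueError("heart ellipsoid is not strictly inside the torso")


@dataclass(frozen=True)
class SessionParams:
    """Coil placement and anatomy state of one scan session.

    ``perturbation_amplitude`` drives the per-session loading screen
    (seeded by ``seed``); ``anatomy_amplitude`` drives the geometric
    anatomy drift shared by all sessions acquired on the same date (seeded
    by ``anatomy_seed``, which is fixed per subject).
    """

    coil_translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    coil_rotation_deg: float = 0.0
    anatomy_scale: float = 1.0
    perturbation_amplitude: float = 0.0
    anatomy_amplitude: float = 0.0
    anatomy_seed: int = 0
    date_years: float = 0.0
    operator: str = "A"
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.coil_translation_mm, dtype=float)
        if np.linalg.norm(t) > 40.0:
            raise ValueError("coil translation exceeds 40 mm")
        if abs(self.coil_rotation_deg) > 15.0:
            raise ValueError("coil rotation exceeds 15 degrees")
        if not 0.9 <= self.anatomy_scale <= 1.1:
            raise ValueError("anatomy scale must lie in [0.9, 1.1]")
        if not 0.0 <= self.perturbation_amplitude <= 0.3:
            raise ValueError("perturbation amplitude must lie in [0, 0.3]")
        if not 0.0 <= self.anatomy_amplitude <= 0.5:
            raise ValueError("anatomy amplitude must lie in [0, 0.5]")


IDENTITY_SESSION = SessionParams()


@dataclass
class B1MapSet:
    """Per-channel complex transmit sensitivities on a regular grid."""

    grid: GridSpec
    data: np.ndarray  # complex, shape (C, Nx, Ny, Nz)
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 4 or self.data.shape[1:] != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.data.view(np.float64))):
            raise ValueError("B1+ maps must be finite everywhere")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def sum_of_magnitudes(self) -> np.ndarray:
        """Voxelwise sum over channels of |b1_c(r)|."""
        return np.abs(self.data).sum(axis=0)


@dataclass
class ROIMask:
    """Binary heart mask on the same grid as the maps it accompanies."""

    grid: GridSpec
    mask: np.ndarray  # bool, shape (Nx, Ny, Nz)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("ROI mask shape does not match grid")
        if self.voxel_count < 50:
            raise ROIError(f"ROI has only {self.voxel_count} voxels (need >= 50)")
        _, n_comp = ndimage.label(self.mask)
        if n_comp != 1:
            raise ROIError(f"ROI must be a single connected component, found {n_comp}")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def _rotation_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _smooth_field(
    grid: GridSpec, rng: np.random.Generator, n_modes: int = 3
) -> np.ndarray:
    """Smooth random field with values in [-1, 1] (sum of long cosine modes)."""
    X, Y, Z = grid.coords_mm()
    f = np.zeros(grid.shape)
    for _ in range(n_modes):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        wavelength = rng.uniform(180.0, 420.0)  # mm, longer than the heart
        phase = rng.uniform(0.0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        q = 2 * np.pi / wavelength * direction
        f += amp * np.cos(q[0] * X + q[1] * Y + q[2] * Z + phase)
    peak = np.max(np.abs(f))
    return f / peak if peak > 0 else f


def _apply_screens(
    data: np.ndarray, grid: GridSpec, seed: int, eps: float
) -> None:
    """Multiply each channel by a smooth complex screen of amplitude eps."""
    rng = np.random.default_rng(seed)
    for c in range(data.shape[0]):
        f = _smooth_field(grid, rng)
        g = _smooth_field(grid, rng)
        data[c] *= (1.0 + eps * f) * np.exp(1j * np.pi * eps * g)


# Gains converting the anatomy-drift amplitude into geometric change:
# relative torso/heart semi-axis drift and heart-centre displacement (mm)
# per unit amplitude, along a fixed per-subject random direction.
_TORSO_DRIFT_GAIN = 0.05
_HEART_DRIFT_GAIN = 0.10
_CENTER_DRIFT_GAIN_MM = 22.0
# Population-systematic component of the anatomy change (the cohort-average
# direction of body-habitus change: chest growth, heart settling posterior
# and caudal). Shared by all subjects; the per-subject random component
# above is superimposed on it.
_POP_TORSO_DRIFT = np.array([0.04, 0.05, 0.01])  # relative per unit amplitude
_POP_HEART_DRIFT = np.array([0.03, 0.03, 0.03])
_POP_CENTER_DRIFT_MM = np.array([0.0, -10.0, 8.0])


def effective_subject(subject: SubjectParams, session: SessionParams) -> SubjectParams:
    """Anatomy as seen in one session: scaled and drifted subject geometry.

    The session's ``anatomy_scale`` is an isotropic size factor; its
    ``anatomy_amplitude`` moves the geometry along a fixed per-subject
    random direction (seeded by ``anatomy_seed``), so sessions acquired on
    the same date see the identical anatomy and the change grows with the
    elapsed time between dates.
    """
    s = session.anatomy_scale
    torso = s * np.asarray(subject.torso_semiaxes_mm)
    heart = s * np.asarray(subject.heart_semiaxes_mm)
    center = s * np.asarray(subject.heart_center_mm)
    amp = session.anatomy_amplitude
    if amp > 0:
        rng = np.random.default_rng(session.anatomy_seed)
        d_torso = rng.standard_normal(3)
        d_heart = rng.standard_normal(3)
        d_center = rng.standard_normal(3)
        torso = torso * (1.0 + amp * (_POP_TORSO_DRIFT + _TORSO_DRIFT_GAIN * d_torso))
        heart = heart * (1.0 + amp * (_POP_HEART_DRIFT + _HEART_DRIFT_GAIN * d_heart))
        center = center + amp * (
            _POP_CENTER_DRIFT_MM + _CENTER_DRIFT_GAIN_MM * d_center
        )
    # Safety clips keep the *drifted* anatomy inside the type invariants
    # and the default grid; they never bind below the baseline geometry,
    # so an oversized subject still fails the grid-containment check.
    base_torso = s * np.asarray(subject.torso_semiaxes_mm)
    base_heart = s * np.asarray(subject.heart_semiaxes_mm)
    torso = np.clip(
        torso,
        np.minimum(70.0, base_torso),
        np.maximum((112.0, 130.0, 220.0), base_torso),
    )
    heart = np.clip(
        heart,
        np.minimum(25.0, base_heart),
        np.maximum(0.5 * torso, base_heart),
    )
    margin = 0.95 - float(np.max(heart / torso))
    n = float(np.linalg.norm(center / torso))
    if margin > 0 and n > margin:
        center = center * (margin / n)
    return SubjectParams(
        torso_semiaxes_mm=tuple(torso),
        heart_center_mm=tuple(center),
        heart_semiaxes_mm=tuple(heart),
        attenuation=subject.attenuation,
        seed=subject.seed,
    )


def simulate_coil_maps(
    subject: SubjectParams,
    grid: GridSpec = DEFAULT_GRID,
    session: SessionParams = IDENTITY_SESSION,
    n_channels: int = 8,
    d0_mm: float = DEFAULT_D0_MM,
    wavelength_mm: float = DEFAULT_WAVELENGTH_MM,
    element_positions_mm: np.ndarray | None = None,
) -> B1MapSet:
    """Simulate one session's relative complex B1+ maps (not yet normalized).

    Channel magnitude: ``1 / (d + d0)`` times an exponential tissue
    attenuation with the normalized depth below the torso surface; channel
    phase: fixed offset + propagation term ``2*pi/wavelength * d``. Coil
    elements are rigidly rotated about z and translated by the session's
    placement parameters; the torso/heart scale with the session's anatomy
    factor; a smooth multiplicative perturbation (session-seeded) emulates
    residual anatomy/positioning change.
    """
    eff = effective_subject(subject, session)
    torso = np.asarray(eff.torso_semiaxes_mm)
    # The grid is a chest section: the body continues beyond the field of
    # view along the head-foot (z) axis, so containment is required only on
    # the transverse axes.
    for axis_name, semi, n, s in zip("xy", torso[:2], grid.shape[:2],
                                     grid.spacing_mm[:2], strict=True):
        if 2 * semi > n * s:
            raise GridError(
                f"grid axis {axis_name} (extent {n * s:.0f} mm) cannot contain "
                f"the torso (diameter {2 * semi:.0f} mm)"
            )

    if element_positions_mm is None:
        element_positions_mm = default_element_positions(torso)
    elements = np.asarray(element_positions_mm, dtype=float)
    if elements.shape != (n_channels, 3):
        raise ValueError(
            f"need {n_channels} element positions, got shape {elements.shape}"
        )
    R = _rotation_z(session.coil_rotation_deg)
    elements = elements @ R.T + np.asarray(session.coil_translation_mm)

    X, Y, Z = grid.coords_mm()
    rho = np.sqrt((X / torso[0]) ** 2 + (Y / torso[1]) ** 2 + (Z / torso[2]) ** 2)
    depth = np.clip(1.0 - rho, 0.0, None)  # 0 at/outside surface, 1 at centre
    atten = np.exp(-eff.attenuation * depth)

    k_wave = 2 * np.pi / wavelength_mm
    data = np.empty((n_channels,) + grid.shape, dtype=np.complex128)
    for c in range(n_channels):
        dx, dy, dz = X - elements[c, 0], Y - elements[c, 1], Z - elements[c, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        mag = atten / (d + d0_mm)
        phase = _CHANNEL_PHASE_OFFSETS[c % len(_CHANNEL_PHASE_OFFSETS)] + k_wave * d
        data[c] = mag * np.exp(1j * phase)

    # Per-session loading screen: a smooth, low-amplitude complex texture
    # per channel (magnitude modulation plus phase screen) emulating the
    # residual coil-loading/electronic state differences between sessions.
    if session.perturbation_amplitude > 0:
        _apply_screens(data, grid, session.seed, session.perturbation_amplitude)

    return B1MapSet(
        grid=grid,
        data=data,
        normalized=False,
        meta={"subject_seed": subject.seed, "session_seed": session.seed,
              "operator": session.operator},
    )


def make_roi(
    subject: SubjectParams,
    grid: GridSpec = DEFAULT_GRID,
    session: SessionParams = IDENTITY_SESSION,
) -> ROIMask:
    """Heart ellipsoid voxels of the session's effective anatomy."""
    eff = effective_subject(subject, session)
    c = np.asarray(eff.heart_center_mm)
    h = np.asarray(eff.heart_semiaxes_mm)
    X, Y, Z = grid.coords_mm()
    mask = ((X - c[0]) / h[0]) ** 2 + ((Y - c[1]) / h[1]) ** 2 + (
        (Z - c[2]) / h[2]
    ) ** 2 <= 1.0
    return ROIMask(grid=grid, mask=mask)


def normalize_b1(maps: B1MapSet, roi: ROIMask) -> B1MapSet:
    """Scale maps so the ROI mean of the sum of channel magnitudes is 1.

    Idempotent: renormalizing a normalized set recomputes a divisor of 1.
    """
    if roi.grid.shape != maps.grid.shape:
        raise ValueError("ROI and maps live on different grids")
    if roi.voxel_count == 0:
        raise ROIError("cannot normalize with an empty ROI")
    s = float(maps.sum_of_magnitudes()[roi.mask].mean())
    if s <= 0:
        raise ValueError("ROI mean sum-of-magnitudes is zero; maps are degenerate")
    return B1MapSet(
        grid=maps.grid, data=maps.data / s, normalized=True, meta=dict(maps.meta)
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariabilityConfig:
    """Session-to-session and operator variability of the cohort generator.

    These values define the study conditions; they are frozen defaults, not
    fitting knobs. Translation/rotation jitter emulates placement
    repeatability, operator biases emulate systematic placement style, the
    anatomy scale emulates slow physiological change, and the perturbation
    amplitude drives the smooth multiplicative field change per session.
    """

    translation_jitter_mm: tuple[float, float, float] = (7.0, 7.0, 12.0)
    rotation_jitter_deg: float = 2.5
    operator_bias_mm: tuple[tuple[float, float, float], ...] = (
        (0.0, 0.0, 0.0),
        (9.0, 6.0, -18.0),
        (-12.0, 7.0, 21.0),
    )
    operator_bias_deg: tuple[float, ...] = (0.0, 3.0, -4.0)
    anatomy_scale_sd: float = 0.02
    # Loading-screen amplitude drawn fresh per session (texture noise).
    perturbation_amplitude_range: tuple[float, float] = (0.02, 0.08)
    # Scan calendar: sessions acquired on the same date share the anatomy
    # state exactly (the default mirrors a baseline scan, a 1-year rescan
    # and two same-day rescans 2 years in).
    session_dates_years: tuple[float, ...] = (0.0, 1.0, 2.0, 2.0)
    # Slow anatomy change: screen amplitude per elapsed year, with a
    # per-subject susceptibility factor drawn from the given range.
    anatomy_drift_per_year: float = 0.10
    anatomy_drift_subject_range: tuple[float, float] = (0.5, 1.4)
    # Anatomy-screen amplitudes assigned to calibration-library members
    # (a library accumulated over years of diverse loading states).
    library_anatomy_range: tuple[float, float] = (0.0, 0.3)

    @classmethod
    def zero(cls) -> "VariabilityConfig":
        """Degenerate variability: all sessions of a subject are identical."""
        return cls(
            translation_jitter_mm=(0.0, 0.0, 0.0),
            rotation_jitter_deg=0.0,
            operator_bias_mm=((0.0, 0.0, 0.0),) * 3,
            operator_bias_deg=(0.0, 0.0, 0.0),
            anatomy_scale_sd=0.0,
            perturbation_amplitude_range=(0.0, 0.0),
            anatomy_drift_per_year=0.0,
            library_anatomy_range=(0.0, 0.0),
        )

    def dates_for(self, n_sessions: int) -> tuple[float, ...]:
        if len(self.session_dates_years) == n_sessions:
            return self.session_dates_years
        return tuple(float(s) for s in range(n_sessions))


@dataclass(frozen=True)
class AnatomySpread:
    """Sampling spread of subject anatomy around the nominal torso/heart."""

    torso_rel_sd: float = 0.06
    heart_rel_sd: float = 0.08
    heart_center_sd_mm: float = 5.0
    attenuation_rel_sd: float = 0.15


TEST_SPREAD = AnatomySpread(
    torso_rel_sd=0.03, heart_rel_sd=0.04, heart_center_sd_mm=2.5,
    attenuation_rel_sd=0.06,
)
# The library cohort spans a broader range of body habitus than the test
# cohort, mirroring a calibration library recruited across BMI/age ranges.
LIBRARY_SPREAD = AnatomySpread(
    torso_rel_sd=0.08, heart_rel_sd=0.08, heart_center_sd_mm=5.0,
    attenuation_rel_sd=0.15,
)


def sample_subject(seed: int, spread: AnatomySpread = TEST_SPREAD) -> SubjectParams:
    """Draw one subject's anatomy around the nominal values."""
    rng = np.random.default_rng(seed)
    base = SubjectParams()
    torso = np.asarray(base.torso_semiaxes_mm) * (
        1.0 + spread.torso_rel_sd * rng.standard_normal(3)
    )
    heart = np.asarray(base.heart_semiaxes_mm) * (
        1.0 + spread.heart_rel_sd * rng.standard_normal(3)
    )
    center = np.asarray(base.heart_center_mm) + spread.heart_center_sd_mm * (
        rng.standard_normal(3)
    )
    atten = base.attenuation * (
        1.0 + spread.attenuation_rel_sd * rng.standard_normal()
    )
    # Guard rails keep the draw inside the type invariants and the default
    # grid's transverse extent (including the widest session anatomy scale).
    torso = np.clip(torso, 70.0, (112.0, 130.0, 220.0))
    heart = np.clip(heart, 25.0, 0.55 * torso)
    center = np.clip(center, -0.25 * torso, 0.25 * torso)
    return SubjectParams(
        torso_semiaxes_mm=tuple(torso),
        heart_center_mm=tuple(center),
        heart_semiaxes_mm=tuple(heart),
        attenuation=float(max(atten, 0.0)),
        seed=int(seed),
    )


def sample_session(
    seed: int,
    operator_index: int,
    variability: VariabilityConfig,
    anatomy_amplitude: float = 0.0,
    anatomy_seed: int = 0,
    date_years: float = 0.0,
) -> SessionParams:
    """Draw one session's coil placement and per-session screen amplitude."""
    rng = np.random.default_rng(seed)
    v = variability
    bias_t = np.asarray(v.operator_bias_mm[operator_index % len(v.operator_bias_mm)])
    bias_r = v.operator_bias_deg[operator_index % len(v.operator_bias_deg)]
    translation = bias_t + np.asarray(v.translation_jitter_mm) * rng.standard_normal(3)
    rotation = bias_r + v.rotation_jitter_deg * rng.standard_normal()
    scale = 1.0 + v.anatomy_scale_sd * rng.standard_normal()
    lo, hi = v.perturbation_amplitude_range
    eps = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    # Clip into the type invariants (jitter tails).
    norm = np.linalg.norm(translation)
    if norm > 40.0:
        translation *= (40.0 - 1e-9) / norm
    rotation = float(np.clip(rotation, -15.0, 15.0))
    scale = float(np.clip(scale, 0.9, 1.1))
    return SessionParams(
        coil_translation_mm=tuple(translation),
        coil_rotation_deg=rotation,
        anatomy_scale=scale,
        perturbation_amplitude=eps,
        anatomy_amplitude=float(np.clip(anatomy_amplitude, 0.0, 0.5)),
        anatomy_seed=int(anatomy_seed),
        date_years=float(date_years),
        operator=string.ascii_uppercase[operator_index % 26],
        seed=int(seed),
    )


def default_operator_indices(n_sessions: int, n_operators: int = 3) -> list[int]:
    """Session -> operator assignment; the 4-session default is A, B, A, C."""
    if n_sessions == 4 and n_operators >= 3:
        return [0, 1, 0, 2]
    return [s % max(n_operators, 1) for s in range(n_sessions)]


@dataclass
class CohortRecord:
    subject: str
    session: int  # 1-based
    operator: str
    seed: int
    subject_params: SubjectParams
    session_params: SessionParams
    maps: B1MapSet
    roi: ROIMask
    path: str | None = None


@dataclass
class Cohort:
    """In-memory cohort: one (maps, ROI) pair per (subject, session)."""

    records: list[CohortRecord]
    master_seed: int
    grid: GridSpec
    variability: VariabilityConfig

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.subject, None)
        return list(seen)

    @property
    def n_sessions(self) -> int:
        return max(r.session for r in self.records)

    def get(self, subject: str, session: int) -> CohortRecord:
        for r in self.records:
            if r.subject == subject and r.session == session:
                return r
        raise KeyError(f"no record for subject={subject} session={session}")

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [r.subject for r in self.records],
                "session": [r.session for r in self.records],
                "operator": [r.operator for r in self.records],
                "path": [r.path or "" for r in self.records],
                "seed": [r.seed for r in self.records],
            }
        )


def generate_cohort(
    n_subjects: int,
    n_sessions: int,
    master_seed: int,
    n_operators: int = 3,
    grid: GridSpec = DEFAULT_GRID,
    variability: VariabilityConfig = VariabilityConfig(),
    spread: AnatomySpread = TEST_SPREAD,
    subject_prefix: str = "S",
    out_dir: str | Path | None = None,
    normalize: bool = True,
    operator_cycle: bool = False,
) -> Cohort:
    """Generate a multi-subject, multi-session cohort of B1+ maps and ROIs.

    Subject anatomy is fixed across that subject's sessions (up to the
    session anatomy-scale factor); session perturbations are independent
    draws; the operator assignment follows :func:`default_operator_indices`.
    Fully reproducible from ``master_seed``. When ``out_dir`` is given every
    (subject, session) pair is written to an HDF5 container and a manifest
    CSV is placed alongside.
    """
    if n_subjects < 1 or n_sessions < 1:
        raise ValueError("need at least one subject and one session")
    rng = np.random.default_rng(master_seed)
    subject_seeds = rng.integers(0, 2**31, size=n_subjects)
    operator_idx = default_operator_indices(n_sessions, n_operators)

    records: list[CohortRecord] = []
    for i in range(n_subjects):
        subject_id = f"{subject_prefix}{i + 1}"
        subject = sample_subject(int(subject_seeds[i]), spread)
        session_rng = np.random.default_rng(subject.seed)
        drift_factor = float(
            session_rng.uniform(*variability.anatomy_drift_subject_range)
        )
        session_seeds = session_rng.integers(0, 2**31, size=n_sessions)
        dates = variability.dates_for(n_sessions)
        for s in range(n_sessions):
            # ``operator_cycle`` spreads operators across subjects (used for
            # single-session calibration libraries so that every placement
            # style is represented); the default assignment is per session.
            op = (i + s) % n_operators if operator_cycle else operator_idx[s]
            if operator_cycle:
                # Library member: anatomy state drawn from the library range
                # rather than accumulated over a scan calendar.
                lo, hi = variability.library_anatomy_range
                an_amp = (
                    float(session_rng.uniform(lo, hi)) if hi > lo else float(lo)
                )
            else:
                an_amp = variability.anatomy_drift_per_year * drift_factor * dates[s]
            sess = sample_session(
                int(session_seeds[s]), op, variability,
                anatomy_amplitude=an_amp, anatomy_seed=subject.seed,
                date_years=dates[s],
            )
            maps = simulate_coil_maps(subject, grid, sess)
            roi = make_roi(subject, grid, sess)
            if normalize:
                maps = normalize_b1(maps, roi)
            records.append(
                CohortRecord(
                    subject=subject_id,
                    session=s + 1,
                    operator=sess.operator,
                    seed=int(session_seeds[s]),
                    subject_params=subject,
                    session_params=sess,
                    maps=maps,
                    roi=roi,
                )
            )

    cohort = Cohort(
        records=records, master_seed=int(master_seed), grid=grid,
        variability=variability,
    )
    if out_dir is not None:
        from .io_formats import write_container, write_manifest

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for r in cohort.records:
            path = out / f"{r.subject}_session{r.session}.h5"
            write_container(
                path, r.maps, r.roi,
                attrs={"seed": r.seed, "operator": r.operator},
            )
            r.path = str(path)
        write_manifest(cohort.manifest(), out / "manifest.csv")
    return cohort


def generate_library(
    n_members: int,
    master_seed: int,
    grid: GridSpec = DEFAULT_GRID,
    variability: VariabilityConfig = VariabilityConfig(),
    out_dir: str | Path | None = None,
) -> Cohort:
    """Single-session calibration library with broader anatomy spread.

    Library seeds are derived from a different stream than any test cohort
    (offset the master seed before calling, as the study pipeline does), and
    member identifiers carry an ``L`` prefix so no id is shared with test
    subjects.
    """
    return generate_cohort(
        n_subjects=n_members,
        n_sessions=1,
        master_seed=master_seed,
        grid=grid,
        variability=variability,
        spread=LIBRARY_SPREAD,
        subject_prefix="L",
        out_dir=out_dir,
        operator_cycle=True,
    )
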