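"""kT-points pTx pulse design by magnitude least squares (MLS).

Three excitation strategies are designed here:

* **default** — a phase-only RF shim (one complex weight per channel, all
  magnitudes equal) computed once on a designated reference map set and then
  frozen for the whole study;
* **TP** — a subject-tailored kT-points pulse (default 4 points) optimized
  on one subject's maps from one session;
* **UP** — a universal kT-points pulse optimized jointly over a library of
  map sets with shared weights and shared k-space locations.

All designs minimize the small-tip-angle (STA) magnitude cost

    sum_r (|A_r w| - theta)^2 + lambda ||w||^2

where ``A`` maps the stacked complex channel/kT-point weights to the complex
transverse excitation at each ROI voxel and ``theta`` is the target flip
angle in degrees. The magnitude target is handled by a variable-exchange
iteration (alternating phase update / regularized least squares), and the
k-space locations of the kT-points are chosen by an interleaved greedy and
local scheme over a regular candidate grid.

The statsmodels-style entry points are :class:`KTPointsModel` and
:class:`KTPointsResults`; the module-level functions are the underlying
operations and remain the canonical API for scripting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .b1_synth import GAMMA_RAD_PER_S_PER_T, B1MapSet, ROIMask
from .exceptions import DesignError, GradientLimitError, NormalizationError
from .grids import GridSpec


@dataclass(frozen=True)
class DesignConfig:
    """Tunable parameters of the pulse design.

    ``lam`` is the Tikhonov weight on total RF power in normalized units;
    the candidate grid spans ``+/- k_extent_cycles`` cycles per field of
    view per axis in steps of ``k_step_cycles`` (and must contain k = 0).
    ``design_roi_cap`` bounds the number of ROI voxels the design matrix
    uses per map (evenly strided, deterministic); evaluation always uses
    the full ROI.
    """

    n_kt: int = 4
    target_fa_deg: float = 10.0
    lam: float = 5e-3
    k_extent_cycles: float = 2.0
    k_step_cycles: float = 1.0
    max_iter: int = 200
    tol: float = 1e-6
    greedy_score_iters: int = 10
    design_roi_cap: int = 256
    # Universal design homogenizes a margin around each library heart so
    # that displaced/changed anatomies still fall inside the uniform region
    # (voxels of binary dilation applied to library ROIs only). The dilated
    # regions are large, so the universal design gets a bigger row budget.
    up_roi_dilation: int = 3
    up_design_roi_cap: int = 512
    subpulse_duration_us: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.n_kt < 1:
            raise ValueError("need at least one kT-point")
        if self.tol <= 0:
            raise ValueError("convergence tolerance must be positive")
        if self.lam < 0:
            raise ValueError("regularization must be non-negative")
        vals = _axis_candidates(self.k_extent_cycles, self.k_step_cycles)
        if not np.any(vals == 0.0):
            raise ValueError("candidate grid must contain k = 0")


def _axis_candidates(extent: float, step: float) -> np.ndarray:
    n = int(round(extent / step))
    return step * np.arange(-n, n + 1, dtype=float)


def candidate_grid(grid: GridSpec, cfg: DesignConfig) -> np.ndarray:
    """Candidate k-space locations in rad/m, shape (n_cand, 3).

    Cycles per field of view are converted per axis; candidates are sorted
    by (||k||, kz, ky, kx) so that enumeration order is the documented,
    deterministic tie-break (smallest-norm candidates first).
    """
    fov_m = np.asarray(grid.fov_mm) / 1000.0
    axes = [
        2 * np.pi * _axis_candidates(cfg.k_extent_cycles, cfg.k_step_cycles) / f
        for f in fov_m
    ]
    KX, KY, KZ = np.meshgrid(axes[0], axes[1], axes[2], indexing="ij")
    cands = np.column_stack([KX.ravel(), KY.ravel(), KZ.ravel()])
    norms = np.linalg.norm(cands, axis=1)
    order = np.lexsort((cands[:, 0], cands[:, 1], cands[:, 2], norms))
    return cands[order]


def _design_rows(maps: B1MapSet, roi: ROIMask, cap: int | None):
    """(B, R): channel sensitivities and positions (m) at design ROI voxels.

    Rows follow the flattened C-order ROI voxel order; when ``cap`` is
    smaller than the ROI an evenly strided, deterministic subset is taken.
    """
    flat_idx = np.flatnonzero(roi.mask.ravel())
    if cap is not None and flat_idx.size > cap:
        sel = np.unique(np.round(np.linspace(0, flat_idx.size - 1, cap)).astype(int))
        flat_idx = flat_idx[sel]
    B = maps.data.reshape(maps.n_channels, -1)[:, flat_idx].T  # (n_r, C)
    R = maps.grid.positions_mm()[flat_idx] / 1000.0  # (n_r, 3) in metres
    return B, R


@dataclass
class STASystem:
    """Small-tip-angle system matrix for one or more map sets.

    ``A`` has one row per (design) ROI voxel and one column per
    (kT-point, channel) pair, ordered kT-major: column ``k * C + c`` holds
    ``c0 * b1_c(r) * exp(i k_k . r)``. ``c0`` converts normalized-B1 drive
    to degrees and equals the target flip angle, so unit total drive at a
    voxel with unit sum-of-magnitudes sensitivity yields the target.
    """

    A: np.ndarray  # complex, (n_rows, C * K)
    c0: float
    n_channels: int
    k_locations: np.ndarray  # (K, 3) rad/m
    row_offsets: np.ndarray = field(default=None)  # member boundaries for stacked systems

    @property
    def n_kt(self) -> int:
        return self.k_locations.shape[0]


_USE_CONFIG_CAP = "config"


def build_system(
    maps: B1MapSet,
    roi: ROIMask,
    k_locations: Sequence[Sequence[float]],
    cfg: DesignConfig,
    cap: int | None | str = _USE_CONFIG_CAP,
) -> STASystem:
    """Assemble the STA design matrix for given kT-point locations.

    ``cap`` limits the number of design rows (default: the config's row
    budget); pass ``None`` to use every ROI voxel.
    """
    if not maps.normalized:
        raise NormalizationError(
            "maps must be normalized first; call normalize_b1(maps, roi)"
        )
    k_locations = np.atleast_2d(np.asarray(k_locations, dtype=float))
    if cap == _USE_CONFIG_CAP:
        cap = cfg.design_roi_cap
    B, R = _design_rows(maps, roi, cap)
    if B.shape[0] == 0:
        raise DesignError("empty design system: ROI contains no voxels")
    phases = np.exp(1j * (R @ k_locations.T))  # (n_r, K)
    c0 = cfg.target_fa_deg
    blocks = [c0 * B * phases[:, k][:, None] for k in range(k_locations.shape[0])]
    A = np.concatenate(blocks, axis=1)
    return STASystem(A=A, c0=c0, n_channels=B.shape[1], k_locations=k_locations)


def mls_cost(A: np.ndarray, w: np.ndarray, theta: float, lam: float) -> float:
    """MLS cost: mean squared magnitude residual (deg^2) + lam * ||w||^2.

    The data term is the per-voxel mean so that lam has the same meaning
    regardless of ROI size or library size.
    """
    r = np.abs(A @ w) - theta
    return float(r @ r / A.shape[0] + lam * np.real(np.vdot(w, w)))


def cp_init(A: np.ndarray, theta: float) -> np.ndarray:
    """Phase-aligned initialization: align each column's mean phasor, then
    scale equal-magnitude weights to hit the mean target."""
    col_mean = A.mean(axis=0)
    phases = np.where(np.abs(col_mean) > 0, col_mean / np.abs(col_mean + (col_mean == 0)), 1.0)
    w = np.conj(phases)
    m = np.abs(A @ w).mean()
    if m > 0:
        w *= theta / m
    return w


def mls_variable_exchange(
    sys: STASystem,
    cfg: DesignConfig,
    init_weights: np.ndarray | None = None,
    max_iter: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Variable-exchange solver for the magnitude-least-squares problem.

    Alternates (i) the optimal target phase ``z = Aw / |Aw|`` and (ii) the
    regularized linear solve ``w = (A^H A + lam I)^-1 A^H (theta z)``. Both
    half-steps minimize the shared surrogate ``||Aw - theta z||^2 +
    lam ||w||^2``, so the recorded cost trace is non-increasing. Returns the
    weights and the cost trace (initial cost included).
    """
    A = sys.A
    if A.size == 0:
        raise DesignError("empty design system")
    if cfg.lam < 0:
        raise DesignError("regularization must be non-negative")
    theta = cfg.target_fa_deg
    lam = cfg.lam
    n_iter = cfg.max_iter if max_iter is None else max_iter

    w = cp_init(A, theta) if init_weights is None else np.asarray(init_weights, complex)
    n_rows = A.shape[0]
    G = A.conj().T @ A / n_rows + lam * np.eye(A.shape[1])
    # Factorization floor: at lam = 0 duplicate kT-point columns make G
    # exactly singular; a relative 1e-12 ridge keeps the solve defined
    # without measurably changing the minimizer.
    floor = 1e-12 * np.real(np.trace(G)) / G.shape[0]
    chol = cho_factor(G + floor * np.eye(G.shape[0]), lower=True)

    costs = [mls_cost(A, w, theta, lam)]
    for _ in range(n_iter):
        z = A @ w
        mag = np.abs(z)
        u = np.where(mag > 0, z / np.where(mag > 0, mag, 1.0), 1.0)
        w = cho_solve(chol, A.conj().T @ (theta * u) / n_rows)
        c = mls_cost(A, w, theta, lam)
        costs.append(c)
        if abs(costs[-2] - c) <= cfg.tol * max(costs[-2], 1e-30):
            break
    return w, np.asarray(costs)


def phase_only_shim_weights(
    sys: STASystem, cfg: DesignConfig, n_iter: int = 60
) -> np.ndarray:
    """Phase-only MLS: equal channel magnitudes, phases by alternating
    projection, magnitude scaled so the mean design-voxel FA hits target."""
    A = sys.A
    theta = cfg.target_fa_deg
    w = cp_init(A, theta)
    phi = np.angle(w)
    for _ in range(n_iter):
        z = A @ np.exp(1j * phi)
        mag = np.abs(z)
        u = np.where(mag > 0, z / np.where(mag > 0, mag, 1.0), 1.0)
        phi = np.angle(A.conj().T @ u)
    w = np.exp(1j * phi)
    m = np.abs(A @ w).mean()
    if m <= 0:
        raise DesignError("degenerate system: zero mean excitation")
    return (theta / m) * w


def _dilated_roi(roi: ROIMask, n_vox: int) -> ROIMask:
    """ROI grown by ``n_vox`` voxels of binary dilation (same grid)."""
    if n_vox <= 0:
        return roi
    from scipy import ndimage

    grown = ndimage.binary_dilation(roi.mask, iterations=int(n_vox))
    return ROIMask(grid=roi.grid, mask=grown)


def _stacked_system(
    members: Sequence[tuple[B1MapSet, ROIMask]],
    k_locations: np.ndarray,
    cfg: DesignConfig,
) -> STASystem:
    systems = [build_system(m, r, k_locations, cfg) for m, r in members]
    n_ch = {s.n_channels for s in systems}
    if len(n_ch) != 1:
        raise DesignError(f"library members have mismatched channel counts: {n_ch}")
    offsets = np.cumsum([0] + [s.A.shape[0] for s in systems])
    return STASystem(
        A=np.concatenate([s.A for s in systems], axis=0),
        c0=cfg.target_fa_deg,
        n_channels=n_ch.pop(),
        k_locations=k_locations,
        row_offsets=offsets,
    )


def greedy_local_kt_selection(
    members: Sequence[tuple[B1MapSet, ROIMask]],
    cfg: DesignConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interleaved greedy / local choice of kT-point locations.

    Starting from the best single candidate, each stage greedily adds the
    candidate that minimizes the MLS cost after re-solving the weights
    (truncated variable exchange for scoring), then locally re-solves the
    weights over all current locations to full tolerance. Stage
    initialization from the previous weights (new point at zero) guarantees
    the final cost with K points never exceeds the cost with K - 1.

    Returns ``(k_locations, weights, stage_costs)``.

    Ties are broken by candidate enumeration order: candidates are scanned
    sorted by (||k||, kz, ky, kx), and a candidate replaces the incumbent
    only if it improves the cost by more than a relative 1e-9.
    """
    if not members:
        raise DesignError("no map sets supplied")
    grid = members[0][0].grid
    cands = candidate_grid(grid, cfg)
    if cands.shape[0] == 0:
        raise DesignError("candidate grid is empty")

    # Precompute per-member design rows and candidate phase tables.
    n_ch = {m.n_channels for m, _ in members}
    if len(n_ch) != 1:
        raise DesignError(f"map sets have mismatched channel counts: {sorted(n_ch)}")
    rows = [_design_rows(m, r, cfg.design_roi_cap) for m, r in members]
    B_all = np.concatenate([c0B(b, cfg) for b, _ in rows], axis=0)  # (n, C)
    R_all = np.concatenate([r for _, r in rows], axis=0)
    E = np.exp(1j * (R_all @ cands.T))  # (n, n_cand)
    C = B_all.shape[1]
    theta, lam = cfg.target_fa_deg, cfg.lam

    selected: list[int] = []
    A_sel = np.empty((B_all.shape[0], 0), dtype=complex)
    w_prev: np.ndarray | None = None
    stage_costs: list[float] = []

    for stage in range(cfg.n_kt):
        best = (math.inf, -1, None)
        if w_prev is None:
            # One init shared by every candidate: scoring must rank the
            # candidates, not the luck of per-candidate initializations
            # (for K = 1 the cost is k-invariant, so a shared init also
            # makes the k = 0 tie-break exact).
            init = cp_init(B_all, theta)
        else:
            init = np.concatenate([w_prev, np.zeros(C, dtype=complex)])
        for j in range(cands.shape[0]):
            block = B_all * E[:, j][:, None]
            A_try = np.concatenate([A_sel, block], axis=1)
            sys_try = STASystem(A_try, theta, C, cands[: stage + 1])
            w_try, trace = mls_variable_exchange(
                sys_try, cfg, init_weights=init, max_iter=cfg.greedy_score_iters
            )
            cost = trace[-1]
            # Strict-improvement tie-break: the earlier (smaller-norm)
            # candidate keeps ties, with an absolute floor so that
            # numerically-zero costs do not reshuffle the order.
            if best[1] < 0 or cost < best[0] - (1e-9 * best[0] + 1e-12):
                best = (cost, j, w_try)
        j_best = best[1]
        assert j_best >= 0
        selected.append(j_best)
        A_sel = np.concatenate([A_sel, B_all * E[:, j_best][:, None]], axis=1)
        # Local step: full re-solve over all current locations.
        sys_sel = STASystem(A_sel, theta, C, cands[selected])
        if w_prev is None:
            init_full = best[2]
        else:
            init_full = np.concatenate([w_prev, np.zeros(C, dtype=complex)])
        w_prev, trace = mls_variable_exchange(sys_sel, cfg, init_weights=init_full)
        stage_costs.append(float(trace[-1]))

    return cands[selected], w_prev, np.asarray(stage_costs)


def c0B(B: np.ndarray, cfg: DesignConfig) -> np.ndarray:
    """Scale raw sensitivity rows by the degree-conversion constant."""
    return cfg.target_fa_deg * B


# ---------------------------------------------------------------------------
# Gradient blips
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientBlip:
    """One inter-kT-point gradient blip: triangular lobe per axis, shared
    duration, per-axis amplitude chosen so the k-space area is exact."""

    duration_us: float
    amplitudes_mT_m: tuple[float, float, float]


def realize_gradient_blips(
    k_locations: np.ndarray,
    max_amplitude_mT_m: float = 40.0,
    max_slew_T_m_s: float = 170.0,
    raster_us: float = 10.0,
    max_duration_us: float | None = None,
) -> list[GradientBlip]:
    """Triangular gradient blips realizing consecutive k-space displacements.

    For each gap the per-axis k-space area ``dk / gamma`` is produced by a
    triangle of shared duration T (the smallest raster multiple that
    respects both the amplitude and slew limits on every axis) with per-axis
    peak ``2 * area / T``, which reproduces ``dk`` exactly.
    """
    k_locations = np.atleast_2d(np.asarray(k_locations, dtype=float))
    if max_amplitude_mT_m <= 0 or max_slew_T_m_s <= 0:
        raise GradientLimitError("gradient limits must be positive")
    gmax = max_amplitude_mT_m * 1e-3  # T/m
    blips: list[GradientBlip] = []
    for j in range(k_locations.shape[0] - 1):
        dk = k_locations[j + 1] - k_locations[j]  # rad/m
        area = dk / GAMMA_RAD_PER_S_PER_T  # T*s/m per axis
        a = np.abs(area)
        if np.all(a == 0):
            blips.append(GradientBlip(0.0, (0.0, 0.0, 0.0)))
            continue
        # Minimal triangle duration per axis under slew and amplitude limits.
        t_slew = 2.0 * np.sqrt(a / max_slew_T_m_s)
        t_amp = 2.0 * a / gmax
        t_min = float(np.max(np.maximum(t_slew, t_amp)))
        duration_us = math.ceil(t_min * 1e6 / raster_us - 1e-9) * raster_us
        if max_duration_us is not None and duration_us > max_duration_us:
            raise GradientLimitError(
                f"k-space displacement {dk} rad/m needs a {duration_us:.0f} us "
                f"blip, exceeding the {max_duration_us:.0f} us limit",
                required_duration_us=duration_us,
            )
        T = duration_us * 1e-6
        amps = 2.0 * area / T  # T/m, signed
        blips.append(GradientBlip(float(duration_us), tuple(1e3 * amps)))
    return blips


# ---------------------------------------------------------------------------
# Pulse container and the three design entry points
# ---------------------------------------------------------------------------

@dataclass
class KTPointsPulse:
    """A designed kT-points pulse (weights in arbitrary relative volts)."""

    weights: np.ndarray  # complex, (C, K)
    k_locations: np.ndarray  # (K, 3) rad/m
    target_fa_deg: float
    method: str  # "default" | "TP" | "UP"
    subpulse_duration_us: float = 100.0
    blips: list[GradientBlip] = field(default_factory=list)
    design_meta: dict = field(default_factory=dict)
    lam: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.complex128)
        self.k_locations = np.atleast_2d(np.asarray(self.k_locations, dtype=float))
        if self.weights.ndim != 2:
            raise ValueError("weights must have shape (channels, n_kt)")
        if self.k_locations.shape != (self.n_kt, 3):
            raise ValueError(
                f"k_locations shape {self.k_locations.shape} inconsistent with "
                f"{self.n_kt} kT-points"
            )
        if self.method == "default":
            if self.n_kt != 1 or np.any(self.k_locations != 0):
                raise ValueError("default shim must be a single kT-point at k = 0")
            mags = np.abs(self.weights[:, 0])
            if not np.allclose(mags, mags[0], rtol=1e-9, atol=1e-12):
                raise ValueError("default shim weights must share one magnitude")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]

    @property
    def n_kt(self) -> int:
        return self.weights.shape[1]

    @property
    def stacked_weights(self) -> np.ndarray:
        """Weights flattened kT-major to match STASystem column order."""
        return self.weights.T.reshape(-1)


def _finalize_pulse(
    w: np.ndarray, k_locations: np.ndarray, cfg: DesignConfig, method: str, meta: dict
) -> KTPointsPulse:
    K = k_locations.shape[0]
    C = w.size // K
    weights = w.reshape(K, C).T
    return KTPointsPulse(
        weights=weights,
        k_locations=k_locations,
        target_fa_deg=cfg.target_fa_deg,
        method=method,
        subpulse_duration_us=cfg.subpulse_duration_us,
        blips=realize_gradient_blips(k_locations) if K > 1 else [],
        design_meta=meta,
        lam=cfg.lam,
        seed=cfg.seed,
    )


def _nominal_fa_scale(w: np.ndarray, A: np.ndarray, theta: float) -> np.ndarray:
    """Scale weights so the mean design-ROI flip angle equals the target.

    Standard nominal-FA normalization: the power penalty biases the raw MLS
    solution slightly below target; this one-time global scale (no
    per-subject recalibration) removes that bias. CV is scale-invariant, so
    homogeneity is unaffected.
    """
    m = np.abs(A @ w).mean()
    return w * (theta / m) if m > 0 else w


def design_tailored(
    maps: B1MapSet, roi: ROIMask, cfg: DesignConfig = DesignConfig(), meta: dict | None = None
) -> KTPointsPulse:
    """Subject-tailored kT-points pulse for one session's maps."""
    k_locs, _, _ = greedy_local_kt_selection([(maps, roi)], cfg)
    sys = build_system(maps, roi, k_locs, cfg)
    w, trace = mls_variable_exchange(sys, cfg)
    w = _nominal_fa_scale(w, sys.A, cfg.target_fa_deg)
    m = {"method": "TP", "final_cost": float(trace[-1]), "n_iter": len(trace) - 1}
    m.update(meta or {})
    return _finalize_pulse(w, k_locs, cfg, "TP", m)


def design_universal(
    library: Sequence[tuple[B1MapSet, ROIMask]],
    cfg: DesignConfig = DesignConfig(),
    meta: dict | None = None,
    scale_reference: Sequence[tuple[B1MapSet, ROIMask]] | None = None,
) -> KTPointsPulse:
    """Universal kT-points pulse over a library, equal member weighting.

    The design region is each library heart grown by ``cfg.up_roi_dilation``
    voxels, so the uniform region extends beyond the heart and tolerates
    anatomy/placement change. The absolute scale is calibrated once: on the
    ``scale_reference`` ensemble (e.g. a standard-anatomy reference scanned
    over the protocol's placement states) when given, otherwise on the
    stacked undilated library hearts. No per-subject adjustment is made.
    """
    if len(library) < 2:
        raise DesignError("universal design needs at least two library members")
    import dataclasses

    cfg_up = dataclasses.replace(cfg, design_roi_cap=cfg.up_design_roi_cap)
    members = [(m, _dilated_roi(r, cfg.up_roi_dilation)) for m, r in library]
    k_locs, _, _ = greedy_local_kt_selection(members, cfg_up)
    sys = _stacked_system(members, k_locs, cfg_up)
    w, trace = mls_variable_exchange(sys, cfg_up)
    scale_pairs = list(scale_reference) if scale_reference else list(library)
    sys_scale = _stacked_system(scale_pairs, k_locs, cfg)
    w = _nominal_fa_scale(w, sys_scale.A, cfg.target_fa_deg)
    m = {
        "method": "UP",
        "library_size": len(library),
        "final_cost": float(trace[-1]),
        "n_iter": len(trace) - 1,
    }
    m.update(meta or {})
    return _finalize_pulse(w, k_locs, cfg, "UP", m)


def default_shim(
    cfg: DesignConfig, reference: B1MapSet, reference_roi: ROIMask, meta: dict | None = None
) -> KTPointsPulse:
    """Phase-only RF shim computed once on the reference map set, then frozen.

    Stands in for a vendor-supplied shim: equal channel magnitudes, phases
    from phase-only MLS on the reference, magnitude scaled so the mean ROI
    flip angle equals the target on the reference.
    """
    k0 = np.zeros((1, 3))
    sys = build_system(reference, reference_roi, k0, cfg)
    w = phase_only_shim_weights(sys, cfg)
    m = {"method": "default"}
    m.update(meta or {})
    return _finalize_pulse(w, k0, cfg, "default", m)


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class KTPointsModel:
    """Pulse-design model over one map set (tailored) or a library (universal).

    Examples
    --------
    >>> model = KTPointsModel(maps, roi, DesignConfig(n_kt=4))
    >>> res = model.fit()
    >>> res.pulse.method
    'TP'
    >>> res.cv()  # CV (%) of the predicted flip angle on the design ROI
    """

    def __init__(
        self,
        maps: B1MapSet | None = None,
        roi: ROIMask | None = None,
        config: DesignConfig = DesignConfig(),
        method: str = "tailored",
        library: Sequence[tuple[B1MapSet, ROIMask]] | None = None,
    ):
        if method not in ("tailored", "universal", "default"):
            raise ValueError(f"unknown design method {method!r}")
        if method == "universal":
            if library is None:
                raise DesignError("universal design requires a library")
        elif maps is None or roi is None:
            raise DesignError(f"{method} design requires maps and roi")
        self.maps = maps
        self.roi = roi
        self.config = config
        self.method = method
        self.library = list(library) if library is not None else None

    @classmethod
    def from_library(
        cls, library: Sequence[tuple[B1MapSet, ROIMask]], config: DesignConfig = DesignConfig()
    ) -> "KTPointsModel":
        return cls(config=config, method="universal", library=library)

    def fit(self) -> "KTPointsResults":
        if self.method == "tailored":
            pulse = design_tailored(self.maps, self.roi, self.config)
            eval_pair = (self.maps, self.roi)
        elif self.method == "universal":
            pulse = design_universal(self.library, self.config)
            eval_pair = self.library[0]
        else:
            pulse = default_shim(self.config, self.maps, self.roi)
            eval_pair = (self.maps, self.roi)
        return KTPointsResults(self, pulse, eval_pair)


class KTPointsResults:
    """Fitted pulse plus prediction/diagnostic helpers."""

    def __init__(self, model: KTPointsModel, pulse: KTPointsPulse, eval_pair):
        self.model = model
        self.pulse = pulse
        self._eval_pair = eval_pair

    def predict(self, maps: B1MapSet | None = None):
        """Predicted STA flip-angle map on the full grid (degrees)."""
        from .fa_eval import predict_fa_sta

        maps = maps if maps is not None else self._eval_pair[0]
        return predict_fa_sta(maps, self.pulse)

    def cv(self, maps: B1MapSet | None = None, roi: ROIMask | None = None) -> float:
        from .fa_eval import compute_cv

        roi = roi if roi is not None else self._eval_pair[1]
        return compute_cv(self.predict(maps), roi)

    def rf_metrics(self):
        from .fa_eval import rf_metrics

        return rf_metrics(self.pulse)

    def summary(self) -> str:
        p = self.pulse
        met = self.rf_metrics()
        lines = [
            "kT-points pulse design results",
            "=" * 34,
            f"method             : {p.method}",
            f"channels           : {p.n_channels}",
            f"kT-points          : {p.n_kt}",
            f"target FA (deg)    : {p.target_fa_deg:g}",
            f"lambda             : {p.lam:g}",
            f"peak |w| (rel. V)  : {met.peak_voltage:.4f}",
            f"mean power (rel.)  : {met.mean_power:.4f}",
            f"CV on design ROI % : {self.cv():.2f}",
        ]
        for k, loc in enumerate(p.k_locations):
            lines.append(
                f"k[{k}] (rad/m)      : ({loc[0]:+.2f}, {loc[1]:+.2f}, {loc[2]:+.2f})"
            )
        if "final_cost" in p.design_meta:
            lines.append(f"final MLS cost     : {p.design_meta['final_cost']:.6g}")
        return "\n".join(lines)
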