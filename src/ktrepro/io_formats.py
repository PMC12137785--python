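"""File formats: HDF5 field-map containers, pulse JSON, manifest/result CSVs.

Layouts
-------
HDF5 container (one per subject/session):

* ``/b1/real``, ``/b1/imag`` — float64, shape ``(C, Nx, Ny, Nz)``
* ``/roi/mask`` — uint8
* ``/fa/<pulse_id>`` — optional float64 flip-angle layers (degrees)
* root attributes: ``schema_version``, ``spacing_mm``, ``origin_mm``,
  ``normalized`` (0/1), plus free-form extras such as ``seed``/``operator``.

Pulse JSON: human-auditable record of a designed pulse — complex weights as
real/imag ``(C, K)`` lists, k-locations in rad/m, subpulse timing, realized
gradient blips and design metadata. All round-trips are bit-exact for
64-bit floats; validation failures raise typed errors, never coerce.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .b1_synth import B1MapSet, ROIMask
from .exceptions import SchemaError, ValidationError
from .fa_eval import FAMap
from .grids import GridSpec
from .pulse_design import GradientBlip, KTPointsPulse

CONTAINER_SCHEMA_VERSION = 1
PULSE_FORMAT_VERSION = 1

_PULSE_FIELDS = {
    "version", "method", "channels", "n_kt", "target_fa_deg", "weights_real",
    "weights_imag", "k_locations_rad_per_m", "subpulse_duration_us", "blips",
    "design_meta", "lambda", "seed",
}


@dataclass(frozen=True)
class ContainerHandle:
    """Inventory of one HDF5 container."""

    path: str
    schema_version: int
    inventory: tuple[str, ...]
    fa_layers: tuple[str, ...]


def write_container(
    path, maps: B1MapSet, roi: ROIMask, fa_layers: dict[str, FAMap] | None = None,
    attrs: dict | None = None,
) -> ContainerHandle:
    """Write maps, ROI and optional FA layers to one HDF5 file."""
    if roi.grid.shape != maps.grid.shape:
        raise ValidationError("grid mismatch between /b1 and /roi datasets")
    for name, fa in (fa_layers or {}).items():
        if fa.grid.shape != maps.grid.shape:
            raise ValidationError(f"grid mismatch between /b1 and /fa/{name}")
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("b1/real", data=maps.data.real.astype(np.float64))
        f.create_dataset("b1/imag", data=maps.data.imag.astype(np.float64))
        f.create_dataset("roi/mask", data=roi.mask.astype(np.uint8))
        for name, fa in (fa_layers or {}).items():
            f.create_dataset(f"fa/{name}", data=fa.fa.astype(np.float64))
        f.attrs["schema_version"] = CONTAINER_SCHEMA_VERSION
        f.attrs["spacing_mm"] = np.asarray(maps.grid.spacing_mm, dtype=np.float64)
        f.attrs["origin_mm"] = np.asarray(maps.grid.origin_mm, dtype=np.float64)
        f.attrs["normalized"] = int(maps.normalized)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
    return inspect_container(path)


def inspect_container(path) -> ContainerHandle:
    with h5py.File(path, "r") as f:
        _check_schema(f, path)
        inventory = []
        f.visit(lambda name: inventory.append(name))
        fa_ids = tuple(sorted(f["fa"].keys())) if "fa" in f else ()
    return ContainerHandle(
        path=str(path),
        schema_version=CONTAINER_SCHEMA_VERSION,
        inventory=tuple(sorted(inventory)),
        fa_layers=fa_ids,
    )


def _check_schema(f: h5py.File, path):
    version = int(f.attrs.get("schema_version", -1))
    if version != CONTAINER_SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: container schema version {version} != supported "
            f"{CONTAINER_SCHEMA_VERSION}"
        )
    for required in ("b1/real", "b1/imag", "roi/mask"):
        if required not in f:
            raise SchemaError(f"{path}: missing required dataset /{required}")


def read_container(path) -> tuple[B1MapSet, ROIMask, dict[str, FAMap]]:
    """Read one container; inverse of :func:`write_container` bit-for-bit."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        _check_schema(f, path)
        real = f["b1/real"][()]
        imag = f["b1/imag"][()]
        if real.shape != imag.shape:
            raise ValidationError(
                f"{path}: /b1/real shape {real.shape} != /b1/imag shape {imag.shape}"
            )
        mask = f["roi/mask"][()].astype(bool)
        grid = GridSpec(
            shape=tuple(int(n) for n in real.shape[1:]),
            spacing_mm=tuple(float(s) for s in f.attrs["spacing_mm"]),
            origin_mm=tuple(float(o) for o in f.attrs["origin_mm"]),
        )
        if mask.shape != grid.shape:
            raise ValidationError(
                f"{path}: grid mismatch between datasets /b1 ({grid.shape}) "
                f"and /roi/mask ({mask.shape})"
            )
        meta = {
            k: f.attrs[k]
            for k in f.attrs
            if k not in ("schema_version", "spacing_mm", "origin_mm", "normalized")
        }
        maps = B1MapSet(
            grid=grid,
            data=real + 1j * imag,
            normalized=bool(int(f.attrs["normalized"])),
            meta={k: (v.item() if hasattr(v, "item") else v) for k, v in meta.items()},
        )
        roi = ROIMask(grid=grid, mask=mask)
        fa_layers = {}
        if "fa" in f:
            for name in f["fa"]:
                arr = f[f"fa/{name}"][()]
                if arr.shape != grid.shape:
                    raise ValidationError(
                        f"{path}: grid mismatch between /b1 and /fa/{name}"
                    )
                fa_layers[name] = FAMap(grid=grid, fa=arr, provenance={"file": name})
    return maps, roi, fa_layers


# ---------------------------------------------------------------------------
# Pulse JSON
# ---------------------------------------------------------------------------

def write_pulse(pulse: KTPointsPulse, path) -> None:
    payload = {
        "version": PULSE_FORMAT_VERSION,
        "method": pulse.method,
        "channels": pulse.n_channels,
        "n_kt": pulse.n_kt,
        "target_fa_deg": pulse.target_fa_deg,
        "weights_real": pulse.weights.real.tolist(),
        "weights_imag": pulse.weights.imag.tolist(),
        "k_locations_rad_per_m": pulse.k_locations.tolist(),
        "subpulse_duration_us": pulse.subpulse_duration_us,
        "blips": [
            {"amplitudes_mT_m": list(b.amplitudes_mT_m), "duration_us": b.duration_us}
            for b in pulse.blips
        ],
        "design_meta": _jsonable(pulse.design_meta),
        "lambda": pulse.lam,
        "seed": pulse.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_pulse(path) -> KTPointsPulse:
    """Read a pulse JSON; tolerates unknown fields with a warning."""
    payload = json.loads(Path(path).read_text())
    version = payload.get("version")
    if version != PULSE_FORMAT_VERSION:
        raise SchemaError(
            f"{path}: pulse format version {version} != supported "
            f"{PULSE_FORMAT_VERSION}"
        )
    unknown = set(payload) - _PULSE_FIELDS
    if unknown:
        warnings.warn(f"{path}: ignoring unknown pulse fields {sorted(unknown)}")
    wr = np.asarray(payload["weights_real"], dtype=float)
    wi = np.asarray(payload["weights_imag"], dtype=float)
    C, K = int(payload["channels"]), int(payload["n_kt"])
    if wr.shape != (C, K) or wi.shape != (C, K):
        raise ValidationError(
            f"{path}: weight arrays must have shape ({C}, {K}), got "
            f"{wr.shape} / {wi.shape}"
        )
    k_locs = np.asarray(payload["k_locations_rad_per_m"], dtype=float)
    if k_locs.shape != (K, 3):
        raise ValidationError(
            f"{path}: n_kt = {K} but k_locations has shape {k_locs.shape}"
        )
    blips = [
        GradientBlip(
            duration_us=float(b["duration_us"]),
            amplitudes_mT_m=tuple(float(a) for a in b["amplitudes_mT_m"]),
        )
        for b in payload["blips"]
    ]
    return KTPointsPulse(
        weights=wr + 1j * wi,
        k_locations=k_locs,
        target_fa_deg=float(payload["target_fa_deg"]),
        method=str(payload["method"]),
        subpulse_duration_us=float(payload["subpulse_duration_us"]),
        blips=blips,
        design_meta=dict(payload.get("design_meta", {})),
        lam=float(payload["lambda"]),
        seed=int(payload["seed"]),
    )


# ---------------------------------------------------------------------------
# Manifests and result tables
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["subject", "session", "operator", "path", "seed"]


def write_manifest(manifest: pd.DataFrame, path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValidationError(f"manifest missing columns {missing}")
    manifest[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject": str, "operator": str, "path": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: manifest missing columns {missing}")
    return df


def validate_file(path) -> str:
    """Validate any artifact file by extension; returns a short description."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        handle = inspect_container(path)
        return (
            f"container schema v{handle.schema_version}, datasets: "
            f"{', '.join(handle.inventory)}"
        )
    if path.suffix == ".json":
        pulse = read_pulse(path)
        return (
            f"pulse file: method={pulse.method}, channels={pulse.n_channels}, "
            f"n_kt={pulse.n_kt}"
        )
    if path.suffix == ".csv":
        df = read_manifest(path)
        return f"manifest with {len(df)} entries"
    raise ValidationError(f"unrecognized file type: {path.suffix}")
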