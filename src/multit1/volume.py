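"""Voxelwise fitting of 4D inversion-recovery NIfTI series.

A measured (or simulated) acquisition is a 4D magnitude volume — one 3D image
per inversion time — plus a sidecar plain-text TI schedule (one millisecond
value per line; NIfTI headers cannot carry arbitrary schedules portably).
``fit_volume`` applies the multi-start bounded fit independently to every
masked voxel and assembles per-component M0/T1 maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .model import InversionRecoverySeries, ParameterBounds
from .solver import MultiStartConfig, SolverConfig, multistart_fit

__all__ = ["VolumeSeries", "ComponentMaps", "read_volume_series", "write_component_maps", "fit_volume"]


@dataclass
class VolumeSeries:
    """4D magnitude data (x, y, z, TI) with its schedule and optional mask."""

    data: np.ndarray
    ti_ms: np.ndarray
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError(f"expected a 4D series, got {self.data.ndim}D")
        if self.ti_ms.size != self.data.shape[-1]:
            raise ValueError(
                f"TI schedule has {self.ti_ms.size} entries but the series holds "
                f"{self.data.shape[-1]} volumes"
            )
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match spatial shape "
                f"{self.data.shape[:3]}"
            )


@dataclass
class ComponentMaps:
    """Per-component M0 and T1 volumes plus fit diagnostics.

    ``m0``/``t1_ms`` have shape (x, y, z, n_components); voxels outside the
    mask (or with failed fits) carry NaN, and ``converged`` counts the starts
    that reported convergence (-1 where unfitted).
    """

    m0: np.ndarray
    t1_ms: np.ndarray
    objective: np.ndarray
    converged: np.ndarray
    affine: np.ndarray


def read_volume_series(image_path, ti_path, mask_path=None) -> VolumeSeries:
    """Load a 4D NIfTI series, its TI schedule, and an optional mask."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{image_path}: expected a 4D image, got {data.ndim}D")
    ti = np.loadtxt(str(ti_path), dtype=float).ravel()
    if ti.size != data.shape[-1]:
        raise ValueError(
            f"TI schedule ({ti.size} entries) does not match the number of "
            f"volumes ({data.shape[-1]})"
        )
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    return VolumeSeries(data=data, ti_ms=ti, mask=mask, affine=np.asarray(img.affine))


def write_component_maps(maps: ComponentMaps, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, volume in (
        ("m0_maps", maps.m0),
        ("t1_ms_maps", maps.t1_ms),
        ("objective_map", maps.objective),
        ("convergence_map", maps.converged.astype(np.float64)),
    ):
        path = outdir / f"{name}.nii"
        nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), maps.affine), path)
        paths[name] = str(path)
    return paths


def fit_volume(
    series: VolumeSeries,
    n_components: int,
    bounds: ParameterBounds,
    mconfig: MultiStartConfig,
    config: SolverConfig | None = None,
    log_every: int = 0,
) -> ComponentMaps:
    """Multi-start fit applied independently to every masked voxel.

    Each voxel draws its starting points from a substream derived from
    (master seed, flat voxel index), so results are independent of traversal
    order and bit-identical across runs with the same seed.
    """
    if series.ti_ms.size < 2 * n_components:
        raise ValueError(
            f"{series.ti_ms.size} inversion times cannot identify "
            f"{n_components} components"
        )
    spatial = series.data.shape[:3]
    flat = series.data.reshape(-1, series.data.shape[-1])
    indices = np.flatnonzero(series.mask.ravel())
    m0 = np.full(spatial + (n_components,), np.nan)
    t1 = np.full(spatial + (n_components,), np.nan)
    obj = np.full(spatial, np.nan)
    conv = np.full(spatial, -1, dtype=int)
    m0_flat = m0.reshape(-1, n_components)
    t1_flat = t1.reshape(-1, n_components)
    obj_flat = obj.reshape(-1)
    conv_flat = conv.reshape(-1)
    for count, idx in enumerate(indices, start=1):
        voxel = InversionRecoverySeries(ti_ms=series.ti_ms, magnitude=flat[idx])
        rng = np.random.default_rng(np.random.SeedSequence([mconfig.seed, int(idx)]))
        try:
            fit = multistart_fit(
                voxel, bounds, mconfig, config, n_components=n_components, rng=rng
            )
        except Exception:
            conv_flat[idx] = 0  # recorded as failed, never aborts the volume
            continue
        m0_flat[idx] = fit.best_params.m0
        t1_flat[idx] = fit.best_params.t1_ms
        obj_flat[idx] = fit.best_objective
        conv_flat[idx] = int(fit.converged_flags.sum())
        if log_every and count % log_every == 0:
            print(f"fitted {count}/{indices.size} voxels", flush=True)
    return ComponentMaps(
        m0=m0, t1_ms=t1, objective=obj, converged=conv, affine=series.affine
    )
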