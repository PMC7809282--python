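"""En-face layer maps: thickness and reflectivity projections, and stimulus sampling.

An OCT volume is a stack of A-scans (axial reflectivity profiles) on a regular
en-face lattice.  For each segmented retinal layer we reduce the voxels between
the layer's upper and lower boundary surfaces to four per-A-scan summaries:
thickness (boundary distance in micrometres) and the minimum / mean / maximum
reflectivity.  These 2-D maps are then sampled at perimetry stimulus locations
by averaging all pixels whose centres fall inside a 0.43-degree-diameter disc
(the Goldmann III stimulus size), yielding the 20 imaging features per point
(5 layers x {thickness, min, mean, max intensity}).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Conversion between visual angle and retinal distance for an emmetropic
#: schematic eye, micrometres per degree.
MICRON_PER_DEGREE = 291.0

LAYERS = ("FR", "IR", "ONL", "ISOS", "RPE")
MAP_KINDS = ("thickness", "min_int", "mean_int", "max_int")

#: Canonical order of the 20 imaging feature names.
FEATURE_NAMES = tuple(f"{layer}_{kind}" for layer in LAYERS for kind in MAP_KINDS)

STIMULUS_DIAMETER_DEG = 0.43


@dataclass
class LatticeInfo:
    """Regular en-face lattice geometry.

    ``x0_deg``/``y0_deg`` are the coordinates of the centre of pixel [0, 0];
    ``deg_per_px`` is the (square) pixel pitch.
    """

    x0_deg: float
    y0_deg: float
    deg_per_px: float
    nx: int
    ny: int

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x0_deg + self.deg_per_px * np.arange(self.nx)
        ys = self.y0_deg + self.deg_per_px * np.arange(self.ny)
        return xs, ys


@dataclass
class LayerMaps:
    """Per-layer thickness and min/mean/max reflectivity projection maps.

    ``maps[layer][kind]`` is a 2-D array indexed [iy, ix] on ``lattice``.
    Thickness is in micrometres, reflectivity in arbitrary units.
    """

    lattice: LatticeInfo
    maps: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def validate(self) -> None:
        for layer, kinds in self.maps.items():
            for kind, arr in kinds.items():
                if arr.shape != (self.lattice.ny, self.lattice.nx):
                    raise ValueError(
                        f"map {layer}/{kind} has shape {arr.shape}, "
                        f"lattice is {(self.lattice.ny, self.lattice.nx)}"
                    )
            if {"min_int", "mean_int", "max_int"} <= set(kinds):
                if not (
                    np.all(kinds["min_int"] <= kinds["mean_int"] + 1e-12)
                    and np.all(kinds["mean_int"] <= kinds["max_int"] + 1e-12)
                ):
                    raise ValueError(f"projection ordering violated for layer {layer}")


def project_layer(
    volume: np.ndarray,
    upper: np.ndarray,
    lower: np.ndarray,
    axial_pitch_um: float = 3.87,
) -> dict[str, np.ndarray]:
    """Reduce one layer of a reflectivity volume to thickness and projections.

    Parameters
    ----------
    volume
        Reflectivity block, shape (ny, nx, nz); axis 2 is depth (A-scan).
    upper, lower
        Boundary surfaces in voxel units, shape (ny, nx); the layer comprises
        voxels with index in ``[ceil(upper), lower)`` i.e. strictly between the
        boundaries, half-open at the lower boundary.
    axial_pitch_um
        Axial voxel size; thickness = (lower - upper) * pitch.

    Returns
    -------
    dict with keys ``thickness``, ``min_int``, ``mean_int``, ``max_int``.

    A zero-thickness A-scan (upper == lower) yields thickness 0 and all three
    projections equal to the voxel value at the shared boundary.
    """
    volume = np.asarray(volume, dtype=float)
    upper = np.asarray(upper, dtype=float)
    lower = np.asarray(lower, dtype=float)
    if volume.ndim != 3:
        raise ValueError("volume must be 3-D (ny, nx, nz)")
    ny, nx, nz = volume.shape
    if upper.shape != (ny, nx) or lower.shape != (ny, nx):
        raise ValueError("boundary surfaces must match the en-face lattice")
    bad = np.argwhere(upper > lower)
    if bad.size:
        iy, ix = bad[0]
        raise ValueError(
            f"crossing boundaries at A-scan (iy={iy}, ix={ix}): "
            f"upper={upper[iy, ix]:.2f} > lower={lower[iy, ix]:.2f}"
        )

    thickness = (lower - upper) * axial_pitch_um
    zidx = np.arange(nz)[None, None, :]
    inside = (zidx >= np.ceil(upper)[..., None]) & (zidx < lower[..., None])
    counts = inside.sum(axis=2)

    mn = np.where(inside, volume, np.inf).min(axis=2)
    mx = np.where(inside, volume, -np.inf).max(axis=2)
    sums = np.where(inside, volume, 0.0).sum(axis=2)
    mean = sums / np.maximum(counts, 1)

    # degenerate A-scans: fall back to the voxel at the shared boundary
    empty = counts == 0
    if np.any(empty):
        bidx = np.clip(np.floor(upper).astype(int), 0, nz - 1)
        bval = np.take_along_axis(volume, bidx[..., None], axis=2)[..., 0]
        mn = np.where(empty, bval, mn)
        mx = np.where(empty, bval, mx)
        mean = np.where(empty, bval, mean)

    return {
        "thickness": thickness,
        "min_int": mn,
        "mean_int": mean,
        "max_int": mx,
    }


def _disc_pixel_mask(lattice: LatticeInfo, x: float, y: float, radius: float) -> np.ndarray:
    xs, ys = lattice.pixel_centers()
    dx = xs[None, :] - x
    dy = ys[:, None] - y
    return dx * dx + dy * dy <= radius * radius  # centre-in-disc, ties included


def sample_at_stimuli(
    maps: LayerMaps,
    grid,
    aperture_deg: float = STIMULUS_DIAMETER_DEG,
) -> pd.DataFrame:
    """Average each of the 20 maps over the stimulus disc at every grid point.

    Parameters
    ----------
    maps
        LayerMaps with all five layers and four map kinds.
    grid
        Object with a ``points`` DataFrame carrying columns
        ``point_id, x_deg, y_deg`` (a ``simulate.StimulusGrid``), or such a
        DataFrame directly.
    aperture_deg
        Stimulus diameter in degrees (Goldmann III = 0.43).

    Returns
    -------
    DataFrame indexed like the grid with one column per imaging feature.
    If the disc at a point contains no pixel centre, the nearest pixel is used
    (sub-pixel aperture on a coarse lattice).
    """
    points = getattr(grid, "points", grid)
    radius = aperture_deg / 2.0
    lat = maps.lattice
    xs, ys = lat.pixel_centers()

    out_of_extent = [
        str(pid)
        for pid, x, y in zip(points["point_id"], points["x_deg"], points["y_deg"])
        if not (xs[0] - radius <= x <= xs[-1] + radius and ys[0] - radius <= y <= ys[-1] + radius)
    ]
    if out_of_extent:
        raise ValueError(f"stimulus points outside map extent: {out_of_extent}")

    records = []
    for pid, x, y in zip(points["point_id"], points["x_deg"], points["y_deg"]):
        mask = _disc_pixel_mask(lat, x, y, radius)
        if not mask.any():
            iy = int(np.argmin(np.abs(ys - y)))
            ix = int(np.argmin(np.abs(xs - x)))
            mask = np.zeros_like(mask)
            mask[iy, ix] = True
        row = {"point_id": pid}
        for layer in LAYERS:
            for kind in MAP_KINDS:
                row[f"{layer}_{kind}"] = float(maps.maps[layer][kind][mask].mean())
        records.append(row)
    return pd.DataFrame.from_records(records).set_index("point_id")


def sample_at_stimuli_bruteforce(
    maps: LayerMaps, grid, aperture_deg: float = STIMULUS_DIAMETER_DEG
) -> pd.DataFrame:
    """Per-pixel loop oracle for :func:`sample_at_stimuli` (test reference)."""
    points = getattr(grid, "points", grid)
    radius = aperture_deg / 2.0
    lat = maps.lattice
    xs, ys = lat.pixel_centers()
    records = []
    for pid, x, y in zip(points["point_id"], points["x_deg"], points["y_deg"]):
        hits = [
            (iy, ix)
            for iy in range(lat.ny)
            for ix in range(lat.nx)
            if (xs[ix] - x) ** 2 + (ys[iy] - y) ** 2 <= radius**2
        ]
        if not hits:
            iy = min(range(lat.ny), key=lambda i: abs(ys[i] - y))
            ix = min(range(lat.nx), key=lambda i: abs(xs[i] - x))
            hits = [(iy, ix)]
        row = {"point_id": pid}
        for layer in LAYERS:
            for kind in MAP_KINDS:
                vals = [maps.maps[layer][kind][iy, ix] for iy, ix in hits]
                row[f"{layer}_{kind}"] = float(np.mean(vals))
        records.append(row)
    return pd.DataFrame.from_records(records).set_index("point_id")


def register(maps: LayerMaps, transform=None) -> LayerMaps:
    """Registration hook between functional and structural coordinates.

    Synthetic cohorts carry exact coordinates, so the default transform is the
    identity; the hook exists so that a real-world non-linear registration can
    be slotted in without touching the sampling code.
    """
    if transform is None:
        return maps
    return transform(maps)
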