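"""Synthetic X-gal / DAPI image pairs with exact ground truth.

Emulates brightfield images of an X-gal-stained monolayer culture — blue-
teal cytoplasmic stain on a near-white background — together with matching
DAPI fluorescence images (bright nuclear disks on a dark background), from
shared geometry, so that every measurement in this package can be checked
against a known answer without real microscope data.

The colour model is a linear darkening ramp, not stain optics: a cell with
stain intensity ``s`` in [0, 1] has cytoplasm colour

    R = 250 - 190 s,  G = 250 - 120 s,  B = 250 - 20 s

so increasing ``s`` shifts the colour from near-white toward dark blue-teal
and monotonically raises the inverted-grayscale value.  Ground truth
(positive-pixel mask and integrated density) is computed on the noise-free
8-bit image before Gaussian sensor noise is added, so oracle comparisons
are exact.  Cells are non-overlapping ellipses placed by rejection
sampling, matching a sub-confluent monolayer; nuclei are disks at the cell
centres (several per cell in multinucleated mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_field",
    "generate_experiment",
    "timecourse_preset",
    "two_group_preset",
]

#: Linear darkening per unit stain intensity, per channel (R, G, B).
STAIN_SLOPE = (190.0, 120.0, 20.0)
CYTO_BASE = 250.0
DAPI_FG = 200.0
DAPI_BG = 10.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic field of view.

    ``stain_intensity`` is a ``(mean, sd)`` pair; per-cell intensities are
    drawn from a normal with those moments and clipped to [0, 1].  The
    same sampled geometry drives both the brightfield and DAPI images.
    Defaults model a sub-confluent culture imaged at moderate
    magnification, scaled to a desk-size frame.
    """

    image_size: tuple[int, int] = (320, 320)
    n_cells: int = 8
    cell_radius_px: tuple[float, float] = (12.0, 20.0)
    stain_intensity: tuple[float, float] = (0.5, 0.05)
    nuclei_per_cell: int = 1
    nucleus_radius_px: tuple[float, float] = (5.0, 8.0)
    background_rgb: tuple[int, int, int] = (250, 250, 248)
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.nuclei_per_cell < 1:
            raise ValueError("n_cells must be >= 0 and nuclei_per_cell >= 1")
        if self.cell_radius_px[0] > self.cell_radius_px[1]:
            raise ValueError("cell_radius_px must be (min, max)")
        if self.nucleus_radius_px[1] >= self.cell_radius_px[0]:
            raise ValueError("nuclei must fit inside the smallest cell")


@dataclass
class GroundTruth:
    """Exact per-field truth, computed on the noise-free image.

    ``true_integrated_density`` is the sum of ``255 - (R+G+B)/3`` over
    ``stain_mask`` of the noise-free 8-bit brightfield image
    (``clean_bf``), so a measurement on that image with that mask must
    reproduce it exactly.
    """

    stain_mask: np.ndarray
    true_integrated_density: float
    nuclei_centroids: np.ndarray
    nuclei_radii: np.ndarray
    n_nuclei: int
    stain_intensities: np.ndarray
    clean_bf: np.ndarray = field(repr=False, default=None)


class PackingError(RuntimeError):
    """Rejection sampling could not place all cells without overlap."""


def _place_cells(
    rng: np.random.Generator, spec: SyntheticSpec, max_attempts: int = 10_000
):
    """Sample non-overlapping ellipse cells: centres, axes, orientations."""
    h, w = spec.image_size
    r_lo, r_hi = spec.cell_radius_px
    centres: list[tuple[float, float]] = []
    axes: list[tuple[float, float]] = []
    thetas: list[float] = []
    max_axes: list[float] = []
    attempts = 0
    while len(centres) < spec.n_cells:
        if attempts >= max_attempts:
            density = spec.n_cells * math.pi * r_hi**2 / (h * w)
            raise PackingError(
                f"could not place {spec.n_cells} cells in {max_attempts} "
                f"attempts (nominal area fraction {density:.2f}); reduce "
                "n_cells or cell radius"
            )
        attempts += 1
        a = rng.uniform(r_lo, r_hi)
        b = rng.uniform(r_lo, r_hi)
        theta = rng.uniform(0.0, math.pi)
        m = max(a, b)
        cy = rng.uniform(m + 2, h - m - 2)
        cx = rng.uniform(m + 2, w - m - 2)
        # bounding-circle separation with a 4 px margin keeps cells (and
        # hence nuclei) disjoint, preserving exact counts
        ok = all(
            math.hypot(cy - py, cx - px) > m + pm + 4.0
            for (py, px), pm in zip(centres, max_axes)
        )
        if ok:
            centres.append((cy, cx))
            axes.append((a, b))
            thetas.append(theta)
            max_axes.append(m)
    return centres, axes, thetas


def _nucleus_positions(
    rng: np.random.Generator,
    centre: tuple[float, float],
    min_axis: float,
    k: int,
    nuc_radius: float,
) -> list[tuple[float, float]]:
    """Place k nuclear centres inside one cell, mutually non-touching."""
    if k == 1:
        return [centre]
    # nuclei on a ring around the cell centre; ring radius must both fit
    # inside the cell and keep neighbouring disks >2 px apart
    d_needed = (2.0 * nuc_radius + 2.0) / (2.0 * math.sin(math.pi / k))
    d_max = min_axis - nuc_radius - 1.0
    if d_needed > d_max:
        raise ValueError(
            f"cannot fit {k} non-touching nuclei of radius {nuc_radius:.1f} "
            f"in a cell of radius {min_axis:.1f}"
        )
    phase = rng.uniform(0.0, 2.0 * math.pi)
    return [
        (
            centre[0] + d_needed * math.sin(phase + 2.0 * math.pi * i / k),
            centre[1] + d_needed * math.cos(phase + 2.0 * math.pi * i / k),
        )
        for i in range(k)
    ]


def generate_field(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Generate one brightfield/DAPI pair with exact ground truth.

    Returns ``(bf, dapi, truth)``: an ``(H, W, 3)`` uint8 brightfield
    image, an ``(H, W)`` uint8 DAPI image, and the :class:`GroundTruth`.
    Fully reproducible from ``spec.seed``; geometry is sampled before
    stain intensities, so two specs differing only in ``stain_intensity``
    share identical cell geometry at the same seed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    centres, axes, thetas = _place_cells(rng, spec)

    nuc_lo, nuc_hi = spec.nucleus_radius_px
    nuc_radii_cell = rng.uniform(nuc_lo, nuc_hi, size=spec.n_cells)
    nuclei: list[tuple[float, float]] = []
    nuclei_r: list[float] = []
    for i in range(spec.n_cells):
        min_axis = min(axes[i])
        for pos in _nucleus_positions(
            rng, centres[i], min_axis, spec.nuclei_per_cell, nuc_radii_cell[i]
        ):
            nuclei.append(pos)
            nuclei_r.append(nuc_radii_cell[i])

    mean_s, sd_s = spec.stain_intensity
    s_vals = np.clip(
        rng.normal(mean_s, sd_s, size=spec.n_cells) if sd_s > 0
        else np.full(spec.n_cells, mean_s),
        0.0,
        1.0,
    )

    bf = np.empty((h, w, 3), dtype=np.float64)
    bf[:, :] = spec.background_rgb
    stain_mask = np.zeros((h, w), dtype=bool)
    for i in range(spec.n_cells):
        rr, cc = draw_ellipse(
            centres[i][0],
            centres[i][1],
            axes[i][0],
            axes[i][1],
            shape=(h, w),
            rotation=thetas[i],
        )
        colour = [CYTO_BASE - slope * s_vals[i] for slope in STAIN_SLOPE]
        bf[rr, cc] = colour
        stain_mask[rr, cc] = True
    clean_bf = np.clip(np.round(bf), 0, 255).astype(np.uint8)

    inv = 255.0 - clean_bf.astype(np.float64).mean(axis=2)
    true_id = math.fsum(inv[stain_mask])  # matches measure_signal bit-for-bit

    dapi = np.full((h, w), DAPI_BG, dtype=np.float64)
    for (cy, cx), r in zip(nuclei, nuclei_r):
        rr, cc = draw_disk((cy, cx), r, shape=(h, w))
        dapi[rr, cc] = DAPI_FG

    if spec.noise_sd > 0:
        bf_noisy = clean_bf + rng.normal(0.0, spec.noise_sd, size=(h, w, 3))
        dapi_noisy = dapi + rng.normal(0.0, spec.noise_sd, size=(h, w))
    else:
        bf_noisy = clean_bf.astype(np.float64)
        dapi_noisy = dapi
    bf_out = np.clip(np.round(bf_noisy), 0, 255).astype(np.uint8)
    dapi_out = np.clip(np.round(dapi_noisy), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        stain_mask=stain_mask,
        true_integrated_density=true_id,
        nuclei_centroids=np.array(nuclei) if nuclei else np.empty((0, 2)),
        nuclei_radii=np.array(nuclei_r),
        n_nuclei=len(nuclei),
        stain_intensities=s_vals,
        clean_bf=clean_bf,
    )
    return bf_out, dapi_out, truth


def generate_experiment(
    group_specs: Mapping[str, SyntheticSpec],
    fields_per_group: int,
    out_dir: str | Path,
    seed: int,
) -> pd.DataFrame:
    """Write a multi-group synthetic experiment to disk.

    For each group and field index ``k`` writes ``<group>_<k>_BF.tif`` and
    ``<group>_<k>_DAPI.tif`` plus a ``manifest.csv`` of ground-truth values
    (columns: field_id, group, n_nuclei, true_id, mean_s).  Per-field seeds
    are ``seed + global field index``, so the whole experiment reproduces
    byte-identically from the master seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    idx = 0
    for group, spec in group_specs.items():
        for k in range(fields_per_group):
            fspec = replace(spec, seed=seed + idx)
            bf, dapi, truth = generate_field(fspec)
            fid = f"{group}_{k}"
            tifffile.imwrite(out_dir / f"{fid}_BF.tif", bf)
            tifffile.imwrite(out_dir / f"{fid}_DAPI.tif", dapi)
            rows.append(
                {
                    "field_id": fid,
                    "group": group,
                    "n_nuclei": truth.n_nuclei,
                    "true_id": truth.true_integrated_density,
                    "mean_s": float(truth.stain_intensities.mean())
                    if truth.stain_intensities.size
                    else 0.0,
                }
            )
            idx += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False, float_format="%.10g")
    return manifest


def timecourse_preset(seed: int = 0) -> dict[str, SyntheticSpec]:
    """Senescence time-course: control, early (3 d) and late (7 d) induction.

    Mean stain intensities 0.05 / 0.5 / 0.8 model background SA-β-gal in
    untreated cells versus the progressive darkening after senescence
    induction; late-senescent cells also carry the enlarged nuclei typical
    of the phenotype.
    """
    base = SyntheticSpec(seed=seed)
    return {
        "control": replace(base, stain_intensity=(0.05, 0.02)),
        "dox_3d": replace(base, stain_intensity=(0.5, 0.05)),
        "dox_7d": replace(
            base, stain_intensity=(0.8, 0.05), nucleus_radius_px=(6.0, 9.0)
        ),
    }


def two_group_preset(seed: int = 0) -> dict[str, SyntheticSpec]:
    """Control versus senescent: the calibration scenario."""
    tc = timecourse_preset(seed)
    return {"control": tc["control"], "senescent": tc["dox_7d"]}
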