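"""Render synthetic populations to multi-channel 16-bit TIFF scenes.

Each scene holds a subset of generated cells re-placed (rejection
sampling, non-overlapping) into the image field: ellipse fills on the
nuclear channel, Gaussian FISH spots at the true signal coordinates on
one channel per chromosome, uniform per-cell IF intensities, and
Poisson + Gaussian read noise.  A ground-truth sidecar CSV and a
channel-map JSON are written alongside the image.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from spermtopo.imaging import ChannelMap
from spermtopo.synthetic import AUTOSOMES, GeneratorConfig, GroundTruth

__all__ = ["render_images", "PlacementError"]


class PlacementError(RuntimeError):
    """Could not place all nuclei without overlap; lower the density."""


def _place_nuclei(
    rng: np.random.Generator,
    L: np.ndarray,
    field_um: tuple[float, float],
    max_attempts: int,
    margin_um: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping centers and orientations via rejection sampling."""
    centers = np.zeros((len(L), 2))
    thetas = rng.uniform(0, 2 * math.pi, size=len(L))
    w, h = field_um
    for i, li in enumerate(L):
        r_i = li / 2.0 + margin_um
        placed = False
        for _ in range(max_attempts):
            c = rng.uniform([r_i, r_i], [w - r_i, h - r_i])
            ok = True
            for j in range(i):
                if np.linalg.norm(c - centers[j]) < r_i + L[j] / 2.0 + margin_um:
                    ok = False
                    break
            if ok:
                centers[i] = c
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"failed to place nucleus {i} after {max_attempts} attempts; "
                "reduce cell count or enlarge the field"
            )
    return centers, thetas


def render_images(
    ground_truth: GroundTruth,
    cell_ids: list[str],
    out_dir: str | Path,
    *,
    scene_name: str = "scene",
    seed: int | None = None,
) -> tuple[np.ndarray, ChannelMap, pd.DataFrame]:
    """Render one scene containing the given cells.

    Writes ``<scene_name>.tif`` (C×H×W uint16), ``<scene_name>_channels.json``
    and ``<scene_name>_truth.csv`` (placed µm coordinates: nucleus pose,
    basal-end annotation, per-signal positions, IF intensities).  Returns
    the image stack, channel map, and the placed truth table.
    """
    cfg: GeneratorConfig = ground_truth.config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cells = ground_truth.cells.set_index("nucleus_id").loc[cell_ids].reset_index()
    signals = ground_truth.signals[ground_truth.signals["nucleus_id"].isin(cell_ids)]

    ps = cfg.pixel_size_um
    h_px, w_px = cfg.image_shape
    field_um = (w_px * ps, h_px * ps)

    L = cells["L_um"].to_numpy()
    l = cells["l_um"].to_numpy()
    centers, thetas = _place_nuclei(rng, L, field_um, cfg.placement_max_attempts)
    u = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
    v = np.stack([-np.sin(thetas), np.cos(thetas)], axis=1)
    basal = centers - (L[:, None] / 2.0) * u
    apex = centers + (L[:, None] / 2.0) * u

    chromosomes = list(AUTOSOMES) + ["X", "Y"]
    roles = {0: "nuclear"}
    for k, chrom in enumerate(chromosomes):
        roles[1 + k] = f"fish:{chrom}"
    roles[1 + len(chromosomes)] = "if:5mC"
    roles[2 + len(chromosomes)] = "if:5hmC"
    cmap = ChannelMap(roles=roles, pixel_size_um=ps)
    n_ch = len(roles)

    stack = np.zeros((n_ch, h_px, w_px), float)
    yy, xx = np.mgrid[0:h_px, 0:w_px]
    x_um = xx * ps
    y_um = yy * ps

    truth_rows: list[dict] = []
    for i, row in cells.iterrows():
        # ellipse membership in the placed pose
        dx = x_um - centers[i, 0]
        dy = y_um - centers[i, 1]
        along = dx * u[i, 0] + dy * u[i, 1]
        perp = dx * v[i, 0] + dy * v[i, 1]
        inside = (along / (L[i] / 2.0)) ** 2 + (perp / (l[i] / 2.0)) ** 2 <= 1.0
        stack[0][inside] += cfg.nuclear_amplitude
        i5m = row["i_5mC"] * cfg.if_amplitude_scale
        i5h = row["i_5hmC"] * cfg.if_amplitude_scale
        stack[cmap.if_channel("5mC")][inside] += i5m
        stack[cmap.if_channel("5hmC")][inside] += i5h
        truth_rows.append(
            {
                "record": "cell", "nucleus_id": row["nucleus_id"], "case": row["case"],
                "fraction": row["fraction"], "chromosome": "",
                "x_um": centers[i, 0], "y_um": centers[i, 1],
                "basal_x_um": basal[i, 0], "basal_y_um": basal[i, 1],
                "apex_x_um": apex[i, 0], "apex_y_um": apex[i, 1],
                "L_um": L[i], "l_um": l[i],
                "i_5mC": row["i_5mC"], "i_5hmC": row["i_5hmC"],
            }
        )

    sigma_px = cfg.spot_sigma_um / ps
    fish_idx = cmap.fish_channels()
    id_to_row = {row["nucleus_id"]: i for i, row in cells.iterrows()}
    for _, srow in signals.iterrows():
        i = id_to_row[srow["nucleus_id"]]
        pos = (
            basal[i]
            + srow["true_t"] * L[i] * u[i]
            + srow["true_h"] * L[i] * v[i]
        )
        cx_px, cy_px = pos[0] / ps, pos[1] / ps
        r0 = max(int(cy_px - 5 * sigma_px), 0)
        r1 = min(int(cy_px + 5 * sigma_px) + 1, h_px)
        c0 = max(int(cx_px - 5 * sigma_px), 0)
        c1 = min(int(cx_px + 5 * sigma_px) + 1, w_px)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        g = cfg.spot_amplitude * np.exp(
            -((cc - cx_px) ** 2 + (rr - cy_px) ** 2) / (2.0 * sigma_px**2)
        )
        stack[fish_idx[srow["chromosome"]]][r0:r1, c0:c1] += g
        truth_rows.append(
            {
                "record": "signal", "nucleus_id": srow["nucleus_id"],
                "case": srow["case"], "fraction": srow["fraction"],
                "chromosome": srow["chromosome"],
                "x_um": pos[0], "y_um": pos[1],
                "basal_x_um": basal[i, 0], "basal_y_um": basal[i, 1],
                "apex_x_um": apex[i, 0], "apex_y_um": apex[i, 1],
                "L_um": L[i], "l_um": l[i],
                "i_5mC": np.nan, "i_5hmC": np.nan,
            }
        )

    noisy = rng.poisson(np.clip(stack + cfg.background, 0, None)).astype(float)
    noisy += rng.normal(0.0, cfg.read_noise_sd, size=noisy.shape)
    image = np.clip(noisy, 0, 65535).astype(np.uint16)

    truth = pd.DataFrame(truth_rows)
    tifffile.imwrite(out / f"{scene_name}.tif", image)
    (out / f"{scene_name}_channels.json").write_text(cmap.to_json())
    truth.to_csv(out / f"{scene_name}_truth.csv", index=False)
    return image, cmap, truth
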