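"""End-to-end measurement pipeline, coordinate-mode and image-mode.

Coordinate mode ingests the coordinate-table CSV schema directly;
image mode runs segmentation + spot detection + IF measurement on a
rendered scene and emits the same per-signal measurement table, so both
modes feed the identical downstream aggregation.
"""

from __future__ import annotations

import json
import hashlib
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from spermtopo import presets
from spermtopo.epimarks import classify_epimarks
from spermtopo.geometry import (
    AXIAL_CLAMP_EPS,
    FishSignal,
    NucleusGeometry,
    radial_position,
    shape_qc,
    zone_of_fraction,
)
from spermtopo.imaging import (
    ChannelMap,
    SegmentationParams,
    SpotParams,
    assign_basal_end,
    detect_spots,
    measure_if_intensity,
    segment_nuclei,
)
from spermtopo.topology import (
    call_repositioning,
    chromocenter_cluster,
    distance_summary,
    summaries_to_frame,
    summarize_topology,
)

logger = logging.getLogger("spermtopo")

#: Chromosome pairs whose inter-centromere distances are summarized.
DISTANCE_PAIRS = (("4", "8"), ("7", "9"), ("18", "X"), ("18", "Y"))


@dataclass
class MeasureResult:
    """Per-signal measurements plus filter counters."""

    signals: pd.DataFrame
    n_input: int
    n_kept: int
    n_qc_fail: int
    n_out_of_bounds: int


def measure_coordinates(
    coords: pd.DataFrame,
    d_mode: str = "euclidean",
    shape_band: tuple[float, float] = (1.2, 2.2),
    clamp_eps: float = AXIAL_CLAMP_EPS,
) -> MeasureResult:
    """Compute axial fraction, zone, and (D/L, H/L) for a coordinate table.

    Applies shape QC on L/l and the axial-clamp rule: fractions within
    ``clamp_eps`` outside [0, 1] are clamped, beyond it the signal is
    excluded as a spot-assignment error.
    """
    required = set(
        ["nucleus_id", "case", "fraction", "chromosome", "x_um", "y_um",
         "basal_x_um", "basal_y_um", "apex_x_um", "apex_y_um", "L_um", "l_um"]
    )
    missing = required - set(coords.columns)
    if missing:
        raise ValueError(f"coordinate table missing columns: {sorted(missing)}")

    rows = []
    n_qc_fail = 0
    n_oob = 0
    for _, row in coords.iterrows():
        nucleus = NucleusGeometry(
            basal_point=(row["basal_x_um"], row["basal_y_um"]),
            apex_point=(row["apex_x_um"], row["apex_y_um"]),
            l=row["l_um"],
            nucleus_id=str(row["nucleus_id"]),
        )
        if not shape_qc(nucleus, shape_band):
            n_qc_fail += 1
            continue
        signal = FishSignal(
            chromosome=str(row["chromosome"]),
            centroid=(row["x_um"], row["y_um"]),
            nucleus_id=str(row["nucleus_id"]),
        )
        rp = radial_position(signal, nucleus, d_mode=d_mode)
        t = rp.axial_fraction
        if t < -clamp_eps or t > 1.0 + clamp_eps:
            n_oob += 1
            continue
        t_clamped = min(max(t, 0.0), 1.0)
        out = {
            "nucleus_id": row["nucleus_id"], "case": row["case"],
            "fraction": row["fraction"], "chromosome": row["chromosome"],
            "axial_fraction": t_clamped,
            "zone": zone_of_fraction(t_clamped),
            "d_over_l": rp.d_over_l, "h_over_l": rp.h_over_l,
        }
        if "bearing" in coords.columns:
            out["bearing"] = row["bearing"]
        rows.append(out)

    signals = pd.DataFrame(rows)
    n_input = len(coords)
    res = MeasureResult(
        signals=signals, n_input=n_input, n_kept=len(signals),
        n_qc_fail=n_qc_fail, n_out_of_bounds=n_oob,
    )
    logger.info(
        "measure_coordinates: %d in, %d kept, %d QC-fail, %d out-of-bounds",
        res.n_input, res.n_kept, res.n_qc_fail, res.n_out_of_bounds,
    )
    assert res.n_kept + res.n_qc_fail + res.n_out_of_bounds == res.n_input
    return res


def measure_scene(
    image: np.ndarray,
    channel_map: ChannelMap,
    truth_sidecar: pd.DataFrame,
    d_mode: str = "euclidean",
    seg_params: SegmentationParams = SegmentationParams(),
    spot_params: SpotParams = SpotParams(),
    shape_band: tuple[float, float] = (1.2, 2.2),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure one rendered scene; returns (signal table, cell table).

    Segmented nuclei are matched to the sidecar's cell records by nearest
    center (within half a nucleus length) to obtain the basal-end
    annotation and the case/fraction labels; unmatched nuclei are dropped.
    The signal table has the same measurement columns as coordinate mode;
    the cell table carries background-subtracted IF intensities.
    """
    cells_truth = truth_sidecar[truth_sidecar["record"] == "cell"].reset_index(drop=True)
    nuclei = segment_nuclei(image, channel_map, seg_params)

    matches: list[tuple[int, pd.Series]] = []  # (nucleus index, truth row)
    truth_centers = cells_truth[["x_um", "y_um"]].to_numpy()
    for ni, nuc in enumerate(nuclei):
        d = np.linalg.norm(truth_centers - np.asarray(nuc.center_um), axis=1)
        j = int(np.argmin(d))
        if d[j] <= cells_truth.loc[j, "L_um"] / 2.0:
            matches.append((ni, cells_truth.loc[j]))

    signal_rows: list[dict] = []
    cell_rows: list[dict] = []
    geoms: dict[int, tuple[NucleusGeometry, pd.Series]] = {}
    for ni, truth_row in matches:
        nuc = nuclei[ni]
        geom = assign_basal_end(nuc, (truth_row["basal_x_um"], truth_row["basal_y_um"]))
        if not shape_qc(geom, shape_band):
            continue
        geoms[nuclei[ni].label] = (geom, truth_row)
        i5m = measure_if_intensity(image, channel_map.if_channel("5mC"), nuc, nuclei)
        i5h = measure_if_intensity(image, channel_map.if_channel("5hmC"), nuc, nuclei)
        cell_rows.append(
            {
                "nucleus_id": truth_row["nucleus_id"], "case": truth_row["case"],
                "fraction": truth_row["fraction"], "i_5mC": i5m, "i_5hmC": i5h,
            }
        )

    for chrom, ch_idx in channel_map.fish_channels().items():
        spots = detect_spots(image, ch_idx, channel_map, nuclei, spot_params, chromosome=chrom)
        for spot in spots:
            entry = geoms.get(int(spot.nucleus_id))
            if entry is None:
                continue
            geom, truth_row = entry
            rp = radial_position(spot, geom, d_mode=d_mode)
            t = rp.axial_fraction
            if t < -AXIAL_CLAMP_EPS or t > 1.0 + AXIAL_CLAMP_EPS:
                continue
            t = min(max(t, 0.0), 1.0)
            signal_rows.append(
                {
                    "nucleus_id": truth_row["nucleus_id"], "case": truth_row["case"],
                    "fraction": truth_row["fraction"], "chromosome": chrom,
                    "axial_fraction": t, "zone": zone_of_fraction(t),
                    "d_over_l": rp.d_over_l, "h_over_l": rp.h_over_l,
                }
            )
    return pd.DataFrame(signal_rows), pd.DataFrame(cell_rows)


def attach_epistate(
    signals: pd.DataFrame,
    cells: pd.DataFrame,
    method: str = "fixed_k_sd",
    **classify_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify cells and join the stratum onto the signal table.

    Returns (signals with ``epistate`` column, cells with flags/stratum).
    Every signal either receives a stratum or the cell-level exclusion
    reason "unclassified" (no matching cell record).
    """
    profiles = classify_epimarks(
        list(zip(cells["i_5mC"], cells["i_5hmC"])), method=method, **classify_kwargs
    )
    cells = cells.copy()
    cells["pos_5mC"] = [p.pos_5mC for p in profiles]
    cells["pos_5hmC"] = [p.pos_5hmC for p in profiles]
    cells["stratum"] = [p.stratum for p in profiles]
    strata = cells.set_index("nucleus_id")["stratum"]
    signals = signals.copy()
    signals["epistate"] = signals["nucleus_id"].map(strata).fillna("unclassified")
    return signals, cells


def distances_from_coordinates(coords: pd.DataFrame) -> pd.DataFrame:
    """Per-nucleus distances (µm) between the canonical chromosome pairs."""
    rows = []
    cols = ["x_um", "y_um"]
    for nucleus_id, grp in coords.groupby("nucleus_id", sort=False):
        by_chrom = {c: g[cols].to_numpy() for c, g in grp.groupby("chromosome")}
        meta = grp.iloc[0]
        for a, b in DISTANCE_PAIRS:
            if a in by_chrom and b in by_chrom and len(by_chrom[a]) == 1 and len(by_chrom[b]) == 1:
                d = float(np.linalg.norm(by_chrom[a][0] - by_chrom[b][0]))
                rows.append(
                    {
                        "nucleus_id": nucleus_id, "case": meta["case"],
                        "fraction": meta["fraction"], "pair": f"{a}-{b}",
                        "distance_um": d,
                    }
                )
    return pd.DataFrame(rows)


def aggregate(
    signals: pd.DataFrame,
    out_dir: str | Path | None = None,
    chromocenter_k: dict[str, int] | None = None,
    alpha: float = 0.05,
) -> dict[str, object]:
    """Full aggregation: summary tables, repositioning calls, chromocenters.

    ``signals`` is the measured (optionally epistate-annotated) table.
    Returns a dict of DataFrames / objects; with ``out_dir``, writes the
    CSV and Newick outputs.
    """
    fractions = sorted(signals["fraction"].unique(),
                       key=lambda f: (list(presets.FRACTIONS) + [f]).index(f))
    results: dict[str, object] = {}

    sig = signals.copy()
    if "epistate" not in sig.columns:
        sig["epistate"] = "all"
    groups = [sig.assign(epistate="all")]
    for stratum in ("hyper", "hypo"):
        sub = sig[sig["epistate"] == stratum]
        if len(sub):
            groups.append(sub)
    stacked = pd.concat(groups, ignore_index=True)

    key_names = ["chromosome", "fraction", "epistate"]
    summaries = summarize_topology(stacked, key_names)
    zone_table = summaries_to_frame(summaries, key_names)
    results["topology"] = zone_table

    # chromosome 18 in sex-bearing context
    if "bearing" in sig.columns:
        c18 = sig[sig["chromosome"] == "18"].copy()
        if len(c18):
            c18["chromosome"] = "18-" + c18["bearing"].astype(str)
            s18 = summarize_topology(c18.assign(epistate="all"), key_names, min_signals=0)
            results["topology_18_bearing"] = summaries_to_frame(s18, key_names)

    # repositioning calls per chromosome, all fraction pairs
    calls = []
    for chrom, cgrp in sig.groupby("chromosome"):
        per_frac = {f: g for f, g in cgrp.groupby("fraction")}
        if len(per_frac) < 2:
            continue
        for i, fa in enumerate(fractions):
            for fb in fractions[i + 1:]:
                if fa in per_frac and fb in per_frac:
                    call = call_repositioning(per_frac, (fa, fb), chromosome=chrom)
                    calls.append(
                        {
                            "chromosome": chrom, "fraction_a": fa, "fraction_b": fb,
                            "direction": call.direction, "p_d": call.p_d, "p_h": call.p_h,
                        }
                    )
    results["repositioning"] = pd.DataFrame(calls)

    # chromocenters per fraction from per-chromosome mean radial points
    k_map = chromocenter_k or {f: presets.CHROMOCENTER_PARTITION[f][0]
                               for f in fractions if f in presets.CHROMOCENTER_PARTITION}
    chromo = {}
    for fraction in fractions:
        sub = sig[sig["fraction"] == fraction]
        means = {
            c: (g["d_over_l"].mean(), g["h_over_l"].mean())
            for c, g in sub.groupby("chromosome")
        }
        k = k_map.get(fraction, min(3, len(means)))
        if len(means) >= max(k, 2):
            chromo[fraction] = chromocenter_cluster(means, k)
    results["chromocenters"] = chromo

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        zone_table.to_csv(out / "topology_summary.csv", index=False)
        if "topology_18_bearing" in results:
            results["topology_18_bearing"].to_csv(out / "topology_18_bearing.csv", index=False)
        results["repositioning"].to_csv(out / "repositioning.csv", index=False)
        for fraction, part in chromo.items():
            (out / f"chromocenters_{fraction}.nwk").write_text(part.newick)
    return results


def run_all(
    config,  # GeneratorConfig
    out_dir: str | Path,
    d_mode: str = "euclidean",
) -> dict[str, object]:
    """simulate → measure → classify → aggregate, coordinate mode.

    Writes all result CSVs plus a run manifest; returns the result dict.
    """
    from spermtopo.synthetic import generate_population, per_fraction_thresholds

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    gt = generate_population(config, out_dir=out / "simulated")
    coords = gt.coordinate_table()
    coords["bearing"] = gt.signals["bearing"]
    measured = measure_coordinates(coords, d_mode=d_mode)

    # classify per fraction with generator-matched thresholds
    cells = gt.cells.rename(columns={})
    parts = []
    for fraction, sub in cells.groupby("fraction"):
        thr_m, thr_h = per_fraction_thresholds(config, fraction)
        sub_signals = measured.signals[measured.signals["fraction"] == fraction]
        s, c = attach_epistate(
            sub_signals, sub, method="fixed_k_sd",
            background_mean=(thr_m, thr_h), background_sd=0.0, k=0.0,
        )
        parts.append((s, c))
    signals = pd.concat([p[0] for p in parts], ignore_index=True)
    cells_out = pd.concat([p[1] for p in parts], ignore_index=True)

    results = aggregate(signals, out_dir=out)
    dists = distances_from_coordinates(coords)
    dist_table = distance_summary(dists)
    dist_table.to_csv(out / "distances.csv", index=False)
    results["distances"] = dist_table
    signals.to_csv(out / "signals.csv", index=False)
    cells_out.to_csv(out / "cells_classified.csv", index=False)

    manifest = {
        "seed": config.seed,
        "d_mode": d_mode,
        "config_sha256": hashlib.sha256(config.to_yaml().encode()).hexdigest(),
        "outputs": sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()),
        "elapsed_s": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
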