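"""Seeded generator of synthetic sperm populations.

Produces coordinate tables (and, via :func:`render_images`, multi-channel
16-bit TIFF scenes) with the statistical structure the analysis pipeline
assumes: per-chromosome/fraction radial position distributions, linear
zone frequencies, correlated 5mC/5hmC intensities with configured
positive proportions, and chromatin-class labels.  The default presets
equal the published per-fraction means (:mod:`spermtopo.presets`), so the
full pipeline run on generator output is a parameter-recovery experiment.

Sampling model, per cell:

* nucleus: ``L ~ Normal(L_mean, L_sd)``, ``l = L / shape_ratio``; random
  in-plane orientation; deterministic grid placement (coordinate mode).
* each signal: axial fraction ``t`` from a truncated normal on
  [0.02, 0.98]; unsigned perpendicular fraction ``|h|`` from a truncated
  normal on [0, 0.95·w(t)/L] where ``w(t)`` is the ellipse half-width,
  with the location parameter solved per signal so the *realized* mean
  matches the preset despite truncation; sign of ``h`` uniform.
* epimarks: bivariate lognormal intensities whose latent correlation is
  chosen so the Pearson correlation of the intensities hits the
  configured target; positivity thresholds are the latent quantiles of
  the configured positive proportions (and are reported, so generator and
  classifier can share them).
* chromatin classes: multinomial draws from the per-fraction proportions.

Each cell bears an X or a Y chromosome (equal odds); chromosome 18 uses
sex-bearing-specific positional presets, so unselected-18 summaries are
mixtures, as in the source data.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy import stats as sps

from spermtopo import presets

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "preset_from_tables",
    "generate_population",
    "predicted_pair_distance",
    "calibrate_pair_distance",
    "COORD_COLUMNS",
]

#: Schema of the coordinate-table CSV (ingest + emit).
COORD_COLUMNS = [
    "nucleus_id", "case", "fraction", "chromosome",
    "x_um", "y_um", "basal_x_um", "basal_y_um", "apex_x_um", "apex_y_um",
    "L_um", "l_um",
]

#: Axial-fraction truncation limits and ellipse-margin factor keeping
#: generated signals strictly interior.
T_MIN, T_MAX, ELLIPSE_MARGIN = 0.02, 0.98, 0.95

AUTOSOMES = ("4", "7", "8", "9", "18")


@dataclass
class PositionPreset:
    """Truncated-normal parameters for one chromosome in one fraction."""

    mean_t: float
    sd_t: float
    mean_h: float
    sd_h: float


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_cases: int = 5
    cells_per_case: int = 100
    fractions: tuple[str, ...] = presets.FRACTIONS
    #: positional presets keyed (chromosome, fraction); chromosome 18 uses
    #: "18-X"/"18-Y" keys by sex bearing.
    positions: dict[tuple[str, str], PositionPreset] = field(default_factory=dict)
    #: alternative parameterization: (a, m, b) zone probabilities keyed the
    #: same way; when set (mode "zones"), t is drawn zone-first.
    zones: dict[tuple[str, str], tuple[float, float, float]] = field(default_factory=dict)
    position_mode: str = "radial"  # "radial" | "zones"
    #: 5mC/5hmC positive proportions keyed (mark, fraction), in [0, 1].
    epimark_positive: dict[tuple[str, str], float] = field(default_factory=dict)
    epimark_log_mean: float = math.log(1000.0)
    epimark_log_sd: float = 0.5
    epimark_rho: float = 0.7  # target Pearson correlation of intensities
    #: chromatin-class probabilities per fraction.
    ab_probs: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    ao_positive: dict[str, float] = field(default_factory=dict)
    tunel_positive: dict[str, float] = field(default_factory=dict)
    #: nucleus shape
    L_mean_um: float = 6.0
    L_sd_um: float = 0.3
    shape_ratio: float = 1.7  # L/l, so max |h|/L = 1/(2*1.7) ~ 0.294
    #: coordinate-mode placement grid pitch (µm)
    grid_pitch_um: float = 12.0
    #: rendering
    pixel_size_um: float = 0.1
    image_shape: tuple[int, int] = (512, 512)
    spot_sigma_um: float = 0.15
    nuclear_amplitude: float = 4000.0
    spot_amplitude: float = 8000.0
    if_amplitude_scale: float = 1.0  # multiplies lognormal intensities into counts
    background: float = 100.0
    read_noise_sd: float = 5.0
    placement_max_attempts: int = 2000

    def to_yaml(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return yaml.safe_dump(enc(dataclasses.asdict(self)), sort_keys=True)

    def validate(self) -> None:
        l_half_frac = 1.0 / (2.0 * self.shape_ratio)
        for key, p in self.positions.items():
            if not (0 < p.mean_t < 1):
                raise ValueError(f"{key}: mean axial fraction must be in (0, 1)")
            if p.mean_h < 0 or p.mean_h >= l_half_frac:
                raise ValueError(
                    f"{key}: mean |h| {p.mean_h} infeasible (ellipse bound {l_half_frac:.4f})"
                )
        for key, p in self.epimark_positive.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"{key}: positive proportion must be in (0, 1)")
        for fr, probs in self.ab_probs.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{fr}: AB class probabilities must sum to 1")


@dataclass
class GroundTruth:
    """Generator output: per-signal and per-cell truth tables.

    ``signals`` has one row per FISH signal with true axial/perpendicular
    fractions and µm coordinates; ``cells`` has one row per sperm with
    epimark intensities, true positivity flags, stratum, and chromatin
    classes.  ``epimark_thresholds`` holds the intensity thresholds that
    realize the configured positive proportions.
    """

    signals: pd.DataFrame
    cells: pd.DataFrame
    epimark_thresholds: dict[str, float]
    config: GeneratorConfig

    def coordinate_table(self) -> pd.DataFrame:
        return self.signals[COORD_COLUMNS].copy()


def preset_from_tables(**overrides) -> GeneratorConfig:
    """Default configuration parameterized by the published table means.

    Positional presets take each chromosome × fraction (D/L, H/L) mean as
    the (axial, perpendicular) truncated-normal means, with default
    per-signal SDs (0.12 axial, 0.05 perpendicular — chosen so simulated
    SEs at n = 100 approximate the printed SEs).  Zone presets, epimark
    positive proportions and chromatin-class proportions come from the
    corresponding published tables.
    """
    sd_t, sd_h = 0.12, 0.05
    positions = {}
    zones = {}
    for chrom, per_frac in presets.RADIAL_MEAN.items():
        if chrom == "18":
            continue  # unselected 18 is the X/Y-bearing mixture
        for frac, (d, h) in per_frac.items():
            positions[(chrom, frac)] = PositionPreset(d, sd_t, h, sd_h)
    for chrom, per_frac in presets.ZONE_FREQ.items():
        if chrom == "18":
            continue
        for frac, amb in per_frac.items():
            total = sum(amb)
            zones[(chrom, frac)] = tuple(v / total for v in amb)
    epi = {
        (mark, frac): presets.EPIMARK_POSITIVE[frac][mark] / 100.0
        for frac in presets.FRACTIONS
        for mark in ("5mC", "5hmC")
    }
    ab, ao, tunel = {}, {}, {}
    for frac, row in presets.CHROMATIN_CLASSES.items():
        total = row["pink"] + row["purple"] + row["navy"]
        ab[frac] = (row["pink"] / total, row["purple"] / total, row["navy"] / total)
        ao[frac] = row["ao_positive"] / 100.0
        tunel[frac] = row["tunel_positive"] / 100.0
    cfg = GeneratorConfig(
        positions=positions, zones=zones, epimark_positive=epi,
        ab_probs=ab, ao_positive=ao, tunel_positive=tunel, **overrides,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# sampling helpers


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size=None) -> np.ndarray:
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _truncnorm_mean(loc: np.ndarray, sd: float, lo: float, hi: np.ndarray) -> np.ndarray:
    """Mean of Normal(loc, sd) truncated to [lo, hi] (vectorized)."""
    a = (lo - loc) / sd
    b = (hi - loc) / sd
    num = sps.norm.pdf(a) - sps.norm.pdf(b)
    den = sps.norm.cdf(b) - sps.norm.cdf(a)
    den = np.maximum(den, 1e-300)
    return loc + sd * num / den

def _compensated_loc(target: np.ndarray, sd: float, lo: float, hi: np.ndarray,
                     iters: int = 60) -> np.ndarray:
    """Location parameters whose [lo, hi]-truncated means equal ``target``.

    Fixed-point iteration loc ← loc + (target − truncated_mean); converges
    because d(mean)/d(loc) ∈ (0, 1].  Where the target is infeasible
    (target ≥ hi) the location saturates; the residual bias is confined to
    the rare signals near the ellipse poles.
    """
    loc = np.array(target, float, copy=True)
    cap = target + 8.0 * sd
    for _ in range(iters):
        loc = np.clip(loc + (target - _truncnorm_mean(loc, sd, lo, hi)), None, cap)
    return loc


def _draw_h_fractions(
    rng: np.random.Generator, t: np.ndarray, mean_h: float, sd_h: float,
    l_over_l: float,
) -> np.ndarray:
    """Signed perpendicular fractions h (H/L units) for axial fractions t.

    |h| is truncated-normal on [0, 0.95·w(t)/L] with mean-compensated
    location; w(t)/L = (l/2L)·sqrt(1 − (2t−1)²).
    """
    bound = ELLIPSE_MARGIN * (l_over_l / 2.0) * np.sqrt(
        np.clip(1.0 - (2.0 * t - 1.0) ** 2, 0.0, None)
    )
    loc = _compensated_loc(np.full_like(t, mean_h), sd_h, 0.0, bound)
    a = (0.0 - loc) / sd_h
    b = np.maximum((bound - loc) / sd_h, a + 1e-9)
    mag = sps.truncnorm.rvs(a, b, loc=loc, scale=sd_h, random_state=rng)
    sign = rng.choice([-1.0, 1.0], size=t.shape)
    return sign * mag


def _draw_axial(
    rng: np.random.Generator, cfg: GeneratorConfig, key: tuple[str, str], n: int
) -> np.ndarray:
    if cfg.position_mode == "zones":
        zone_p = cfg.zones[key]
        # zone-first: pick the third, then uniform within it (clipped to the
        # interior truncation limits at the ends)
        edges = [(2.0 / 3.0, T_MAX), (1.0 / 3.0, 2.0 / 3.0), (T_MIN, 1.0 / 3.0)]  # a, m, b
        which = rng.choice(3, size=n, p=zone_p)
        lo = np.array([edges[w][0] for w in which])
        hi = np.array([edges[w][1] for w in which])
        return rng.uniform(lo, hi)
    p = cfg.positions[key]
    return _truncnorm(rng, p.mean_t, p.sd_t, T_MIN, T_MAX, size=n)


def _latent_rho(target: float, sigma1: float, sigma2: float) -> float:
    """Latent normal correlation producing a target lognormal Pearson rho."""
    s11 = math.expm1(sigma1 * sigma1)
    s22 = math.expm1(sigma2 * sigma2)
    inner = 1.0 + target * math.sqrt(s11 * s22)
    if inner <= 0:
        raise ValueError(f"target correlation {target} infeasible for these sigmas")
    rho = math.log(inner) / (sigma1 * sigma2)
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"target correlation {target} infeasible (latent rho {rho:.3f})")
    return rho


# ---------------------------------------------------------------------------
# main entry points


def generate_population(
    config: GeneratorConfig, out_dir: str | Path | None = None
) -> GroundTruth:
    """Draw a full synthetic population; optionally write the CSV outputs.

    Returns the ground truth (per-signal and per-cell tables).  With
    ``out_dir``, writes ``coordinates.csv`` (the coordinate-table schema),
    ``cells.csv``, and ``config.yaml`` (provenance echo).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sigma = config.epimark_log_sd
    rho_latent = _latent_rho(config.epimark_rho, sigma, sigma)
    chol = np.linalg.cholesky(np.array([[1.0, rho_latent], [rho_latent, 1.0]]))

    signal_frames: list[pd.DataFrame] = []
    cell_frames: list[pd.DataFrame] = []
    grid_cols = int(math.ceil(math.sqrt(config.n_cases * config.cells_per_case
                                        * len(config.fractions))))
    cell_index = 0

    for case_i in range(config.n_cases):
        case = f"K{case_i + 1}"
        for fraction in config.fractions:
            n = config.cells_per_case
            L = rng.normal(config.L_mean_um, config.L_sd_um, size=n)
            L = np.clip(L, 1e-3, None)
            l = L / config.shape_ratio
            theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
            bearing = rng.choice(["X", "Y"], size=n)

            # epimarks: latent bivariate normal -> lognormal intensities
            z = rng.standard_normal((n, 2)) @ chol.T
            i_m = np.exp(config.epimark_log_mean + sigma * z[:, 0])
            i_h = np.exp(config.epimark_log_mean + sigma * z[:, 1])
            zc_m = sps.norm.ppf(1.0 - config.epimark_positive[("5mC", fraction)])
            zc_h = sps.norm.ppf(1.0 - config.epimark_positive[("5hmC", fraction)])
            pos_m = z[:, 0] > zc_m
            pos_h = z[:, 1] > zc_h
            stratum = np.where(pos_m & pos_h, "hyper",
                               np.where(~pos_m & ~pos_h, "hypo", "mixed"))

            ab = rng.choice(["pink", "purple", "navy"], size=n, p=config.ab_probs[fraction])
            ao = np.where(rng.random(n) < config.ao_positive[fraction], "red_yellow", "green")
            tun = np.where(rng.random(n) < config.tunel_positive[fraction], "positive", "negative")

            # per-chromosome signal draws, vectorized over cells
            per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            l_over_l = 1.0 / config.shape_ratio
            for chrom in AUTOSOMES + ("X", "Y"):
                if chrom == "18":
                    t = np.empty(n)
                    h = np.empty(n)
                    for b_label in ("X", "Y"):
                        idx = np.flatnonzero(bearing == b_label)
                        if idx.size == 0:
                            continue
                        key = (f"18-{b_label}", fraction)
                        t_sub = _draw_axial(rng, config, key, idx.size)
                        mean_h, sd_h = _h_params(config, key)
                        t[idx] = t_sub
                        h[idx] = _draw_h_fractions(rng, t_sub, mean_h, sd_h, l_over_l)
                    per_chrom[chrom] = (t, h)
                else:
                    key = (chrom, fraction)
                    t = _draw_axial(rng, config, key, n)
                    mean_h, sd_h = _h_params(config, key)
                    per_chrom[chrom] = (t, _draw_h_fractions(rng, t, mean_h, sd_h, l_over_l))

            u = np.stack([np.cos(theta), np.sin(theta)], axis=1)
            v = np.stack([-np.sin(theta), np.cos(theta)], axis=1)
            cx = (np.arange(cell_index, cell_index + n) % grid_cols) * config.grid_pitch_um
            cy = (np.arange(cell_index, cell_index + n) // grid_cols) * config.grid_pitch_um
            center = np.stack([cx, cy], axis=1).astype(float)
            basal = center - (L[:, None] / 2.0) * u
            apex = center + (L[:, None] / 2.0) * u
            nucleus_id = np.array([f"{case}-{fraction}-{i:05d}" for i in range(n)])

            cell_frames.append(pd.DataFrame({
                "nucleus_id": nucleus_id, "case": case, "fraction": fraction,
                "bearing": bearing, "i_5mC": i_m, "i_5hmC": i_h,
                "true_pos_5mC": pos_m, "true_pos_5hmC": pos_h, "true_stratum": stratum,
                "ab_class": ab, "ao_class": ao, "tunel_class": tun,
                "L_um": L, "l_um": l,
                "basal_x_um": basal[:, 0], "basal_y_um": basal[:, 1],
                "apex_x_um": apex[:, 0], "apex_y_um": apex[:, 1],
            }))

            for chrom, (t, h) in per_chrom.items():
                if chrom in ("X", "Y"):
                    keep = np.flatnonzero(bearing == chrom)
                else:
                    keep = np.arange(n)
                tk, hk = t[keep], h[keep]
                pos = (basal[keep]
                       + (tk * L[keep])[:, None] * u[keep]
                       + (hk * L[keep])[:, None] * v[keep])
                signal_frames.append(pd.DataFrame({
                    "nucleus_id": nucleus_id[keep], "case": case, "fraction": fraction,
                    "chromosome": chrom, "bearing": bearing[keep],
                    "true_t": tk, "true_h": hk,
                    "x_um": pos[:, 0], "y_um": pos[:, 1],
                    "basal_x_um": basal[keep, 0], "basal_y_um": basal[keep, 1],
                    "apex_x_um": apex[keep, 0], "apex_y_um": apex[keep, 1],
                    "L_um": L[keep], "l_um": l[keep],
                }))
            cell_index += n

    signals = (
        pd.concat(signal_frames, ignore_index=True)
        .sort_values(["nucleus_id", "chromosome"], kind="stable")
        .reset_index(drop=True)
    )
    cells = pd.concat(cell_frames, ignore_index=True)
    thresholds = {
        mark: float(np.exp(config.epimark_log_mean + sigma
                           * sps.norm.ppf(1.0 - _pooled_positive(config, mark))))
        for mark in ("5mC", "5hmC")
    }
    gt = GroundTruth(signals=signals, cells=cells, epimark_thresholds=thresholds,
                     config=config)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        gt.coordinate_table().to_csv(out / "coordinates.csv", index=False)
        cells.to_csv(out / "cells.csv", index=False)
        (out / "config.yaml").write_text(config.to_yaml())
    return gt


def per_fraction_thresholds(config: GeneratorConfig, fraction: str) -> tuple[float, float]:
    """Intensity thresholds realizing the configured positive proportions."""
    sigma = config.epimark_log_sd
    return tuple(
        float(np.exp(config.epimark_log_mean
                     + sigma * sps.norm.ppf(1.0 - config.epimark_positive[(mark, fraction)])))
        for mark in ("5mC", "5hmC")
    )


def _pooled_positive(config: GeneratorConfig, mark: str) -> float:
    vals = [config.epimark_positive[(mark, f)] for f in config.fractions]
    return float(np.mean(vals))


def _h_params(config: GeneratorConfig, key: tuple[str, str]) -> tuple[float, float]:
    if key in config.positions:
        p = config.positions[key]
        return p.mean_h, p.sd_h
    # zone-mode without a radial preset: mid-depth default
    return 0.15, 0.05


# ---------------------------------------------------------------------------
# distance calibration


def predicted_pair_distance(
    config: GeneratorConfig,
    pair: tuple[str, str],
    fraction: str,
    n_mc: int = 50_000,
    seed: int = 1234,
) -> float:
    """Monte-Carlo mean inter-centromere distance (µm) implied by the presets.

    Signals are placed independently per chromosome, so the pair-distance
    mean is a derived quantity; this estimator samples it directly.
    """
    rng = np.random.default_rng(seed)
    L = np.clip(rng.normal(config.L_mean_um, config.L_sd_um, size=n_mc), 1e-3, None)
    l_over_l = 1.0 / config.shape_ratio
    coords = []
    for chrom in pair:
        key = (chrom, fraction)
        t = _draw_axial(rng, config, key, n_mc)
        mean_h, sd_h = _h_params(config, key)
        h = _draw_h_fractions(rng, t, mean_h, sd_h, l_over_l)
        coords.append((t, h))
    (t1, h1), (t2, h2) = coords
    return float(np.mean(L * np.hypot(t1 - t2, h1 - h2)))


def calibrate_pair_distance(
    config: GeneratorConfig,
    pair: tuple[str, str],
    fraction: str,
    target_um: float,
    n_mc: int = 50_000,
    seed: int = 1234,
) -> GeneratorConfig:
    """Scale the pair's axial SDs so the implied mean distance hits a target.

    Returns a copy of the configuration with ``sd_t`` of both chromosomes
    in ``pair`` (for ``fraction``) multiplied by a common factor found by
    root-finding on the Monte-Carlo predictor.  Raises if the target is
    outside the reachable bracket.
    """
    new_cfg = dataclasses.replace(config, positions=dict(config.positions))

    def with_scale(s: float) -> GeneratorConfig:
        cfg = dataclasses.replace(new_cfg, positions=dict(new_cfg.positions))
        for chrom in pair:
            key = (chrom, fraction)
            p = cfg.positions[key]
            cfg.positions[key] = PositionPreset(p.mean_t, p.sd_t * s, p.mean_h, p.sd_h)
        return cfg

    def objective(s: float) -> float:
        return predicted_pair_distance(with_scale(s), pair, fraction, n_mc, seed) - target_um

    lo, hi = 0.2, 5.0
    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"target {target_um} µm unreachable by scaling axial SDs in [{lo}, {hi}]"
        )
    s_star = optimize.brentq(objective, lo, hi, xtol=1e-3)
    return with_scale(s_star)
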