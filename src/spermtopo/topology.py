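"""Aggregation of per-signal measurements into topology summaries.

Builds the per-chromosome × fraction × epistate summary tables (linear
zone frequencies and radial mean ± SE), calls repositioning between
fractions per axis, clusters per-chromosome mean radial points into
chromocenters (Ward linkage, Newick export), computes chromocenter
convex-hull areas, and summarizes inter-centromere distances with
cross-fraction fold changes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import ConvexHull, QhullError

from spermtopo.geometry import zone_of_fraction
from spermtopo.stats import StatsConfig, kw_dunn, round_half_up

__all__ = [
    "TopologySummary",
    "RepositionCall",
    "ChromocenterPartition",
    "summarize_topology",
    "call_repositioning",
    "chromocenter_cluster",
    "chromocenter_hull_area",
    "distance_summary",
    "linkage_to_newick",
]

#: Minimum signals per summary group before a scoring-depth warning.
MIN_SIGNALS = 100


@dataclass(frozen=True)
class TopologySummary:
    """Per-group aggregate of zone frequencies and radial coordinates."""

    key: tuple
    zone_freq_mean: tuple[float, float, float]  # (a, m, b) % mean over cases
    zone_freq_sd: tuple[float, float, float]
    mean_d_over_l: float
    se_d_over_l: float
    mean_h_over_l: float
    se_h_over_l: float
    n_signals: int
    per_case_zone_freq: pd.DataFrame = field(repr=False, default=None)


def _zone_freqs(axial: np.ndarray) -> np.ndarray:
    """(a, m, b) percentages of a vector of axial fractions."""
    zones = np.array([zone_of_fraction(t) for t in axial])
    n = zones.size
    return np.array([100.0 * np.sum(zones == z) / n for z in ("a", "m", "b")])


def summarize_topology(
    signals: pd.DataFrame,
    group_keys: list[str],
    *,
    case_column: str = "case",
    min_signals: int = MIN_SIGNALS,
) -> list[TopologySummary]:
    """Aggregate a signal table into per-group topology summaries.

    ``signals`` needs columns ``axial_fraction``, ``d_over_l``,
    ``h_over_l``, the grouping keys, and (for per-case zone statistics) a
    case column.  Zone frequencies are computed per case and then averaged
    (mean ± SD across cases); radial coordinates are pooled over all
    signals in the group (mean ± SE with per-signal n).
    """
    required = {"axial_fraction", "d_over_l", "h_over_l"}
    missing = required - set(signals.columns)
    if missing:
        raise ValueError(f"signal table missing columns: {sorted(missing)}")

    out: list[TopologySummary] = []
    for key, grp in signals.groupby(group_keys, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        n = len(grp)
        if n == 0:
            warnings.warn(f"group {key}: empty, skipped", stacklevel=2)
            continue
        if n < min_signals:
            warnings.warn(
                f"group {key}: only {n} signals (< {min_signals})", stacklevel=2
            )

        if case_column in grp.columns and grp[case_column].nunique() > 1:
            per_case = (
                grp.groupby(case_column)["axial_fraction"]
                .apply(lambda s: pd.Series(_zone_freqs(s.to_numpy()), index=["a", "m", "b"]))
                .unstack()
            )
            zf_mean = per_case.mean(axis=0).to_numpy()
            zf_sd = per_case.std(axis=0, ddof=1).to_numpy()
        else:
            per_case = pd.DataFrame(
                [_zone_freqs(grp["axial_fraction"].to_numpy())], columns=["a", "m", "b"]
            )
            zf_mean = per_case.iloc[0].to_numpy()
            zf_sd = np.zeros(3)

        d = grp["d_over_l"].to_numpy()
        h = grp["h_over_l"].to_numpy()
        sd_d = float(np.std(d, ddof=1)) if n > 1 else 0.0
        sd_h = float(np.std(h, ddof=1)) if n > 1 else 0.0
        out.append(
            TopologySummary(
                key=key,
                zone_freq_mean=tuple(zf_mean),
                zone_freq_sd=tuple(zf_sd),
                mean_d_over_l=float(np.mean(d)),
                se_d_over_l=sd_d / math.sqrt(n),
                mean_h_over_l=float(np.mean(h)),
                se_h_over_l=sd_h / math.sqrt(n),
                n_signals=n,
                per_case_zone_freq=per_case,
            )
        )
    return out


def summaries_to_frame(summaries: list[TopologySummary], key_names: list[str]) -> pd.DataFrame:
    """Flatten TopologySummary records into a tidy table."""
    rows = []
    for s in summaries:
        row = dict(zip(key_names, s.key))
        row.update(
            a_pct=s.zone_freq_mean[0], m_pct=s.zone_freq_mean[1], b_pct=s.zone_freq_mean[2],
            a_sd=s.zone_freq_sd[0], m_sd=s.zone_freq_sd[1], b_sd=s.zone_freq_sd[2],
            mean_d_over_l=s.mean_d_over_l, se_d_over_l=s.se_d_over_l,
            mean_h_over_l=s.mean_h_over_l, se_h_over_l=s.se_h_over_l,
            n_signals=s.n_signals,
        )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RepositionCall:
    """Direction of centromere repositioning between two groups."""

    chromosome: str
    pair: tuple[str, str]
    direction: str  # basal-apical | apical-basal | center-periphery | periphery-center | both | none
    p_d: float
    p_h: float


def call_repositioning(
    groups: dict[str, pd.DataFrame],
    pair: tuple[str, str],
    chromosome: str = "",
    config: StatsConfig | None = None,
) -> RepositionCall:
    """Test for a positional shift between two fractions, per axis.

    ``groups`` maps fraction name → signal table with ``d_over_l`` and
    ``h_over_l``.  When three or more groups are supplied, each axis uses
    the Kruskal–Wallis omnibus over all groups followed by Dunn's pairwise
    test, and the adjusted p for ``pair`` is reported; with exactly two
    groups a rank-sum test is used directly.  A significant D-axis shift
    is labelled by the sign of the mean difference (increase → toward the
    apical pole); a significant H-axis shift likewise (increase → toward
    the periphery).
    """
    cfg = config or StatsConfig()
    a_name, b_name = pair
    if a_name not in groups or b_name not in groups:
        raise KeyError(f"pair {pair} not found among groups {sorted(groups)}")
    names = list(groups)
    ia, ib = names.index(a_name), names.index(b_name)
    for name, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 signals")

    p_axis: dict[str, float] = {}
    sig_axis: dict[str, bool] = {}
    delta: dict[str, float] = {}
    for axis in ("d_over_l", "h_over_l"):
        samples = [groups[n][axis].to_numpy() for n in names]
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            warnings.warn(f"{axis}: all values tied; no call", stacklevel=2)
            p_axis[axis] = 1.0
            sig_axis[axis] = False
            delta[axis] = 0.0
            continue
        res = kw_dunn(samples, cfg)
        p = float(res.pairwise_p[ia, ib])
        # pairwise comparison only meaningful if the omnibus rejects
        significant = res.omnibus_p < cfg.alpha and p < cfg.alpha
        p_axis[axis] = p
        sig_axis[axis] = significant
        delta[axis] = float(samples[ib].mean() - samples[ia].mean())

    d_sig, h_sig = sig_axis["d_over_l"], sig_axis["h_over_l"]
    if d_sig and h_sig:
        direction = "both"
    elif d_sig:
        direction = "basal-apical" if delta["d_over_l"] > 0 else "apical-basal"
    elif h_sig:
        direction = "center-periphery" if delta["h_over_l"] > 0 else "periphery-center"
    else:
        direction = "none"
    return RepositionCall(
        chromosome=chromosome,
        pair=pair,
        direction=direction,
        p_d=p_axis["d_over_l"],
        p_h=p_axis["h_over_l"],
    )


@dataclass(frozen=True)
class ChromocenterPartition:
    """Ward linkage over per-chromosome mean radial points."""

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray
    k: int
    clusters: tuple[frozenset[str], ...]
    newick: str

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string.

    Branch lengths are differences of merge heights (leaves hang from
    their parent's height).
    """
    n = len(labels)

    def node(i: int, parent_height: float) -> str:
        if i < n:
            return f"{labels[i]}:{parent_height:.6g}"
        row = z[i - n]
        h = row[2]
        left = node(int(row[0]), h)
        right = node(int(row[1]), h)
        return f"({left},{right}):{parent_height - h:.6g}"

    root_height = z[-1, 2] if len(z) else 0.0
    return node(n + len(z) - 1, root_height).rsplit(":", 1)[0] + ";"


def chromocenter_cluster(
    mean_positions: dict[str, tuple[float, float]], k: int
) -> ChromocenterPartition:
    """Ward clustering of per-chromosome mean (D/L, H/L) points.

    Agglomerative Ward linkage on Euclidean distances, cut to ``k``
    clusters; the tree is also exported as Newick with merge heights as
    branch lengths.
    """
    labels = tuple(mean_positions)
    pts = np.array([mean_positions[c] for c in labels], float)
    if k < 1 or k > len(labels):
        raise ValueError(f"k={k} out of range for {len(labels)} points")
    if len(labels) == 1:
        return ChromocenterPartition(
            labels=labels, linkage_matrix=np.empty((0, 4)), k=1,
            clusters=(frozenset(labels),), newick=f"{labels[0]};",
        )
    z = linkage(pts, method="ward")
    assignment = fcluster(z, k, criterion="maxclust")
    clusters: dict[int, set[str]] = {}
    for lab, cl in zip(labels, assignment):
        clusters.setdefault(int(cl), set()).add(lab)
    return ChromocenterPartition(
        labels=labels,
        linkage_matrix=z,
        k=k,
        clusters=tuple(frozenset(s) for s in clusters.values()),
        newick=linkage_to_newick(z, list(labels)),
    )


def chromocenter_hull_area(
    mean_positions: dict[str, tuple[float, float]], include_mirror: bool = False
) -> float:
    """Convex-hull area of the mean radial points (normalized units²).

    With ``include_mirror`` the point set is unioned with its reflection
    across the longitudinal axis (H → −H) before taking the hull,
    mirroring the two indistinguishable slide poses.
    """
    pts = np.array(list(mean_positions.values()), float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points for a hull area")
    if include_mirror:
        mirrored = pts * np.array([1.0, -1.0])
        pts = np.vstack([pts, mirrored])
    try:
        return float(ConvexHull(pts).volume)  # 2-D "volume" is the area
    except QhullError:
        warnings.warn("points are collinear; hull area 0", stacklevel=2)
        return 0.0


def distance_summary(
    distances: pd.DataFrame,
    *,
    pair_column: str = "pair",
    fraction_column: str = "fraction",
    value_column: str = "distance_um",
    reference: str = "raw",
    min_n: int = 100,
) -> pd.DataFrame:
    """Per-pair per-fraction distance mean ± SE with fold changes.

    Fold change columns report each fraction's mean relative to the
    ``reference`` fraction's mean (half-up, 2 decimals) alongside the
    unrounded ratio.
    """
    rows = []
    for (pair, fraction), grp in distances.groupby([pair_column, fraction_column], sort=True):
        vals = grp[value_column].to_numpy()
        n = vals.size
        if n == 0:
            warnings.warn(f"{pair}/{fraction}: empty, skipped", stacklevel=2)
            continue
        if n < min_n:
            warnings.warn(f"{pair}/{fraction}: only {n} distances (< {min_n})", stacklevel=2)
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        rows.append(
            {pair_column: pair, fraction_column: fraction,
             "mean_um": float(np.mean(vals)), "se_um": sd / math.sqrt(n), "n": n}
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out

    ref_means = (
        out[out[fraction_column] == reference]
        .set_index(pair_column)["mean_um"]
        .to_dict()
    )
    ratios, ratios_2dp = [], []
    for _, row in out.iterrows():
        ref = ref_means.get(row[pair_column])
        if ref is None or ref <= 0:
            ratios.append(float("nan"))
            ratios_2dp.append(float("nan"))
        else:
            r = row["mean_um"] / ref
            ratios.append(r)
            ratios_2dp.append(round_half_up(r, 2))
    out["fold_vs_" + reference] = ratios
    out["fold_vs_" + reference + "_2dp"] = ratios_2dp
    return out
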