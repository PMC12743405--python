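"""Epimark (5mC/5hmC) classification and chromatin-class tabulation.

Each sperm carries two background-subtracted immunofluorescence
intensities.  A per-mark threshold turns them into positive/negative
flags; the pair of flags defines the stratum used for topology
stratification: *hyper* (both positive), *hypo* (both negative), or
*mixed*.  Mixed cells still count toward positive-frequency tables but
are excluded from hyper/hypo topology groups.

Thresholding strategies:

``fixed_k_sd``
    positive iff intensity > background_mean + k · background_SD, with the
    background statistics supplied per mark (k defaults to 2).
``otsu``
    per-mark Otsu threshold computed from the cell-intensity histogram;
    invariant under strictly increasing affine rescaling of intensities.

Chromatin classes (protamination, AO, TUNEL) enter as categorical labels;
this module only counts and summarizes them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

__all__ = [
    "EpimarkProfile",
    "ChromatinClass",
    "classify_epimarks",
    "class_frequencies",
    "AB_CLASSES",
    "AO_CLASSES",
    "TUNEL_CLASSES",
]

AB_CLASSES = ("pink", "purple", "navy")
AO_CLASSES = ("green", "red_yellow")
TUNEL_CLASSES = ("negative", "positive")

Stratum = Literal["hyper", "hypo", "mixed"]


@dataclass(frozen=True)
class EpimarkProfile:
    """Per-cell epimark intensities, positivity flags, and stratum."""

    i_5mC: float
    i_5hmC: float
    pos_5mC: bool
    pos_5hmC: bool

    @property
    def stratum(self) -> Stratum:
        if self.pos_5mC and self.pos_5hmC:
            return "hyper"
        if not self.pos_5mC and not self.pos_5hmC:
            return "hypo"
        return "mixed"


@dataclass(frozen=True)
class ChromatinClass:
    """Categorical chromatin-integrity labels for one sperm."""

    ab_class: str
    ao_class: str
    tunel_class: str

    def __post_init__(self) -> None:
        if self.ab_class not in AB_CLASSES:
            raise ValueError(f"ab_class must be one of {AB_CLASSES}, got {self.ab_class!r}")
        if self.ao_class not in AO_CLASSES:
            raise ValueError(f"ao_class must be one of {AO_CLASSES}, got {self.ao_class!r}")
        if self.tunel_class not in TUNEL_CLASSES:
            raise ValueError(
                f"tunel_class must be one of {TUNEL_CLASSES}, got {self.tunel_class!r}"
            )


def _per_mark(value, name: str) -> tuple[float, float]:
    """Broadcast a scalar or (5mC, 5hmC) pair to a per-mark pair."""
    if np.isscalar(value):
        return float(value), float(value)
    pair = tuple(float(v) for v in value)
    if len(pair) != 2:
        raise ValueError(f"{name} must be scalar or a (5mC, 5hmC) pair")
    return pair


def classify_epimarks(
    intensities: Sequence[tuple[float, float]],
    method: Literal["fixed_k_sd", "otsu"] = "fixed_k_sd",
    *,
    background_mean: float | tuple[float, float] = 0.0,
    background_sd: float | tuple[float, float] = 0.0,
    k: float = 2.0,
) -> list[EpimarkProfile]:
    """Classify cells into 5mC/5hmC positive/negative and strata.

    Parameters
    ----------
    intensities
        Per-cell (i_5mC, i_5hmC) background-subtracted intensities.
    method
        ``fixed_k_sd``: positive iff intensity > background_mean + k·SD
        (background stats per mark or scalar).  ``otsu``: per-mark Otsu
        threshold over the cell intensities (needs ≥ 2 cells and
        non-constant intensities).
    """
    arr = np.asarray(intensities, float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("intensities must be a sequence of (i_5mC, i_5hmC) pairs")

    if method == "fixed_k_sd":
        bm = _per_mark(background_mean, "background_mean")
        bs = _per_mark(background_sd, "background_sd")
        thresholds = (bm[0] + k * bs[0], bm[1] + k * bs[1])
    elif method == "otsu":
        if arr.shape[0] < 2:
            raise ValueError("otsu thresholding needs at least 2 cells")
        thresholds = []
        for col in range(2):
            x = arr[:, col]
            if np.ptp(x) == 0:
                raise ValueError("otsu threshold degenerate: constant intensities")
            thresholds.append(float(threshold_otsu(x, nbins=256)))
        thresholds = tuple(thresholds)
    else:
        raise ValueError(f"unknown method: {method!r}")

    return [
        EpimarkProfile(
            i_5mC=float(m),
            i_5hmC=float(h),
            pos_5mC=bool(m > thresholds[0]),
            pos_5hmC=bool(h > thresholds[1]),
        )
        for m, h in arr
    ]


def class_frequencies(
    labels: pd.DataFrame,
    field: str,
    classes: Sequence[str] | None = None,
    *,
    case_column: str | None = "case",
    min_n: int = 1000,
) -> pd.DataFrame:
    """Tabulate class frequencies (%) per case, with a mean ± SD row.

    Parameters
    ----------
    labels
        One row per cell, with a categorical column ``field`` and
        (optionally) a ``case`` column.
    classes
        Class order for the output columns; defaults to the sorted set of
        observed labels (or the canonical order for known fields).
    min_n
        Scoring-depth warning threshold per case.

    Returns
    -------
    DataFrame indexed by case (plus ``mean`` and ``sd`` rows when more
    than one case is present); one column per class, rows sum to 100.
    """
    if len(labels) == 0:
        raise ValueError("no records to tabulate")
    if classes is None:
        canonical = {"ab_class": AB_CLASSES, "ao_class": AO_CLASSES, "tunel_class": TUNEL_CLASSES}
        classes = canonical.get(field, tuple(sorted(labels[field].unique())))

    if case_column is not None and case_column in labels.columns:
        grouped = labels.groupby(case_column, sort=True)
    else:
        grouped = [("all", labels)]

    rows = {}
    for case, sub in grouped:
        n = len(sub)
        if n < min_n:
            warnings.warn(
                f"case {case!r}: only {n} cells scored (< {min_n})", stacklevel=2
            )
        counts = sub[field].value_counts()
        freqs = np.array([100.0 * counts.get(c, 0) / n for c in classes])
        rows[case] = freqs
        if not math.isclose(freqs.sum(), 100.0, abs_tol=1e-9):
            raise AssertionError("class frequencies must sum to 100")

    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(classes))
    out.index.name = case_column or "case"
    if len(rows) > 1:
        per_case = out.to_numpy()
        out.loc["mean"] = per_case.mean(axis=0)
        out.loc["sd"] = per_case.std(axis=0, ddof=1)
    return out
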