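"""Published reference values used as generator presets and worked examples.

These are the printed per-fraction summary statistics from the study the
pipeline reproduces: donor semen parameters, chromatin-integrity class
frequencies, epimark-positive frequencies, linear zone frequencies, radial
coordinates, and inter-centromere distances.  They parameterize the
synthetic-population generator and serve as inputs to the arithmetic
worked examples; they are data, not tunable code.
"""

from __future__ import annotations

FRACTIONS = ("raw", "SU", "DGC")
CHROMOSOMES = ("4", "7", "8", "9", "18", "X", "Y")

# ---------------------------------------------------------------------------
# Donor semen parameters (5 normozoospermic cases).  Columns: age, sperm
# concentration (10^6/ml), ejaculate volume (ml), total sperm count (10^6),
# normal morphology (%), total motility (%), progressive motility (%).
SEMEN_CASES: dict[str, dict[str, float]] = {
    "K1": {"age": 30, "concentration": 101.23, "volume": 3.0, "total_count": 303.7,
           "morphology": 21.0, "total_motility": 76.0, "progressive_motility": 59.0},
    "K2": {"age": 26, "concentration": 48.93, "volume": 2.5, "total_count": 122.3,
           "morphology": 4.0, "total_motility": 74.0, "progressive_motility": 66.0},
    "K3": {"age": 30, "concentration": 82.00, "volume": 4.5, "total_count": 369.0,
           "morphology": 7.0, "total_motility": 63.0, "progressive_motility": 55.0},
    "K4": {"age": 25, "concentration": 80.25, "volume": 3.8, "total_count": 305.0,
           "morphology": 4.0, "total_motility": 57.0, "progressive_motility": 48.0},
    "K5": {"age": 30, "concentration": 122.00, "volume": 2.0, "total_count": 244.0,
           "morphology": 6.0, "total_motility": 67.0, "progressive_motility": 62.0},
}

# ---------------------------------------------------------------------------
# Chromatin-integrity class frequencies (%), mean over cases, per fraction.
# AB protamination classes sum to 100 within each fraction.
CHROMATIN_CLASSES: dict[str, dict[str, float]] = {
    "raw": {"pink": 75.47, "purple": 13.77, "navy": 10.76,
            "ao_positive": 21.03, "tunel_positive": 5.54},
    "SU": {"pink": 93.76, "purple": 3.22, "navy": 3.02,
           "ao_positive": 6.70, "tunel_positive": 5.50},
    "DGC": {"pink": 95.04, "purple": 3.39, "navy": 1.57,
            "ao_positive": 6.39, "tunel_positive": 2.76},
}

# ---------------------------------------------------------------------------
# Epimark-positive sperm frequencies (%), mean over cases, per fraction.
EPIMARK_POSITIVE: dict[str, dict[str, float]] = {
    "raw": {"5mC": 57.82, "5hmC": 57.86},
    "SU": {"5mC": 64.87, "5hmC": 64.61},
    "DGC": {"5mC": 61.59, "5hmC": 61.79},
}

# ---------------------------------------------------------------------------
# Linear zone frequencies (%), mean over cases, per chromosome x fraction.
# Keys "18" (unselected), "18-X"/"18-Y" (sex-bearing context).  Order (a, m, b).
ZONE_FREQ: dict[str, dict[str, tuple[float, float, float]]] = {
    "4": {"raw": (9.33, 60.17, 30.50), "SU": (11.83, 60.83, 27.33), "DGC": (16.67, 60.83, 22.50)},
    "7": {"raw": (21.23, 62.03, 16.73), "SU": (23.17, 58.17, 18.50), "DGC": (26.83, 53.33, 19.83)},
    "8": {"raw": (10.17, 58.33, 31.50), "SU": (16.67, 57.00, 26.33), "DGC": (18.33, 57.17, 24.50)},
    "9": {"raw": (16.03, 68.83, 15.13), "SU": (17.67, 65.17, 16.83), "DGC": (23.17, 60.67, 16.17)},
    "18": {"raw": (20.43, 59.22, 20.35), "SU": (18.75, 59.25, 22.00), "DGC": (20.67, 58.67, 20.67)},
    "18-X": {"raw": (21.13, 56.13, 22.73), "SU": (19.00, 56.33, 24.67), "DGC": (20.00, 59.67, 20.33)},
    "18-Y": {"raw": (19.73, 62.30, 17.97), "SU": (18.50, 62.17, 19.33), "DGC": (21.33, 57.67, 21.00)},
    "X": {"raw": (27.10, 65.53, 7.37), "SU": (25.33, 69.83, 4.83), "DGC": (27.00, 64.67, 8.33)},
    "Y": {"raw": (19.30, 70.57, 10.13), "SU": (19.67, 71.17, 9.17), "DGC": (20.67, 65.00, 14.33)},
}

# ---------------------------------------------------------------------------
# Radial coordinates, mean over pooled signals, per chromosome x fraction:
# (D/L, H/L).  Chromosome 18 given unselected and per sex-bearing context.
RADIAL_MEAN: dict[str, dict[str, tuple[float, float]]] = {
    "4": {"raw": (0.462, 0.163), "SU": (0.504, 0.173), "DGC": (0.525, 0.179)},
    "7": {"raw": (0.552, 0.141), "SU": (0.553, 0.140), "DGC": (0.567, 0.150)},
    "8": {"raw": (0.463, 0.142), "SU": (0.498, 0.151), "DGC": (0.520, 0.169)},
    "9": {"raw": (0.543, 0.132), "SU": (0.548, 0.138), "DGC": (0.567, 0.150)},
    "18": {"raw": (0.536, 0.152), "SU": (0.535, 0.169), "DGC": (0.541, 0.157)},
    "18-X": {"raw": (0.531, 0.148), "SU": (0.530, 0.173), "DGC": (0.544, 0.156)},
    "18-Y": {"raw": (0.542, 0.156), "SU": (0.541, 0.165), "DGC": (0.539, 0.157)},
    "X": {"raw": (0.598, 0.130), "SU": (0.612, 0.148), "DGC": (0.594, 0.129)},
    "Y": {"raw": (0.563, 0.134), "SU": (0.584, 0.153), "DGC": (0.568, 0.135)},
}

# ---------------------------------------------------------------------------
# Mean inter-centromere distances (µm) per chromosome pair x fraction.
DISTANCE_MEAN: dict[tuple[str, str], dict[str, float]] = {
    ("4", "8"): {"raw": 1.888, "SU": 2.073, "DGC": 2.184},
    ("7", "9"): {"raw": 1.571, "SU": 1.707, "DGC": 1.989},
    ("18", "X"): {"raw": 1.859, "SU": 1.926, "DGC": 1.853},
    ("18", "Y"): {"raw": 1.662, "SU": 1.858, "DGC": 1.739},
}

# Published chromocenter partitions (Ward clustering of per-chromosome mean
# radial points), with the cluster count used for each fraction.
CHROMOCENTER_PARTITION: dict[str, tuple[int, list[frozenset[str]]]] = {
    "raw": (3, [frozenset({"4", "8"}), frozenset({"7", "9", "18", "Y"}), frozenset({"X"})]),
    "SU": (4, [frozenset({"4", "8"}), frozenset({"7", "9"}), frozenset({"X", "Y"}), frozenset({"18"})]),
    "DGC": (2, [frozenset({"4", "8", "18"}), frozenset({"7", "9", "X", "Y"})]),
}

# Study design: chromosomes x fractions x epigenetic strata x minimum
# signals per combination.
DESIGN_FACTORS = {"chromosomes": 7, "fractions": 3, "epistates": 2, "min_signals": 100}


def radial_points(fraction: str, chromosomes: tuple[str, ...] = CHROMOSOMES) -> dict[str, tuple[float, float]]:
    """Per-chromosome mean (D/L, H/L) points for one fraction (18 unselected)."""
    return {c: RADIAL_MEAN[c][fraction] for c in chromosomes}
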