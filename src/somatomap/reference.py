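"""Reported group summaries from the STOML3 nerve cross-anastomosis study.

These are the printed inputs (means ± SEM with group sizes, and category
counts) that the statistics layer recomputes test statistics from: myelinated
axon counts distal to the anastomosis, conduction velocities of intact /
self-anastomosed / cross-anastomosed afferents, RAM vibration thresholds,
terminal-field spans and dorsoventral areal densities for the left (second
digit) and right (third digit) terminal fields, focus-shift components, and
the mechano-insensitive / tap-unit proportions from the electrical search
protocol.

All values are exactly as printed; derived quantities (t, F, Fisher p,
percent changes, planar shifts) are always recomputed, never stored.
"""

from __future__ import annotations

import numpy as np

from .stats import ContingencyTable, SummaryStats

__all__ = [
    "AXON_COUNTS",
    "CV_ABETA",
    "CV_SAM",
    "CV_RAM",
    "CV_ADELTA",
    "RAM_VIBRATION_THRESHOLDS",
    "SPANS",
    "DENSITY_DV",
    "VOXEL_COUNTS_1E6",
    "FOCUS_SHIFT_COMPONENTS_UM",
    "INSENSITIVE_COUNTS",
    "TAP_UNIT_COUNTS",
]

#: myelinated axons distal to the cross-anastomosis (control vs stoml3 null)
AXON_COUNTS = {
    "control": SummaryStats(mean=722.4, sem=133.9, n=3),
    "stoml3": SummaryStats(mean=649.2, sem=54.92, n=3),
}

#: conduction velocities (m/s), groups ordered intact / self / cross
CV_ABETA = (
    SummaryStats(15.58, 0.72, 22),
    SummaryStats(11.84, 0.37, 31),
    SummaryStats(10.82, 0.50, 18),
)
CV_SAM = (
    SummaryStats(17.09, 1.19, 8),
    SummaryStats(11.69, 0.48, 17),
    SummaryStats(11.00, 0.63, 12),
)
CV_RAM = (
    SummaryStats(14.72, 0.86, 14),
    SummaryStats(12.04, 0.58, 14),
    SummaryStats(10.45, 0.85, 6),
)
CV_ADELTA = (
    SummaryStats(5.14, 0.37, 15),
    SummaryStats(4.48, 0.50, 16),
    SummaryStats(3.55, 0.70, 10),
)

#: RAM mechanical thresholds (mN) from the 50 Hz vibration stimulus,
#: wild-type groups intact / self / cross
RAM_VIBRATION_THRESHOLDS = (
    SummaryStats(13.9, 2.4, 10),
    SummaryStats(7.1, 1.3, 14),
    SummaryStats(10.6, 5.2, 5),
)

#: terminal-field spans (µm): field -> axis -> (control, mutant)
SPANS = {
    "left": {
        "ML": (SummaryStats(167.9, 5.9, 8), SummaryStats(191.6, 6.3, 6)),
        "RC": (SummaryStats(882.0, 45.6, 8), SummaryStats(1143.0, 42.3, 6)),
        "DV": (SummaryStats(103.4, 2.9, 8), SummaryStats(108.9, 3.8, 6)),
    },
    "right": {
        "ML": (SummaryStats(209.0, 5.3, 8), SummaryStats(233.9, 5.8, 6)),
        "RC": (SummaryStats(885.7, 47.0, 8), SummaryStats(1155.0, 85.4, 6)),
        "DV": (SummaryStats(108.5, 3.4, 8), SummaryStats(114.9, 5.6, 6)),
    },
}

#: dorsoventral areal densities (voxels/µm²): field -> (control, mutant)
DENSITY_DV = {
    "left": (SummaryStats(30.8, 1.5, 8), SummaryStats(24.0, 0.9, 6)),
    "right": (SummaryStats(24.4, 1.2, 8), SummaryStats(16.5, 1.8, 6)),
}

#: total labelled voxels, in millions: field -> (control, mutant)
VOXEL_COUNTS_1E6 = {
    "left": (SummaryStats(3.14, 0.418, 8), SummaryStats(2.78, 0.183, 6)),
    "right": (SummaryStats(2.30, 0.271, 8), SummaryStats(1.79, 0.260, 6)),
}

#: mean focus displacement of the mutant group, (lateral, ventral) µm
FOCUS_SHIFT_COMPONENTS_UM = {
    "left": (18.75, 1.42),
    "right": (14.00, 13.54),
}

#: electrical search: (insensitive, sensitive) counts per genotype
INSENSITIVE_COUNTS = {
    "Adelta": ContingencyTable(
        counts=np.array([[4, 18], [25, 16]]),
        row_labels=("control", "stoml3"),
        col_labels=("insensitive", "sensitive"),
    ),
    "Abeta": ContingencyTable(
        counts=np.array([[10, 28], [33, 20]]),
        row_labels=("control", "stoml3"),
        col_labels=("insensitive", "sensitive"),
    ),
}

#: tap-units among mechanosensitive fibres of the cross-anastomosed nerve
TAP_UNIT_COUNTS = ContingencyTable(
    counts=np.array([[1, 18], [15, 12]]),
    row_labels=("control", "stoml3"),
    col_labels=("tap-unit", "other"),
)
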