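"""Published per-subject accuracy tables for the two benchmark datasets.

These are the reference subject-wise peak test accuracies (%) reported for
the five channel configurations of each dataset, together with the summary
rows as printed.  They serve as input fixtures for validating the summary
conventions of :func:`mieog.data_model.summarize_table` (population
standard deviation; even-count median as the midpoint of the two central
values) — the printed summary rows are recoverable from the per-subject
rows only under those conventions.
"""

from __future__ import annotations

#: 4-class, 9-subject dataset (22 EEG + 3 EOG): per-subject accuracy (%) by
#: channel configuration, subjects S1..S9 in order.
DATASET1_ROWS: dict[str, list[float]] = {
    "22 EEG": [81.8, 65.5, 91.3, 81.0, 83.6, 77.5, 92.2, 90.5, 93.1],
    "22 EEG + 3 EOG": [85.3, 75.8, 89.6, 86.2, 95.6, 80.1, 91.3, 91.3, 96.5],
    "3 EOG": [62.0, 63.7, 51.7, 62.9, 94.8, 62.9, 90.5, 86.2, 75.8],
    "3 EEG": [65.5, 48.2, 82.7, 59.4, 69.8, 55.1, 85.3, 76.7, 81.0],
    "3 EEG + 3 EOG": [79.3, 71.5, 83.6, 71.5, 95.6, 71.5, 92.2, 91.3, 90.5],
}

#: Printed summary rows for the same table: configuration -> (mean, median, std).
DATASET1_SUMMARY: dict[str, tuple[float, float, float]] = {
    "22 EEG": (84.0, 83.6, 8.46),
    "22 EEG + 3 EOG": (87.9, 89.6, 6.46),
    "3 EOG": (72.2, 63.7, 14.23),
    "3 EEG": (69.3, 69.8, 12.41),
    "3 EEG + 3 EOG": (83.0, 83.6, 9.3),
}

#: 7-class, 10-subject dataset (60 EEG + 2 EOG), subjects S1..S10 in order.
DATASET2_ROWS: dict[str, list[float]] = {
    "60 EEG": [35.7, 47.3, 40.1, 66.9, 64.2, 45.0, 64.2, 66.9, 63.3, 81.2],
    "60 EEG + 2 EOG": [44.6, 57.1, 43.7, 79.4, 68.7, 48.0, 70.5, 64.2, 62.5, 87.5],
    "2 EOG": [51.7, 49.1, 31.2, 62.5, 58.9, 50.0, 48.2, 59.8, 58.9, 81.2],
    "3 EEG": [45.5, 41.9, 41.0, 62.5, 73.2, 44.0, 52.6, 73.2, 58.9, 55.3],
    "3 EEG + 2 EOG": [58.0, 56.2, 41.0, 67.8, 73.2, 42.0, 53.5, 73.2, 66.0, 79.4],
}

DATASET2_SUMMARY: dict[str, tuple[float, float, float]] = {
    "60 EEG": (57.4, 63.75, 13.784),
    "60 EEG + 2 EOG": (62.6, 63.35, 13.89),
    "2 EOG": (55.1, 55.3, 12.16),
    "3 EEG": (54.8, 53.95, 11.48),
    "3 EEG + 2 EOG": (61.0, 62.0, 12.47),
}
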