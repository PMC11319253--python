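"""Published 10-fold benchmark results for this architecture on the Bonn data.

Per-fold accuracy/sensitivity/specificity values and their printed means,
as reported for the FFT + FC-NLSTM pipeline on the real Bonn corpus.  They
serve two purposes: fixtures for the aggregation machinery (recomputing
each Mean from its ten fold values) and context for comparing synthetic
runs against the published operating point.

Note: in the published tables the C_vs_E row is internally inconsistent —
its ten printed fold values do not average to its printed means (recomputed
0.9925/0.9975/0.9875 vs printed 0.9875/1.0000/0.9750).  The values are
transcribed verbatim; consumers that need self-consistent rows should
exclude C_vs_E (see ``INCONSISTENT_CELLS``).
"""

from __future__ import annotations

#: Per-task published fold values and printed means.  Structure:
#: task -> metric -> (ten fold values, printed mean).
PUBLISHED_FOLDS: dict[str, dict[str, tuple[tuple[float, ...], float]]] = {
    "A_vs_E": {
        "acc": ((1.0, 1.0, 1.0, 0.9875, 0.9875, 0.9875, 1.0, 1.0, 1.0, 1.0), 0.9962),
        "sen": ((1.0, 1.0, 1.0, 0.9756, 0.9756, 0.9756, 1.0, 1.0, 1.0, 1.0), 0.9927),
        "spe": ((1.0,) * 10, 1.0),
    },
    "B_vs_E": {
        "acc": ((1.0, 0.9875, 0.9875, 0.9625, 0.9875, 1.0, 0.9750, 1.0, 1.0, 1.0), 0.9900),
        "sen": ((1.0, 1.0, 0.9750, 1.0, 0.9750, 1.0, 1.0, 1.0, 1.0, 1.0), 0.9950),
        "spe": ((1.0, 0.9750, 1.0, 0.9250, 1.0, 1.0, 0.9500, 1.0, 1.0, 1.0), 0.9850),
    },
    "AB_vs_E": {
        "acc": ((1.0, 1.0, 0.9917, 1.0, 0.9917, 1.0, 1.0, 1.0, 1.0, 1.0), 0.9983),
        "sen": ((1.0, 1.0, 0.9750, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0), 0.9975),
        "spe": ((1.0, 1.0, 1.0, 1.0, 0.9875, 1.0, 1.0, 1.0, 1.0, 1.0), 0.9988),
    },
    "C_vs_E": {
        "acc": ((1.0, 0.9750, 1.0, 1.0, 0.9750, 0.9875, 0.9875, 1.0, 1.0, 1.0), 0.9875),
        "sen": ((1.0, 0.9750, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0), 1.0),
        "spe": ((1.0, 0.9750, 1.0, 1.0, 0.9500, 0.9750, 0.9750, 1.0, 1.0, 1.0), 0.9750),
    },
    "D_vs_E": {
        "acc": ((0.9625, 1.0, 0.9750, 1.0, 0.9375, 0.9875, 0.9875, 0.9500, 0.9750, 0.9875), 0.9763),
        "sen": ((0.9750, 1.0, 0.9750, 1.0, 1.0, 1.0, 0.9750, 1.0, 1.0, 0.9750), 0.9900),
        "spe": ((0.9500, 1.0, 0.9750, 1.0, 0.8750, 0.9750, 1.0, 0.9000, 0.9500, 1.0), 0.9625),
    },
    "CD_vs_E": {
        "acc": ((0.9583, 0.9750, 1.0, 1.0, 1.0, 0.9833, 0.9833, 1.0, 0.9833, 0.9833), 0.9867),
        "sen": ((1.0, 1.0, 1.0, 1.0, 1.0, 0.9500, 0.9750, 1.0, 0.9750, 0.9750), 0.9875),
        "spe": ((0.9375, 0.9625, 1.0, 1.0, 1.0, 1.0, 0.9875, 1.0, 0.9875, 0.9875), 0.9863),
    },
    "ABCD_vs_E": {
        "acc": ((0.9950, 0.9950, 0.9850, 0.9500, 1.0, 0.9900, 0.9550, 0.9900, 0.9650, 0.9900), 0.9815),
        "sen": ((0.9750, 0.9750, 0.9500, 0.8000, 1.0, 0.9750, 0.8000, 0.9500, 0.9250, 0.9500), 0.9300),
        "spe": ((1.0, 1.0, 0.9938, 0.9875, 1.0, 0.9938, 0.9938, 1.0, 0.9750, 1.0), 0.9944),
    },
    "AB_vs_CD": {
        "acc": ((0.9812, 0.9875, 0.9875, 1.0, 0.9938, 0.9875, 0.9938, 1.0, 0.9938, 0.9812), 0.9906),
        "sen": ((0.9875, 0.9750, 0.9875, 1.0, 0.9875, 0.9875, 0.9875, 1.0, 1.0, 0.9750), 0.9887),
        "spe": ((0.9750, 1.0, 0.9875, 1.0, 1.0, 0.9875, 1.0, 1.0, 0.9875, 0.9875), 0.9925),
    },
    "AB_vs_CDE": {
        "acc": ((0.9800, 0.9650, 0.9850, 0.9800, 0.9900, 0.9700, 0.9950, 0.9800, 0.9750, 0.9750), 0.9795),
        "sen": ((0.9833, 0.9583, 0.9750, 0.9750, 0.9833, 0.9750, 1.0, 0.9667, 0.9667, 0.9750), 0.9758),
        "spe": ((0.9750, 0.9750, 1.0, 0.9875, 1.0, 0.9625, 0.9875, 1.0, 0.9875, 0.9750), 0.9850),
    },
}

#: (task, metric) cells whose printed mean does not equal the mean of the
#: printed fold values (source-table transcription defect).
INCONSISTENT_CELLS: frozenset[tuple[str, str]] = frozenset(
    {("C_vs_E", "acc"), ("C_vs_E", "sen"), ("C_vs_E", "spe")}
)

#: Published mean accuracy per (task, feature kind) for the feature
#: comparison on the real corpus.
PUBLISHED_FEATURE_ACCURACY: dict[str, dict[str, float]] = {
    "A_vs_E": {"fft": 0.9962, "dwt": 0.8975, "emd": 0.7312},
    "B_vs_E": {"fft": 0.9900, "dwt": 0.9425, "emd": 0.5525},
    "AB_vs_E": {"fft": 0.9983, "dwt": 0.9658, "emd": 0.7833},
    "C_vs_E": {"fft": 0.9913, "dwt": 0.9338, "emd": 0.5000},
    "D_vs_E": {"fft": 0.9763, "dwt": 0.9400, "emd": 0.8925},
    "CD_vs_E": {"fft": 0.9867, "dwt": 0.9533, "emd": 0.6667},
    "AB_vs_CD": {"fft": 0.9906, "dwt": 0.8631, "emd": 0.9569},
    "ABCD_vs_E": {"fft": 0.9815, "dwt": 0.9655, "emd": 0.9915},
    "AB_vs_CDE": {"fft": 0.9795, "dwt": 0.8505, "emd": 0.7890},
}
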