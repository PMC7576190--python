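"""Published group-level reference values for RVO OCTA morphometry.

Group means ± SD of the seven morphometric parameters from a clinical
retinal-vein-occlusion cohort (31 control, 34 BRVO, 21 CRVO eyes; central
3×3 mm, SCP and DCP). Raw per-eye images of that cohort are not publicly
available, so these summary values serve two purposes here:

* internal-consistency audits — the implemented definitions imply
  mean BL ≥ mean EL within every group, and the ratio of the group-mean
  length sums should sit near the group-mean tortuosity (near, not equal:
  a mean of per-eye ratios is not a ratio of means);
* soft calibration windows for the synthetic generator's layer presets.

Keys are (layer, group); values map metric name → (mean, sd). Units follow
the metrics stage: sums in mm, means in µm, VT dimensionless, VD fraction.
"""

from __future__ import annotations

GROUP_SUMMARY = {
    ("SCP", "control"): {
        "branch_number": (293.871, 90.195),
        "sum_bl_mm": (32.852, 7.762),
        "sum_el_mm": (28.742, 6.642),
        "mean_bl_um": (114.291, 10.124),
        "mean_el_um": (100.181, 9.247),
        "vt": (1.142, 0.013),
        "vd": (0.231, 0.044),
    },
    ("SCP", "BRVO_fellow_affected"): {
        "branch_number": (292.235, 108.897),
        "sum_bl_mm": (32.965, 9.429),
        "sum_el_mm": (28.853, 7.948),
        "mean_bl_um": (118.134, 17.388),
        "mean_el_um": (103.858, 16.179),
        "vt": (1.139, 0.017),
        "vd": (0.227, 0.053),
    },
    ("SCP", "BRVO_fellow_nonaffected"): {
        "branch_number": (303.882, 114.693),
        "sum_bl_mm": (33.857, 9.73),
        "sum_el_mm": (29.518, 8.172),
        "mean_bl_um": (117.414, 20.099),
        "mean_el_um": (102.989, 19.216),
        "vt": (1.143, 0.019),
        "vd": (0.229, 0.056),
    },
    ("SCP", "BRVO_affected"): {
        "branch_number": (260.618, 85.151),
        "sum_bl_mm": (30.824, 7.832),
        "sum_el_mm": (26.706, 6.554),
        "mean_bl_um": (122.688, 17.180),
        "mean_el_um": (106.714, 16.052),
        "vt": (1.152, 0.019),
        "vd": (0.215, 0.047),
    },
    ("SCP", "BRVO_nonaffected"): {
        "branch_number": (267.265, 101.579),
        "sum_bl_mm": (31.003, 8.626),
        "sum_el_mm": (27.049, 7.210),
        "mean_bl_um": (121.454, 17.630),
        "mean_el_um": (106.477, 16.702),
        "vt": (1.143, 0.020),
        "vd": (0.216, 0.048),
    },
    ("SCP", "CRVO_fellow"): {
        "branch_number": (279.238, 101.88),
        "sum_bl_mm": (32.049, 9.019),
        "sum_el_mm": (27.970, 7.595),
        "mean_bl_um": (119.368, 15.760),
        "mean_el_um": (104.524, 14.436),
        "vt": (1.143, 0.018),
        "vd": (0.223, 0.050),
    },
    ("SCP", "CRVO"): {
        "branch_number": (250.857, 94.882),
        "sum_bl_mm": (30.221, 9.500),
        "sum_el_mm": (26.289, 8.171),
        "mean_bl_um": (126.491, 20.766),
        "mean_el_um": (110.445, 19.303),
        "vt": (1.147, 0.016),
        "vd": (0.213, 0.059),
    },
    ("DCP", "control"): {
        "branch_number": (445.065, 91.663),
        "sum_bl_mm": (35.985, 9.069),
        "sum_el_mm": (29.809, 7.141),
        "mean_bl_um": (80.006, 5.665),
        "mean_el_um": (66.480, 3.964),
        "vt": (1.203, 0.024),
        "vd": (0.204, 0.043),
    },
    ("DCP", "BRVO_fellow_affected"): {
        "branch_number": (450.000, 94.186),
        "sum_bl_mm": (36.681, 8.928),
        "sum_el_mm": (30.533, 7.107),
        "mean_bl_um": (81.029, 4.042),
        "mean_el_um": (67.592, 3.148),
        "vt": (1.199, 0.021),
        "vd": (0.203, 0.041),
    },
    ("DCP", "BRVO_fellow_nonaffected"): {
        "branch_number": (450.382, 89.828),
        "sum_bl_mm": (36.824, 8.946),
        "sum_el_mm": (30.697, 7.148),
        "mean_bl_um": (81.064, 5.129),
        "mean_el_um": (67.744, 3.735),
        "vt": (1.197, 0.021),
        "vd": (0.204, 0.039),
    },
    ("DCP", "BRVO_affected"): {
        "branch_number": (318.588, 127.817),
        "sum_bl_mm": (27.045, 11.496),
        "sum_el_mm": (22.428, 9.379),
        "mean_bl_um": (83.407, 7.536),
        "mean_el_um": (69.480, 5.774),
        "vt": (1.201, 0.028),
        "vd": (0.151, 0.057),
    },
    ("DCP", "BRVO_nonaffected"): {
        "branch_number": (365.235, 126.556),
        "sum_bl_mm": (29.478, 11.801),
        "sum_el_mm": (24.723, 9.572),
        "mean_bl_um": (78.526, 8.152),
        "mean_el_um": (66.306, 5.828),
        "vt": (1.183, 0.028),
        "vd": (0.165, 0.057),
    },
    ("DCP", "CRVO_fellow"): {
        "branch_number": (441.667, 71.633),
        "sum_bl_mm": (35.911, 6.803),
        "sum_el_mm": (29.726, 5.393),
        "mean_bl_um": (81.069, 3.717),
        "mean_el_um": (67.223, 3.255),
        "vt": (1.207, 0.021),
        "vd": (0.204, 0.030),
    },
    ("DCP", "CRVO"): {
        "branch_number": (282.429, 103.912),
        "sum_bl_mm": (23.457, 9.672),
        "sum_el_mm": (19.696, 8.001),
        "mean_bl_um": (80.980, 10.077),
        "mean_el_um": (68.225, 8.163),
        "vt": (1.187, 0.018),
        "vd": (0.136, 0.051),
    },
}


def ratio_of_mean_sums(layer: str, group: str) -> float:
    """Group-mean ΣBL divided by group-mean ΣEL — the tortuosity implied by
    the printed sums, to be compared against the printed group VT."""
    row = GROUP_SUMMARY[(layer, group)]
    return row["sum_bl_mm"][0] / row["sum_el_mm"][0]
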