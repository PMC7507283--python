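"""Embedded genotype-mean trait tables for the seven rice genotypes.

Four published tables of genotype means ± standard errors (n = 5 biological
replicates) at 14 and 28 days after sowing (DAS): manually sampled growth
parameters (tables ``table1``/``table2``) and imaging-derived parameters
(``table3``/``table4``), each with the published one-way ANOVA significance
code (** p < 0.001, * p < 0.05, NS non-significant).  Values are transcribed
verbatim and treated as immutable; a checksum over the canonical
serialization guards against silent edits.

Traits absent at a date (e.g. tiller number at 14 DAS) simply do not appear
in that table, mirroring the "–" cells of the published correlation table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .io import TableLevel, TraitTable

GENOTYPES = ("LB-46", "GM-217", "AC38399", "ARC10656", "Vandana", "Sabita", "Varshadhan")

#: Number of biological replicates behind every mean ± SE.
N_REPLICATES = 5

# trait -> (unit, means, standard errors, ANOVA code); genotype order as above
_TABLE1 = {  # manual sampling, 14 DAS
    "shoot_length": ("cm", (24.22, 30.78, 23.40, 22.3, 27.76, 20.28, 22.82),
                     (1.36, 0.83, 1.63, 1.19, 0.65, 0.64, 1.05), "**"),
    "root_length": ("cm", (14.98, 15.34, 16.76, 16.26, 18.48, 17.24, 19.94),
                    (0.28, 1.47, 0.78, 0.77, 1.27, 0.46, 3.73), "NS"),
    "shoot_dry_weight": ("g", (0.0466, 0.059, 0.0382, 0.033, 0.0528, 0.0342, 0.0996),
                         (0.007, 0.008, 0.005, 0.001, 0.002, 0.004, 0.05), "NS"),
    "root_dry_weight": ("g", (0.0182, 0.0246, 0.0174, 0.020, 0.0212, 0.0192, 0.0146),
                        (0.002, 0.006, 0.002, 0.004, 0.002, 0.002, 0.0015), "NS"),
    "seed_weight_with_mesocotyl": ("g", (0.0154, 0.0494, 0.0108, 0.0062, 0.0132, 0.0094, 0.01),
                                   (0.002, 0.03, 0.006, 0.001, 0.001, 0.005, 0.001), "NS"),
    "mesocotyl_length": ("cm", (0.38, 0.34, 0.32, 0.30, 0.34, 0.30, 0.38),
                         (0.04, 0.02, 0.03, 0.04, 0.02, 0.04, 0.03), "NS"),
    "stem_thickness": ("mm", (1.47, 1.25, 1.14, 1.38, 1.40, 1.10, 1.32),
                       (0.07, 0.02, 0.08, 0.06, 0.008, 0.06, 0.028), "**"),
    "leaf_number": ("count", (3.6, 4.0, 3.0, 3.2, 3.0, 3.0, 3.6),
                    (0.24, 0.31, 0.05, 0.2, 0.01, 0.001, 0.24), "**"),
    "first_leaf_weight": ("g", (0.0032, 0.0034, 0.0030, 0.0030, 0.0048, 0.0044, 0.0026),
                          (0.0004, 0.0003, 0.0004, 0.0002, 0.0003, 0.003, 0.0004), "NS"),
    "second_leaf_weight": ("g", (0.0088, 0.0078, 0.0086, 0.0058, 0.0108, 0.0068, 0.0064),
                           (0.003, 0.001, 0.001, 0.002, 0.005, 0.007, 0.006), "NS"),
    "third_leaf_weight": ("g", (0.0094, 0.0098, 0.0096, 0.0078, 0.0168, 0.007, 0.0108),
                          (0.004, 0.004, 0.002, 0.003, 0.006, 0.005, 0.004), "*"),
}

_TABLE2 = {  # manual sampling, 28 DAS
    "shoot_length": ("cm", (41.48, 49.52, 42.92, 43.68, 43.88, 39.76, 39.00),
                     (2.76, 2.4, 1.76, 0.37, 2.05, 0.81, 1.77), "*"),
    "root_length": ("cm", (25.32, 25.40, 28.22, 26.72, 25.78, 32.28, 23.44),
                    (1.46, 1.48, 1.18, 1.42, 2.21, 1.67, 1.63), "*"),
    "shoot_dry_weight": ("g", (0.396, 0.303, 0.188, 0.136, 0.180, 0.159, 0.269),
                         (0.033, 0.10, 0.036, 0.011, 0.026, 0.009, 0.039), "**"),
    "root_dry_weight": ("g", (0.27, 0.169, 0.142, 0.073, 0.149, 0.088, 0.112),
                        (0.025, 0.05, 0.03, 0.011, 0.015, 0.007, 0.013), "**"),
    "tiller_number": ("count", (3.40, 1.80, 1.20, 1.00, 1.00, 1.20, 2.20),
                      (0.24, 0.58, 0.20, 0.001, 0.001, 0.20, 0.37), "**"),
    "stem_weight": ("g", (0.38, 0.15, 0.07, 0.07, 0.09, 0.07, 0.11),
                    (0.17, 0.04, 0.01, 0.003, 0.02, 0.01, 0.01), "*"),
    "stem_thickness": ("mm", (3.48, 3.46, 3.05, 2.81, 3.13, 3.12, 2.70),
                       (0.31, 0.20, 0.20, 0.12, 0.17, 0.18, 0.19), "NS"),
    "leaf_number": ("count", (11.2, 7.40, 6.40, 6.40, 6.20, 6.20, 8.80),
                    (1.16, 1.40, 0.68, 0.24, 0.20, 0.20, 1.24), "**"),
    "first_leaf_weight": ("g", (0.002, 0.003, 0.003, 0.003, 0.003, 0.005, 0.003),
                          (0.0001, 0.0004, 0.0002, 0.0004, 0.0002, 0.0006, 0.0002), "NS"),
    "second_leaf_weight": ("g", (0.008, 0.006, 0.004, 0.006, 0.006, 0.010, 0.007),
                           (0.0009, 0.0008, 0.0006, 0.0009, 0.0008, 0.0002, 0.0009), "NS"),
    "third_leaf_weight": ("g", (0.010, 0.011, 0.005, 0.011, 0.012, 0.011, 0.014),
                          (0.001, 0.002, 0.001, 0.001, 0.002, 0.001, 0.002), "NS"),
    "fourth_leaf_weight": ("g", (0.013, 0.017, 0.016, 0.018, 0.024, 0.017, 0.023),
                           (0.002, 0.002, 0.002, 0.001, 0.002, 0.001, 0.002), "NS"),
    "fifth_leaf_weight": ("g", (0.024, 0.032, 0.023, 0.022, 0.032, 0.029, 0.027),
                          (0.001, 0.002, 0.002, 0.001, 0.002, 0.002, 0.001), "NS"),
    "sixth_leaf_weight": ("g", (0.036, 0.036, 0.037, 0.027, 0.038, 0.027, 0.033),
                          (0.002, 0.002, 0.002, 0.001, 0.002, 0.001, 0.002), "NS"),
    "seventh_leaf_weight": ("g", (0.009, 0.009, 0.005, 0.006, 0.005, 0.005, 0.003),
                            (0.0008, 0.0007, 0.0002, 0.0002, 0.0003, 0.0005, 0.0006), "NS"),
}

_TABLE3 = {  # imaging, 14 DAS
    "first_leaf_length": ("mm", (52.47, 39.33, 47.86, 48.90, 55.69, 61.88, 44.45),
                          (5.79, 2.62, 5.29, 2.22, 1.89, 3.97, 4.16), "*"),
    "second_leaf_length": ("mm", (131.17, 125.18, 143.59, 120.87, 147.78, 112.42, 118.97),
                           (16.29, 7.25, 6.96, 8.15, 3.62, 6.39, 4.30), "NS"),
    "third_leaf_length": ("mm", (178.21, 202.07, 173.02, 158.66, 203.80, 118.24, 158.06),
                          (10.2, 4.17, 10.95, 9.32, 4.40, 17.82, 8.61), "**"),
    "first_leaf_width": ("mm", (2.39, 1.83, 2.40, 2.02, 2.83, 2.54, 2.43),
                         (0.48, 0.15, 0.24, 0.14, 0.11, 0.23, 0.12), "NS"),
    "second_leaf_width": ("mm", (2.38, 2.53, 2.80, 2.51, 2.78, 2.96, 2.68),
                          (0.21, 0.13, 0.25, 0.14, 0.11, 0.30, 0.07), "NS"),
    "third_leaf_width": ("mm", (2.96, 2.20, 3.12, 2.4, 3.81, 2.61, 3.61),
                         (0.23, 0.13, 0.43, 0.35, 0.12, 0.25, 0.27), "**"),
    "first_leaf_area": ("mm2", (97.38, 81.10, 107.57, 115.90, 114.28, 107.52, 80.29),
                        (20.53, 11.53, 17.43, 13.72, 7.06, 7.72, 12.35), "NS"),
    "second_leaf_area": ("mm2", (242.33, 257.90, 305.80, 214.34, 276.31, 217.15, 225.43),
                         (38.73, 17.78, 31.68, 18.34, 15.97, 31.27, 23.62), "NS"),
    "third_leaf_area": ("mm2", (381.01, 352.48, 374.25, 268.87, 511.13, 221.04, 351.85),
                        (45.32, 10.54, 57.70, 40.13, 30.33, 46.28, 54.56), "**"),
    "stem_area": ("mm2", (185.89, 402.86, 176.98, 199.65, 216.80, 143.79, 171.66),
                  (54.0, 30.15, 20.04, 25.43, 15.28, 13.42, 12.39), "**"),
    "eccentricity": ("", (205.37, 287.20, 148.08, 64.477, 241.80, 110.20, 160.49),
                     (22.72, 23.04, 31.81, 17.45, 17.06, 12.64, 18.61), "**"),
    "convex_hull": ("mm2", (9029.58, 24191.40, 4624.74, 6657.24, 17011.46, 2635.28, 5376.21),
                    (3243.0, 3913.40, 1784.0, 2597.0, 3955.0, 679.39, 1912.0), "**"),
    "caliper_length": ("mm", (311.49, 403.99, 227.75, 207.89, 415.39, 162.58, 286.71),
                       (48.16, 25.76, 49.0, 21.76, 22.75, 19.40, 34.94), "**"),
    "wpa_s": ("mm2", (906.62, 1264.52, 964.61, 798.76, 1118.54, 689.49, 829.22),
              (89.0, 98.0, 98.64, 44.57, 49.51, 68.34, 75.42), "**"),
    "wpa_i": ("mm2", (1095.45, 1498.38, 726.61, 593.90, 1384.60, 514.22, 857.27),
              (178.0, 124.0, 143.0, 61.76, 86.28, 57.06, 138.47), "**"),
    "top_view_area": ("mm2", (3061.90, 3222.871, 1637.00, 1359.82, 1057.60, 1057.60, 1539.68),
                      (642.51, 848.06, 591.0, 337.0, 284.0, 284.62, 422.0), "**"),
    "compactness": ("", (0.34, 0.13, 0.35, 0.20, 0.06, 0.40, 0.29),
                    (0.04, 0.01, 0.03, 0.02, 0.01, 0.05, 0.02), "**"),
}

_TABLE4 = {  # imaging, 28 DAS
    "first_leaf_length": ("mm", (66.32, 63.20, 48.21, 67.36, 72.14, 101.26, 48.21),
                          (2.76, 13.26, 3.08, 16.78, 18.87, 19.02, 3.08), "NS"),
    "second_leaf_length": ("mm", (111.94, 147.49, 130.81, 128.46, 173.22, 126.56, 130.81),
                           (20.43, 16.44, 4.61, 19.29, 20.30, 29.26, 4.61), "NS"),
    "third_leaf_length": ("mm", (151.18, 193.23, 180.63, 177.35, 229.31, 174.90, 180.63),
                          (20.03, 22.2, 4.42, 15.42, 21.69, 31.52, 4.42), "NS"),
    "fourth_leaf_length": ("mm", (198.58, 229.58, 210.45, 228.71, 271.79, 201.28, 210.45),
                           (15.05, 21.52, 4.95, 25.32, 26.66, 27.44, 4.95), "NS"),
    "fifth_leaf_length": ("mm", (243.21, 229.89, 230.32, 234.56, 205.24, 180.11, 230.32),
                          (21.18, 37.97, 11.47, 39.73, 44.85, 27.27, 13.31), "NS"),
    "sixth_leaf_length": ("mm", (229.48, 168.76, 229.27, 190.79, 184.21, 255.59, 229.27),
                          (44.81, 74.47, 41.11, 92.98, 81.17, 21.16, 41.11), "NS"),
    "seventh_leaf_length": ("mm", (201.18, 582.00, 74.13, 85.64, 83.14, 228.57, 74.13),
                            (39.41, 82.14, 14.64, 17.24, 19.62, 24.51, 4.91), "NS"),
    "first_leaf_width": ("mm", (2.16, 2.18, 2.89, 2.11, 3.50, 3.60, 2.89),
                         (0.34, 0.28, 0.37, 0.33, 0.20, 0.21, 0.37), "**"),
    "second_leaf_width": ("mm", (2.62, 2.66, 2.77, 2.49, 3.34, 3.74, 2.77),
                          (0.24, 0.41, 0.16, 0.27, 0.32, 0.23, 0.16), "*"),
    "third_leaf_width": ("mm", (3.19, 3.03, 3.68, 2.88, 4.39, 3.96, 3.68),
                         (0.42, 0.52, 0.16, 0.32, 0.36, 0.37, 0.16), "*"),
    "fourth_leaf_width": ("mm", (4.36, 3.42, 4.78, 3.36, 4.57, 4.22, 4.78),
                          (0.50, 0.24, 0.34, 0.08, 0.44, 0.36, 0.34), "**"),
    "fifth_leaf_width": ("mm", (4.61, 14.25, 5.25, 2.79, 3.34, 4.14, 5.25),
                         (0.91, 10.88, 0.26, 0.39, 0.61, 0.61, 0.26), "NS"),
    "sixth_leaf_width": ("mm", (4.34, 3.03, 4.33, 2.63, 3.17, 4.16, 4.33),
                         (0.90, 0.72, 0.87, 0.42, 0.69, 0.14, 0.87), "NS"),
    "seventh_leaf_width": ("mm", (5.31, 5.42, 0.93, 0.98, 0.94, 4.02, 0.93),
                           (0.86, 0.92, 0.08, 0.10, 0.08, 0.17, 0.11), "NS"),
    "first_leaf_area": ("mm2", (115.62, 99.29, 96.96, 118.96, 166.62, 253.11, 96.96),
                        (15.13, 23.83, 14.69, 41.85, 37.83, 56.69, 14.69), "*"),
    "second_leaf_area": ("mm2", (225.30, 241.81, 237.80, 250.32, 413.61, 339.22, 237.81),
                         (46.01, 56.29, 18.04, 50.13, 86.04, 85.60, 18.04), "NS"),
    "third_leaf_area": ("mm2", (351.65, 385.22, 397.66, 361.76, 690.66, 482.88, 397.66),
                        (74.75, 91.89, 12.85, 59.46, 142.21, 110.97, 12.85), "NS"),
    "fourth_leaf_area": ("mm2", (604.80, 559.96, 583.40, 492.26, 845.77, 598.48, 583.40),
                         (115.2, 65.80, 24.37, 62.38, 145.52, 86.07, 24.37), "NS"),
    "fifth_leaf_area": ("mm2", (873.96, 613.48, 734.45, 485.48, 495.43, 460.41, 734.46),
                        (151.6, 85.58, 90.82, 118.77, 148.94, 137.46, 90.82), "NS"),
    "sixth_leaf_area": ("mm2", (881.14, 546.32, 743.25, 372.59, 378.47, 790.56, 743.25),
                        (258.6, 269.52, 176.97, 232.86, 214.36, 65.25, 176.97), "NS"),
    "seventh_leaf_area": ("mm2", (811.20, 998.36, 52.21, 65.92, 62.34, 573.51, 52.21),
                          (196.4, 257.31, 8.54, 10.35, 14.68, 55.74, 7.24), "NS"),
    "stem_area": ("mm2", (647.09, 856.64, 650.17, 630.66, 725.42, 726.68, 650.17),
                  (84.22, 60.32, 54.88, 30.95, 85.67, 27.03, 54.88), "NS"),
    "eccentricity": ("", (285.21, 311.64, 234.53, 196.20, 196.91, 169.86, 260.95),
                     (33.9, 24.15, 24.43, 20.69, 15.77, 24.42, 33.49), "**"),
    "convex_hull": ("mm2", (80580.53, 58032.17, 21874.73, 20969.94, 16674.40, 24296.94, 35618.86),
                    (15441.0, 14316.0, 6181.0, 4023.0, 2546.0, 6958.0, 13802.31), "**"),
    "caliper_length": ("mm", (510.05, 457.71, 374.78, 305.70, 327.26, 302.32, 451.99),
                       (66.91, 74.49, 29.91, 35.86, 29.27, 49.05, 58.82), "*"),
    "wpa_s": ("mm2", (4522.00, 3585.16, 3510.24, 2488.48, 3337.50, 3107.58, 3454.15),
              (503.0, 406.04, 406.96, 97.75, 293.75, 74.03, 248.33), "**"),
    "wpa_i": ("mm2", (4068.50, 2215.22, 2032.65, 1109.57, 1456.73, 1744.54, 2483.14),
              (938.0, 580.52, 310.0, 50.02, 150.38, 149.50, 399.20), "**"),
    "top_view_area": ("mm2", (8940.64, 3052.59, 4107.37, 2092.91, 2419.07, 3578.04, 5536.39),
                      (3461.0, 377.0, 1301.0, 421.0, 537.93, 894.76, 1623.0), "**"),
    "compactness": ("", (0.11, 0.05, 0.19, 0.10, 0.15, 0.15, 0.16),
                    (0.08, 0.01, 0.06, 0.06, 0.07, 0.08, 0.07), "**"),
}

_TABLES = {
    "table1": (_TABLE1, 14),
    "table2": (_TABLE2, 28),
    "table3": (_TABLE3, 14),
    "table4": (_TABLE4, 28),
}

#: SHA-256 over the canonical JSON serialization of all four tables;
#: asserted in the test suite to prevent silent edits.
TABLES_SHA256 = "cae2deb6ad75fb7674b6387f5b1905fd18f1c0d13480d9c115cbacd554c98954"


def tables_checksum() -> str:
    """Checksum of the embedded tables in canonical JSON form."""
    payload = json.dumps(
        {name: entry[0] for name, entry in _TABLES.items()}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()


@dataclass(frozen=True)
class PaperFixture:
    """One published table: genotype means, SEs, ANOVA codes, n = 5."""

    name: str
    means: TraitTable
    ses: TraitTable
    anova_codes: dict
    n: int = N_REPLICATES

    @property
    def das(self) -> int:
        return self.means.das


def load_paper_fixture(name: str) -> PaperFixture:
    """Return one embedded table: ``table1`` .. ``table4``."""
    if name not in _TABLES:
        raise ValidationError(
            f"unknown fixture {name!r}; expected one of {sorted(_TABLES)}"
        )
    entry, das = _TABLES[name]
    means = pd.DataFrame(
        {trait: vals[1] for trait, vals in entry.items()}, index=list(GENOTYPES)
    )
    ses = pd.DataFrame(
        {trait: vals[2] for trait, vals in entry.items()}, index=list(GENOTYPES)
    )
    units = {trait: vals[0] for trait, vals in entry.items()}
    codes = {trait: vals[3] for trait, vals in entry.items()}
    return PaperFixture(
        name=name,
        means=TraitTable(data=means, das=das, level=TableLevel.GENOTYPE_MEAN, units=units),
        ses=TraitTable(data=ses, das=das, level=TableLevel.GENOTYPE_MEAN, units=units),
        anova_codes=codes,
    )
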