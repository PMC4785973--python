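"""Reference values from the remodelled-DIOM imaging study.

These printed summary values anchor the synthetic genotype presets and serve
as inputs to worked examples: the control median area/diameter trajectory,
two single-muscle fold-change examples from high-resolution stacks, and the
per-genotype eclosion summary of the screened RNAi cohorts (times in h.min
notation, i.e. 108.22 = 108 h 22 min).
"""

from __future__ import annotations

#: control median DIOM area (μm²) at the trajectory anchors (h aHE)
CONTROL_MEDIAN_AREA = {5: 17925.0, 50: 6038.0, 100: 15719.0}

#: control median DIOM diameter (μm)
CONTROL_MEDIAN_DIAMETER = {5: 84.4, 50: 24.4}

#: single-muscle worked examples: (area before, area after) μm²
AREA_FOLD_EXAMPLES = {
    "control_day1_day2": (8755.0, 3596.0),    # 2.4-fold decline
    "Rheb_shRNA_day1_day2": (14643.0, 2697.0),  # 5.4-fold decline
}

#: eclosion summary rows: genotype -> (n pupae, n eclosed, mean eclosion h.min)
#: mean is None where no pupae of that genotype eclosed during observation
ECLOSION_TABLE = {
    "Chro_control": (8, 4, "108.22"),
    "Rheb": (9, 7, "107.34"),
    "TOR": (8, 2, "106.45"),
    "Tsc1": (4, 2, "108.00"),
    "Tsc2_1": (3, 0, None),
    "Tsc2_2": (10, 10, "106.51"),
    "Atg5": (6, 4, "107.07"),
    "Atg9": (7, 3, "106.20"),
    "Atg12": (6, 1, "104.00"),
    "Atg18": (6, 3, "105.00"),
    "yki": (6, 1, "110.30"),
}

#: printed cohort total of the eclosion summary
ECLOSION_TOTAL = (73, 37, "107.04")


def eclosion_rows():
    """(mean h.min, n eclosed) pairs for the weighted-mean summary."""
    return [(mean, n_ecl) for (_, n_ecl, mean) in ECLOSION_TABLE.values()
            if mean is not None and n_ecl > 0]
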