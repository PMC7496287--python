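"""Built-in reference values of the underlying in vitro proton RBE study.

Four human cell lines spanning high and low photon (α/β)_x ratios were
irradiated with a 200 kV x-ray reference beam and with scanned protons at
six positions inside two 80 mm spread-out Bragg peaks.  The fitted LQ
parameters printed by that study serve three purposes here: as truth values
for the synthetic-assay generator, as inputs for parameters-only analyses
(model predictions without raw colony counts), and as plausibility anchors
in the test-suite.

Values are printed to two decimals in the source tables; uncertainties of
the x-ray fits are carried where available.
"""

from __future__ import annotations

from .types import BeamCondition, LQParameters, Radiation, Setup

#: Dose-averaged LET (keV/µm) at the six proton sample positions, keyed by
#: (setup, depth in mm): proximal, central and distal positions of the two
#: SOBPs (setup A centred at 80 mm, setup B at 155 mm).
LET_BY_POSITION = {
    (Setup.A, 55.0): 2.1,
    (Setup.A, 80.0): 2.8,
    (Setup.A, 105.0): 4.5,
    (Setup.B, 130.0): 1.9,
    (Setup.B, 155.0): 2.5,
    (Setup.B, 180.0): 4.1,
}

#: The six LET_d conditions, ascending (keV/µm).
LET_GRID = (1.9, 2.1, 2.5, 2.8, 4.1, 4.5)

#: Proton beam conditions at the six sample positions, ascending in LET_d.
PROTON_CONDITIONS = tuple(
    sorted(
        (
            BeamCondition(Radiation.PROTON, let_d=let, depth_mm=depth, setup=setup)
            for (setup, depth), let in LET_BY_POSITION.items()
        ),
        key=lambda c: c.let_d,
    )
)

XRAY_CONDITION = BeamCondition(Radiation.XRAY_200KV)

#: Printed (α/β)_x ratios (Gy) used throughout the study's model
#: evaluations; note these are the published rounded ratios, not the
#: quotients of the rounded alpha and beta below.
ALPHA_BETA_X = {"HaCat": 15.0, "FaDu": 10.0, "Du145": 4.7, "SKMel": 3.0}

#: X-ray LQ parameters per cell line (alpha Gy⁻¹, beta Gy⁻²).
XRAY_LQ = {
    "HaCat": LQParameters(alpha=0.30, beta=0.02, se_alpha=0.02, se_beta=0.005),
    "FaDu": LQParameters(alpha=0.30, beta=0.03, se_alpha=0.02, se_beta=0.005),
    "Du145": LQParameters(alpha=0.14, beta=0.03, se_alpha=0.02, se_beta=0.005),
    "SKMel": LQParameters(alpha=0.12, beta=0.04, se_alpha=0.01, se_beta=0.005),
}

#: Proton LQ parameters per cell line and LET_d (keV/µm → (alpha, beta)).
PROTON_LQ = {
    "HaCat": {
        1.9: (0.20, 0.04),
        2.1: (0.25, 0.03),
        2.5: (0.25, 0.03),
        2.8: (0.25, 0.04),
        4.1: (0.22, 0.04),
        4.5: (0.33, 0.02),
    },
    "FaDu": {
        1.9: (0.31, 0.03),
        2.1: (0.25, 0.03),
        2.5: (0.23, 0.04),
        2.8: (0.20, 0.05),
        4.1: (0.29, 0.04),
        4.5: (0.26, 0.04),
    },
    "Du145": {
        1.9: (0.34, 0.02),
        2.1: (0.30, 0.04),
        2.5: (0.31, 0.03),
        2.8: (0.33, 0.03),
        4.1: (0.37, 0.03),
        4.5: (0.39, 0.03),
    },
    "SKMel": {
        1.9: (0.32, 0.04),
        2.1: (0.35, 0.04),
        2.5: (0.29, 0.06),
        2.8: (0.43, 0.03),
        4.1: (0.34, 0.07),
        4.5: (0.42, 0.06),
    },
}

CELL_LINES = tuple(XRAY_LQ)


def proton_lq(cell_line: str, let_d: float) -> LQParameters:
    """Printed proton LQ parameters for a cell line at one LET_d."""
    alpha, beta = PROTON_LQ[cell_line][let_d]
    return LQParameters(alpha=alpha, beta=beta)
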