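"""Core domain types for clonogenic survival analysis and RBE estimation.

All dose quantities are physical doses in Gy, LET values are dose-averaged
linear energy transfer (LET_d) in keV/µm, and LQ parameters carry their
conventional units: alpha in Gy⁻¹, beta in Gy⁻².
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class Radiation(str, enum.Enum):
    """Radiation quality of an irradiation session."""

    XRAY_200KV = "xray_200kV"
    PROTON = "proton"


class RBESource(str, enum.Enum):
    """Provenance of an RBE estimate: experimental fit or a prediction model."""

    EXPERIMENTAL = "experimental"
    MCN = "MCN"
    ROR = "ROR"
    JON = "JON"
    RMF = "RMF"


class ValidationError(ValueError):
    """Raised when a record or table violates a domain invariant."""


@dataclass(frozen=True)
class SurvivalRecord:
    """A single well of a clonogenic assay.

    ``colonies`` is the number of colonies counted after incubation (the
    >50-cell survival criterion is assumed to have been applied when
    counting); ``cells_seeded`` is the number of cells plated in the well.
    """

    cell_line: str
    radiation: Radiation
    dose: float
    cells_seeded: int
    colonies: int
    session: str
    well: str = ""
    let_d: float = 0.0
    depth_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValidationError(f"dose must be >= 0, got {self.dose}")
        if self.cells_seeded <= 0:
            raise ValidationError(
                f"cells_seeded must be positive, got {self.cells_seeded}"
            )
        if self.colonies < 0:
            raise ValidationError(f"colonies must be >= 0, got {self.colonies}")
        if self.colonies > self.cells_seeded:
            raise ValidationError(
                f"colonies ({self.colonies}) exceed cells seeded "
                f"({self.cells_seeded})"
            )
        if self.radiation is Radiation.PROTON and not self.let_d > 0:
            raise ValidationError("proton records must carry let_d > 0")


class Setup(str, enum.Enum):
    """Irradiation geometry label: two SOBP setups plus the x-ray reference."""

    A = "A"
    B = "B"
    REFERENCE = "reference"


#: Sample depths (mm) available in each SOBP setup when the study geometry
#: is emulated: proximal, central and distal positions of an 80 mm SOBP.
SETUP_DEPTHS_MM = {Setup.A: (55.0, 80.0, 105.0), Setup.B: (130.0, 155.0, 180.0)}


@dataclass(frozen=True)
class BeamCondition:
    """Radiation quality plus position-specific LET_d and geometry labels."""

    radiation: Radiation
    let_d: float = 0.0
    depth_mm: Optional[float] = None
    setup: Setup = Setup.REFERENCE

    def __post_init__(self) -> None:
        if self.let_d < 0:
            raise ValidationError(f"let_d must be >= 0, got {self.let_d}")
        if self.setup in SETUP_DEPTHS_MM and self.depth_mm is not None:
            if self.depth_mm not in SETUP_DEPTHS_MM[self.setup]:
                raise ValidationError(
                    f"depth {self.depth_mm} mm not a sample position of "
                    f"setup {self.setup.value}"
                )

    @property
    def key(self) -> tuple:
        return (self.radiation.value, self.let_d)


@dataclass(frozen=True)
class LQParameters:
    """Fitted linear-quadratic parameters with uncertainties.

    The covariance entries come from the curvature of the fit objective;
    ``alpha_over_beta`` and its standard error are delta-method derived.
    """

    alpha: float
    beta: float
    se_alpha: float = 0.0
    se_beta: float = 0.0
    cov_alpha_beta: float = 0.0
    n_points: int = 0
    chi2: float = float("nan")

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValidationError(
                f"alpha and beta must be >= 0, got ({self.alpha}, {self.beta})"
            )
        if self.se_alpha < 0 or self.se_beta < 0:
            raise ValidationError("standard errors must be >= 0")
        # positive semi-definiteness of the 2x2 covariance matrix
        det = (self.se_alpha * self.se_beta) ** 2 - self.cov_alpha_beta**2
        if det < -1e-12 * max(1.0, (self.se_alpha * self.se_beta) ** 2):
            raise ValidationError("covariance matrix not positive semi-definite")

    @property
    def alpha_over_beta(self) -> float:
        if self.beta == 0:
            return math.inf
        return self.alpha / self.beta

    @property
    def covariance(self) -> np.ndarray:
        return np.array(
            [
                [self.se_alpha**2, self.cov_alpha_beta],
                [self.cov_alpha_beta, self.se_beta**2],
            ]
        )

    def survival(self, dose) -> np.ndarray:
        """LQ surviving fraction exp(-αD - βD²)."""
        d = np.asarray(dose, dtype=float)
        return np.exp(-self.alpha * d - self.beta * d * d)


@dataclass(frozen=True)
class SurvivalPoint:
    """Aggregated surviving fraction at one dose level.

    ``norm_rel_var`` is the relative variance of the shared
    plating-efficiency normalization of this point's mean (all wells of a
    session are divided by the same estimated control plating efficiency,
    so this error is common to the whole curve); it feeds the correlated
    part of the fit's parameter covariance.
    """

    dose: float
    sf_mean: float
    sf_sd: float
    n_obs: int
    norm_rel_var: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.sf_mean <= 1.5:
            raise ValidationError(
                f"sf_mean must lie in (0, 1.5], got {self.sf_mean} "
                f"at dose {self.dose}"
            )
        if self.sf_sd < 0:
            raise ValidationError("sf_sd must be >= 0")
        if self.n_obs < 1:
            raise ValidationError("n_obs must be >= 1")


class EndpointKind(str, enum.Enum):
    SURVIVAL_LEVEL = "survival_level"
    PROTON_DOSE = "proton_dose"


@dataclass(frozen=True)
class EndpointSpec:
    """RBE endpoint: either an iso-survival level or a fixed proton dose.

    ``survival_level(0.9)`` is the 90%-survival endpoint (low-dose region),
    ``survival_level(0.1)`` the 10%-survival endpoint; ``proton_dose(2.0)``
    is the RBE at a fixed 2 Gy proton dose.
    """

    kind: EndpointKind
    survival_level: Optional[float] = None
    proton_dose: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind is EndpointKind.SURVIVAL_LEVEL:
            if self.survival_level is None or self.proton_dose is not None:
                raise ValidationError("survival_level endpoint needs only S")
            if not 0 < self.survival_level < 1:
                raise ValidationError(
                    f"survival level must lie strictly in (0, 1), "
                    f"got {self.survival_level}"
                )
        else:
            if self.proton_dose is None or self.survival_level is not None:
                raise ValidationError("proton_dose endpoint needs only Dp")
            if not self.proton_dose > 0:
                raise ValidationError("proton dose must be > 0")

    @classmethod
    def at_survival(cls, level: float) -> "EndpointSpec":
        return cls(EndpointKind.SURVIVAL_LEVEL, survival_level=level)

    @classmethod
    def at_dose(cls, dose: float) -> "EndpointSpec":
        return cls(EndpointKind.PROTON_DOSE, proton_dose=dose)

    @property
    def label(self) -> str:
        if self.kind is EndpointKind.SURVIVAL_LEVEL:
            return f"RBE_{round(self.survival_level * 100)}"
        return f"RBE_{self.proton_dose:g}Gy"


@dataclass(frozen=True)
class RBEEstimate:
    """An RBE value with its propagated standard error."""

    value: float
    se: float
    endpoint: EndpointSpec
    condition: BeamCondition
    source: RBESource
    cell_line: str = ""

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValidationError(f"RBE must be > 0, got {self.value}")
        if self.se < 0:
            raise ValidationError("se must be >= 0")


@dataclass(frozen=True)
class MaxMinPair:
    """Asymptotic RBE limits of a phenomenological model.

    ``rbe_max`` is the RBE in the vanishing-dose limit (α_p/α_x) and
    ``rbe_min`` the RBE in the high-dose limit (sqrt(β_p/β_x)).
    """

    rbe_max: float
    rbe_min: float
    model: RBESource

    def __post_init__(self) -> None:
        if not self.rbe_min > 0:
            raise ValidationError("rbe_min must be > 0")
        if not np.isfinite(self.rbe_max):
            raise ValidationError("rbe_max must be finite")


@dataclass(frozen=True)
class RMFInputs:
    """Inputs of the repair-misrepair-fixation LQ conversion.

    ``rbe_dsb`` is the RBE for double-strand-break induction at the beam
    condition (an external input, e.g. from a Monte Carlo damage
    simulation); ``nucleus_diameter`` (µm) sets the frequency-mean specific
    energy unless ``zbar_f`` is overridden directly.
    """

    rbe_dsb: float
    nucleus_diameter: float = 5.0
    zbar_f: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.rbe_dsb) or self.rbe_dsb < 0:
            raise ValidationError("rbe_dsb must be finite and >= 0")
        if not self.nucleus_diameter > 0:
            raise ValidationError("nucleus_diameter must be > 0")


@dataclass(frozen=True)
class RegressionResult:
    """Linear LET_d–RBE regression summary with the slope F-test."""

    slope: float
    intercept: float
    f_stat: float
    p_value: float
    n: int
    endpoint: EndpointSpec
    cell_line: str = ""
    se_slope: float = float("nan")

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValidationError("regression needs at least 3 points")
        if not 0 < self.p_value <= 1:
            raise ValidationError("p_value must lie in (0, 1]")
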