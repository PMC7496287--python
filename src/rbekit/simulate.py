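"""Synthetic clonogenic-assay generator.

Emulates the study design end to end: 6-well plates seeded dose-
dependently (250 cells for 0/0.5 Gy, 500 for 1/2 Gy, 1000 for 4 Gy, 2000
for 6 Gy), at least three independent irradiation sessions, and colony
counts that are Poisson around cells_seeded · PE_session · S(D) with
S(D) = exp(−αD − βD²).  The session plating efficiency fluctuates
lognormally around the cell line's nominal plating efficiency, which
makes the per-session control normalisation meaningful.  Counts are
truncated at the number of seeded cells.

The built-in archetypes carry the published LQ truth values of the four
study cell lines, so end-to-end recovery tests have known ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import study
from .types import BeamCondition, LQParameters, Radiation, SurvivalRecord

log = logging.getLogger(__name__)

DEFAULT_DOSES = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0)
DEFAULT_SEEDING = {0.0: 250, 0.5: 250, 1.0: 500, 2.0: 500, 4.0: 1000, 6.0: 2000}


@dataclass(frozen=True)
class AssayDesign:
    """Plate layout and replication structure of one simulated assay."""

    dose_levels: tuple = DEFAULT_DOSES
    seeding: dict = field(default_factory=lambda: dict(DEFAULT_SEEDING))
    wells_per_plate: int = 6
    sessions: int = 3
    plating_efficiency: float = 0.3
    sigma_session: float = 0.1

    def __post_init__(self) -> None:
        if self.sessions < 1:
            raise ValueError("sessions must be >= 1")
        if not 0 < self.plating_efficiency < 1:
            raise ValueError("plating_efficiency must lie in (0, 1)")
        if any(self.seeding.get(d, 0) <= 0 for d in self.dose_levels):
            raise ValueError("every dose level needs a positive seeding density")


@dataclass(frozen=True)
class TissueArchetype:
    """LQ truth values of one cell line for x-rays and per-LET_d protons."""

    name: str
    alpha_x: float
    beta_x: float
    proton_lq: dict  # let_d -> (alpha, beta)
    plating_efficiency: float = 0.3

    def __post_init__(self) -> None:
        if self.alpha_x < 0 or self.beta_x < 0:
            raise ValueError("LQ rates must be >= 0")
        for let, (a, b) in self.proton_lq.items():
            if a < 0 or b < 0:
                raise ValueError(f"LQ rates must be >= 0 (LET_d {let})")

    @property
    def let_grid(self) -> tuple:
        return tuple(sorted(self.proton_lq))

    def lq_for(self, condition: BeamCondition) -> LQParameters:
        if condition.radiation is Radiation.XRAY_200KV:
            return LQParameters(alpha=self.alpha_x, beta=self.beta_x)
        try:
            a, b = self.proton_lq[condition.let_d]
        except KeyError:
            raise KeyError(
                f"{self.name}: no proton LQ truth at LET_d {condition.let_d}"
            ) from None
        return LQParameters(alpha=a, beta=b)


def study_archetypes(plating_efficiency: float = 0.3) -> dict[str, TissueArchetype]:
    """The four study cell lines with their published LQ parameters as truth."""
    return {
        name: TissueArchetype(
            name=name,
            alpha_x=study.XRAY_LQ[name].alpha,
            beta_x=study.XRAY_LQ[name].beta,
            proton_lq=dict(study.PROTON_LQ[name]),
            plating_efficiency=plating_efficiency,
        )
        for name in study.CELL_LINES
    }


def simulate_assay(
    design: AssayDesign,
    archetype: TissueArchetype,
    condition: BeamCondition,
    rng: np.random.Generator | int | None = None,
) -> list[SurvivalRecord]:
    """Simulate one cell line × beam condition clonogenic assay.

    Each session draws one plating efficiency PE·exp(N(0, σ_session)) and
    then, per dose and well, a Poisson colony count with mean
    cells_seeded · PE_session · S(D), truncated at cells_seeded.
    """
    rng = np.random.default_rng(rng)
    lq = archetype.lq_for(condition)
    pe = archetype.plating_efficiency or design.plating_efficiency
    records = []
    for s in range(1, design.sessions + 1):
        pe_session = pe * np.exp(rng.normal(0.0, design.sigma_session))
        for dose in design.dose_levels:
            seeded = design.seeding[dose]
            sf = float(lq.survival(dose))
            mean = seeded * pe_session * sf
            if mean > seeded:
                log.warning(
                    "expected colonies (%.1f) exceed seeded cells (%d); "
                    "counts will truncate",
                    mean,
                    seeded,
                )
            counts = np.minimum(
                rng.poisson(mean, size=design.wells_per_plate), seeded
            )
            for w, c in enumerate(counts, start=1):
                records.append(
                    SurvivalRecord(
                        cell_line=archetype.name,
                        radiation=condition.radiation,
                        let_d=condition.let_d,
                        depth_mm=condition.depth_mm,
                        dose=dose,
                        cells_seeded=seeded,
                        colonies=int(c),
                        session=f"S{s}",
                        well=f"W{w}",
                    )
                )
    return records


def simulate_study(
    design: AssayDesign | None = None,
    archetypes: dict[str, TissueArchetype] | None = None,
    seed: int | None = None,
) -> list[SurvivalRecord]:
    """Simulate the full study: every archetype under x-rays plus all
    proton conditions of its LET grid, in a deterministic order."""
    design = design or AssayDesign()
    archetypes = archetypes or study_archetypes()
    rng = np.random.default_rng(seed)
    records = []
    for name in sorted(archetypes):
        arch = archetypes[name]
        conditions = [study.XRAY_CONDITION] + [
            c for c in study.PROTON_CONDITIONS if c.let_d in arch.let_grid
        ]
        for cond in conditions:
            records.extend(simulate_assay(design, arch, cond, rng))
    return records


def make_study_fixture(
    seed: int,
    out_dir: str | Path,
    design: AssayDesign | None = None,
) -> list[Path]:
    """Write per-cell-line CSV fixtures for the full simulated study.

    Deterministic for a fixed seed (byte-identical on rerun).  Returns
    the written paths.
    """
    from .io import write_survival_table  # local import to avoid a cycle

    design = design or AssayDesign()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = simulate_study(design, seed=seed)
    paths = []
    by_cell: dict[str, list[SurvivalRecord]] = {}
    for r in records:
        by_cell.setdefault(r.cell_line, []).append(r)
    for cell in sorted(by_cell):
        path = out_dir / f"survival_{cell}.csv"
        write_survival_table(by_cell[cell], path)
        paths.append(path)
    return paths
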