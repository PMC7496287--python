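"""Full analysis orchestration: fit → experimental RBE → model predictions
→ LET_d regression → tidy tables and a machine-readable run manifest.

Two entry modes cover the two realistic data situations:

* raw mode — colony-count CSVs (or the built-in simulator) are normalised
  to surviving fractions and fitted per condition before RBE derivation;
* parameters-only mode — a printed-table style CSV of LQ parameters is
  consumed directly, so published tables can be reproduced without raw
  counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, association, endpoints, io, lq, models, simulate
from .types import (
    BeamCondition,
    EndpointKind,
    EndpointSpec,
    LQParameters,
    Radiation,
    RBESource,
    RMFInputs,
    ValidationError,
)

log = logging.getLogger(__name__)

DEFAULT_ENDPOINTS = (
    EndpointSpec.at_survival(0.9),
    EndpointSpec.at_survival(0.1),
    EndpointSpec.at_dose(0.5),
    EndpointSpec.at_dose(2.0),
    EndpointSpec.at_dose(6.0),
)
DEFAULT_MODELS = (RBESource.MCN, RBESource.ROR, RBESource.JON, RBESource.RMF)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source must be set: ``inputs`` (raw survival CSVs),
    ``lq_table`` (parameters-only CSV) or ``simulate=True`` (built-in
    generator with ``seed``).  ``rbe_dsb`` maps LET_d to the
    double-strand-break induction RBE required by the RMF model; without
    it the RMF column is skipped with a warning.
    """

    inputs: tuple = ()
    lq_table: str | None = None
    simulate: bool = False
    seed: int = 0
    endpoints: tuple = DEFAULT_ENDPOINTS
    models: tuple = DEFAULT_MODELS
    rbe_dsb: dict = field(default_factory=dict)
    nucleus_diameter: float = 5.0
    reference_quality_factor: float = 1.0
    strict: bool = False
    weighted_regression: bool = False
    absolute_sigma: bool = False
    out_dir: str = "rbekit_out"

    def __post_init__(self) -> None:
        n_sources = bool(self.inputs) + bool(self.lq_table) + bool(self.simulate)
        if n_sources != 1:
            raise ValidationError(
                "exactly one input source required: inputs, lq_table or simulate"
            )
        if not self.endpoints:
            raise ValidationError("at least one endpoint required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "endpoints" in kwargs:
            kwargs["endpoints"] = tuple(
                _parse_endpoint(e) for e in kwargs["endpoints"]
            )
        if "models" in kwargs:
            kwargs["models"] = tuple(RBESource(m) for m in kwargs["models"])
        if "inputs" in kwargs:
            kwargs["inputs"] = tuple(kwargs["inputs"])
        if "rbe_dsb" in kwargs and kwargs["rbe_dsb"]:
            kwargs["rbe_dsb"] = {
                float(k): float(v) for k, v in dict(kwargs["rbe_dsb"]).items()
            }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


def _parse_endpoint(spec) -> EndpointSpec:
    """Parse 'S=0.9' / 'Dp=2' strings or {survival_level:}/{proton_dose:} maps."""
    if isinstance(spec, EndpointSpec):
        return spec
    if isinstance(spec, dict):
        if "survival_level" in spec:
            return EndpointSpec.at_survival(float(spec["survival_level"]))
        if "proton_dose" in spec:
            return EndpointSpec.at_dose(float(spec["proton_dose"]))
        raise ValidationError(f"cannot parse endpoint {spec!r}")
    text = str(spec).strip()
    key, _, value = text.partition("=")
    key = key.strip().lower()
    if key == "s":
        return EndpointSpec.at_survival(float(value))
    if key == "dp":
        return EndpointSpec.at_dose(float(value))
    raise ValidationError(f"cannot parse endpoint {text!r} (use 'S=0.9' or 'Dp=2')")


def _lq_from_row(row) -> LQParameters:
    return LQParameters(
        alpha=float(row["alpha"]),
        beta=float(row["beta"]),
        se_alpha=float(row.get("se_alpha", 0.0) or 0.0)
        if not pd.isna(row.get("se_alpha", 0.0))
        else 0.0,
        se_beta=float(row.get("se_beta", 0.0) or 0.0)
        if not pd.isna(row.get("se_beta", 0.0))
        else 0.0,
        cov_alpha_beta=float(row.get("cov_alpha_beta", 0.0) or 0.0)
        if not pd.isna(row.get("cov_alpha_beta", 0.0))
        else 0.0,
    )


def _load_lq_frame(config: RunConfig) -> pd.DataFrame:
    """Stage 1: obtain the per-condition LQ parameter table."""
    if config.lq_table:
        return io.read_lq_table(config.lq_table)
    if config.simulate:
        records = simulate.simulate_study(seed=config.seed)
    else:
        records = []
        for path in config.inputs:
            records.extend(io.read_survival_table(path, strict=config.strict))
    sf = lq.compute_surviving_fractions(records)
    return lq.fit_conditions(sf, absolute_sigma=config.absolute_sigma)


def _experimental_estimates(lq_frame: pd.DataFrame, config: RunConfig) -> list:
    ests = []
    for cell, group in lq_frame.groupby("cell_line"):
        xrows = group[group["radiation"] == Radiation.XRAY_200KV.value]
        if xrows.empty:
            log.warning("%s: no x-ray reference fit; skipping RBE", cell)
            continue
        lq_x = _lq_from_row(xrows.iloc[0])
        for _, row in group[group["radiation"] == Radiation.PROTON.value].iterrows():
            lq_p = _lq_from_row(row)
            cond = BeamCondition(Radiation.PROTON, let_d=float(row["let_d"]))
            for ep in config.endpoints:
                try:
                    ests.append(
                        endpoints.rbe_at_endpoint(lq_x, lq_p, ep, cond, cell)
                    )
                except ValidationError as exc:
                    log.warning("%s %s: %s", cell, ep.label, exc)
    return ests


def _model_estimates(lq_frame: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Model predictions at the fixed-dose endpoints for every condition."""
    doses = [
        ep.proton_dose
        for ep in config.endpoints
        if ep.kind is EndpointKind.PROTON_DOSE
    ]
    rows = []
    for cell, group in lq_frame.groupby("cell_line"):
        xrows = group[group["radiation"] == Radiation.XRAY_200KV.value]
        if xrows.empty:
            continue
        xrow = xrows.iloc[0]
        lq_x = _lq_from_row(xrow)
        ab = float(xrow.get("alpha_over_beta", np.nan))
        if np.isnan(ab):
            ab = lq_x.alpha_over_beta
        for _, row in group[group["radiation"] == Radiation.PROTON.value].iterrows():
            let = float(row["let_d"])
            for dp in doses:
                for model in config.models:
                    if model is RBESource.EXPERIMENTAL:
                        continue
                    if model is RBESource.RMF:
                        if let not in config.rbe_dsb:
                            continue
                        rmf = RMFInputs(
                            rbe_dsb=config.rbe_dsb[let],
                            nucleus_diameter=config.nucleus_diameter,
                        )
                        value = models.predict_rmf(dp, lq_x, rmf, let, ab)
                        se = float("nan")  # RBE_DSB carries no stated error
                    else:
                        value = config.reference_quality_factor * models.predict_pheno(
                            model,
                            dp,
                            let,
                            alpha_x=lq_x.alpha,
                            beta_x=lq_x.beta,
                            alpha_over_beta_x=ab,
                        )
                        se = models.pheno_prediction_se(model, dp, let, lq_x, ab)
                    rows.append(
                        dict(
                            cell_line=cell,
                            let_d=let,
                            source=model.value,
                            endpoint=f"RBE_{dp:g}Gy",
                            value=value,
                            se=se,
                        )
                    )
    if (
        RBESource.RMF in config.models
        and not config.rbe_dsb
        and not lq_frame[lq_frame["radiation"] == Radiation.PROTON.value].empty
    ):
        log.warning("RMF requested but no rbe_dsb mapping configured; skipped")
    return pd.DataFrame(rows)


def estimates_to_frame(ests) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                cell_line=e.cell_line,
                let_d=e.condition.let_d,
                source=e.source.value,
                endpoint=e.endpoint.label,
                value=e.value,
                se=e.se,
            )
            for e in ests
        ]
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write the result bundle to ``config.out_dir``.

    Returns a dict with the in-memory tables: ``lq`` (per-condition fit
    parameters), ``rbe`` (experimental and model estimates), ``regression``
    and the ``manifest``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    lq_frame = _load_lq_frame(config)
    ests = _experimental_estimates(lq_frame, config)
    exp_frame = estimates_to_frame(ests)
    model_frame = _model_estimates(lq_frame, config)
    rbe_frame = pd.concat([exp_frame, model_frame], ignore_index=True)
    if rbe_frame.empty:
        raise ValidationError("no RBE estimates produced (check inputs)")
    rbe_frame = rbe_frame.sort_values(
        ["cell_line", "endpoint", "source", "let_d"]
    ).reset_index(drop=True)

    reg_rows = []
    for source, res in association.regress_groups(
        ests, weighted=config.weighted_regression
    ):
        reg_rows.append(
            dict(
                cell_line=res.cell_line,
                endpoint=res.endpoint.label,
                source=source.value,
                slope=res.slope,
                se_slope=res.se_slope,
                intercept=res.intercept,
                f_stat=res.f_stat,
                p_value=res.p_value,
                n=res.n,
            )
        )
    reg_frame = pd.DataFrame(reg_rows)

    manifest = {
        "rbekit_version": __version__,
        "seed": config.seed,
        "coefficients_version": models.load_coefficients()["version"],
        "coefficients_sha256": models.coefficients_hash(),
        "config": _config_echo(config),
    }

    io.write_results(lq_frame, out / "lq_parameters.csv")
    io.write_results(rbe_frame, out / "rbe_estimates.csv")
    if not reg_frame.empty:
        io.write_results(reg_frame, out / "regression.csv")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info(
        "pipeline complete: %d LQ fits, %d RBE rows, %d regressions -> %s",
        len(lq_frame),
        len(rbe_frame),
        len(reg_frame),
        out,
    )
    return {
        "lq": lq_frame,
        "rbe": rbe_frame,
        "regression": reg_frame,
        "manifest": manifest,
    }


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    echo["endpoints"] = [ep.label for ep in config.endpoints]
    echo["models"] = [m.value for m in config.models]
    echo["inputs"] = [str(p) for p in config.inputs]
    echo["rbe_dsb"] = {str(k): v for k, v in config.rbe_dsb.items()}
    # the output location does not influence any computed value
    echo.pop("out_dir", None)
    return echo
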