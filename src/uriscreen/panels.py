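"""Synthetic clone-level lysate panels.

A screening campaign picks clones of a transformed host, induces
expression, lyses, and measures each lysate's total protein P (Bradford),
activity concentration AC, and specific activity SA = AC / P.  Expression
level and lysis efficiency vary clone to clone, so P varies even for a
fixed construct, and AC inherits that variation on top of the mutant's
intrinsic catalytic capacity.

The generator encodes that causal story: SA and P are drawn independently
from per-candidate marginals and AC = SA * P.  The product structure
induces the positive AC-protein correlation observed in real panels; its
delta-method prediction is

    r(AC, P) = mu_sa * sd_p / sqrt(mu_sa^2 sd_p^2 + mu_p^2 sd_sa^2 + sd_sa^2 sd_p^2)

The package ships the four-candidate summary table (A-D, n = 30) used as
the screening fixture throughout.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError

__all__ = [
    "CandidateModel",
    "ClonePanel",
    "generate_panel",
    "models_from_summary",
    "load_table1",
    "table1_models",
    "predicted_ac_protein_corr",
]

FAMILIES = ("gaussian", "lognormal")


@dataclass(frozen=True)
class CandidateModel:
    """Marginal distributions of one candidate's specific activity and
    total protein (means/SDs in U/mg and mg/mL)."""

    name: str
    mu_sa: float
    sd_sa: float
    mu_p: float
    sd_p: float
    family: str = "gaussian"
    truncate_at_zero: bool = True

    def __post_init__(self):
        if self.mu_sa <= 0 or self.mu_p <= 0:
            raise DomainError("means must be positive")
        if self.sd_sa < 0 or self.sd_p < 0:
            raise DomainError("SDs must be nonnegative")
        if self.family not in FAMILIES:
            raise DomainError(f"family must be one of {FAMILIES}")


@dataclass(frozen=True)
class ClonePanel:
    """One candidate's simulated screening panel (arrays of length n)."""

    candidate: str
    n: int
    protein_mg_per_mL: np.ndarray
    ac_U_per_mL: np.ndarray
    sa_U_per_mg: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        for arr in (self.protein_mg_per_mL, self.ac_U_per_mL, self.sa_U_per_mg):
            if np.asarray(arr).shape != (self.n,):
                raise DomainError("panel arrays must have length n")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "candidate": self.candidate,
                "clone_id": np.arange(1, self.n + 1),
                "protein_mg_per_mL": self.protein_mg_per_mL,
                "ac_U_per_mL": self.ac_U_per_mL,
                "sa_U_per_mg": self.sa_U_per_mg,
            }
        )


def _lognormal_params(mu: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu_log, sigma_log) for a lognormal with given mean/SD."""
    sigma2 = math.log1p((sd / mu) ** 2)
    return math.log(mu) - 0.5 * sigma2, math.sqrt(sigma2)


def _draw_marginal(
    rng: np.random.Generator, mu: float, sd: float, n: int, family: str, truncate: bool
) -> np.ndarray:
    if sd == 0:
        return np.full(n, mu)
    if family == "lognormal":
        mu_log, sigma_log = _lognormal_params(mu, sd)
        return rng.lognormal(mu_log, sigma_log, n)
    x = rng.normal(mu, sd, n)
    if truncate:
        # resample rather than clip so the positive-part moments stay close
        bad = x <= 0
        while np.any(bad):
            x[bad] = rng.normal(mu, sd, int(bad.sum()))
            bad = x <= 0
    return x


def generate_panel(
    model: CandidateModel,
    n: int = 30,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ClonePanel:
    """Draw a clone panel: SA and P independent, AC = SA * P.

    Reproducible under ``seed`` (PCG64 generator); pass ``rng`` instead to
    draw from an existing stream.
    """
    if n < 2:
        raise DomainError("panel needs at least 2 clones")
    if model.family == "gaussian":
        for label, mu, sd in (("sd_sa", model.mu_sa, model.sd_sa),
                              ("sd_p", model.mu_p, model.sd_p)):
            if mu > 0 and sd / mu > 0.5:
                warnings.warn(
                    f"{model.name}: {label}/mean > 0.5 with gaussian family; "
                    "zero-truncation will distort the moments",
                    stacklevel=2,
                )
    if rng is None:
        rng = np.random.default_rng(seed)
    sa = _draw_marginal(rng, model.mu_sa, model.sd_sa, n, model.family, model.truncate_at_zero)
    protein = _draw_marginal(rng, model.mu_p, model.sd_p, n, model.family, model.truncate_at_zero)
    return ClonePanel(
        candidate=model.name,
        n=n,
        protein_mg_per_mL=protein,
        ac_U_per_mL=sa * protein,
        sa_U_per_mg=sa,
        seed=seed,
    )


def predicted_ac_protein_corr(model: CandidateModel) -> float:
    """Delta-method Pearson r(AC, P) for the independent-product model."""
    num = model.mu_sa * model.sd_p
    den = math.sqrt(
        (model.mu_sa * model.sd_p) ** 2
        + (model.mu_p * model.sd_sa) ** 2
        + (model.sd_sa * model.sd_p) ** 2
    )
    return num / den


def models_from_summary(
    summary: Mapping[str, Mapping[str, object]],
    family: str = "gaussian",
) -> list[CandidateModel]:
    """Build candidate models from a summary table.

    ``summary`` maps candidate name -> {"specific_activity": [mean, sd],
    "protein": [mean, sd], ...}; extra keys are ignored.
    """
    if not summary:
        raise SchemaError("empty summary table")
    models = []
    for name, row in summary.items():
        for field in ("specific_activity", "protein"):
            if field not in row:
                raise SchemaError(f"candidate {name!r}: missing field {field!r}")
            pair = row[field]
            if len(pair) != 2:
                raise SchemaError(f"candidate {name!r}: field {field!r} must be [mean, sd]")
        mu_sa, sd_sa = (float(x) for x in row["specific_activity"])
        mu_p, sd_p = (float(x) for x in row["protein"])
        models.append(CandidateModel(name, mu_sa, sd_sa, mu_p, sd_p, family=family))
    return models


def load_table1() -> dict:
    """The built-in four-candidate screening fixture (parsed JSON)."""
    with resources.files("uriscreen.data").joinpath("table1_candidates.json").open() as fh:
        return json.load(fh)


def table1_models(family: str = "gaussian") -> list[CandidateModel]:
    """Candidate models A-D from the built-in fixture."""
    return models_from_summary(load_table1()["candidates"], family=family)
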