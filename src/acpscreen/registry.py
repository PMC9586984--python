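"""Per-stratum probit models with eligibility/exclusion rules.

The cohort is partitioned by a chosen set of risk factors, one probit model
of outcome on AIS score is fitted per subgroup, and each subgroup gets a
status:

    fitted                 model converged and the AIS slope is significant
    no_variation           no positives (or no negatives), or subgroup too
                           small to attempt a fit
    fit_failed             optimizer did not converge (e.g. separation)
    slope_not_significant  converged but slope p-value > alpha

Only ``fitted`` strata carry ACP cutoffs and enter screening evaluation and
the spectrum.  Reference models (the with/without-MD pair, codes "1xxxxx"
and "0xxxxx") are fitted on their own complete-case populations and can be
appended for display alongside any registry.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import probit
from .cohort import assign_stratum_codes, validate_stratum_code
from .errors import AcpScreenError, IdentifiabilityError, NoVariationError
from .probit import ProbitFit, fit_probit

__all__ = [
    "StratumModel",
    "ModelRegistry",
    "stratify",
    "fit_stratified",
    "fit_reference_models",
    "registry_report",
    "STATUS_FITTED",
    "STATUS_NO_VARIATION",
    "STATUS_FIT_FAILED",
    "STATUS_NOT_SIGNIFICANT",
]

STATUS_FITTED = "fitted"
STATUS_NO_VARIATION = "no_variation"
STATUS_FIT_FAILED = "fit_failed"
STATUS_NOT_SIGNIFICANT = "slope_not_significant"


@dataclass
class StratumModel:
    """One subgroup: its members' scores/outcomes, fit (if any) and status."""

    code: str
    n: int
    n_pos: int
    status: str
    fit: ProbitFit | None
    ais: np.ndarray
    y: np.ndarray

    @property
    def is_fitted(self) -> bool:
        return self.status == STATUS_FITTED

    def acp(self, level: float) -> probit.ACP:
        if self.fit is None:
            raise AcpScreenError(f"stratum {self.code} has no fit")
        return probit.acp(self.fit, level)


class ModelRegistry:
    """Mapping stratum code -> :class:`StratumModel`, plus reference models."""

    def __init__(self, active_positions, alpha: float, min_positives: int):
        self.active_positions = tuple(sorted(active_positions))
        self.alpha = alpha
        self.min_positives = min_positives
        self.models: dict[str, StratumModel] = {}
        self.reference: dict[str, StratumModel] = {}

    def __getitem__(self, code: str) -> StratumModel:
        return self.models[code]

    def __iter__(self):
        return iter(self.models.values())

    def __len__(self) -> int:
        return len(self.models)

    def add_reference(self, model: StratumModel) -> None:
        self.reference[model.code] = model

    def fitted_models(self, include_reference: bool = False) -> list[StratumModel]:
        out = [m for m in self.models.values() if m.is_fitted]
        if include_reference:
            out += [m for m in self.reference.values() if m.is_fitted]
        return out

    def n_total(self) -> int:
        return sum(m.n for m in self.models.values())


def stratify(
    cohort: pd.DataFrame, active_positions: Iterable[int]
) -> dict[str, pd.DataFrame]:
    """Partition a complete-case cohort into 2^k subgroups.

    Every code over the active positions is enumerated (inactive positions
    'x'), so empty subgroups appear with zero rows; sizes sum to the input n.
    """
    active = sorted(set(active_positions))
    if not active:
        raise ValueError("active_positions is empty")
    codes = assign_stratum_codes(cohort, active)
    strata: dict[str, pd.DataFrame] = {}
    for bits in itertools.product("01", repeat=len(active)):
        chars = ["x"] * 6
        for pos, bit in zip(active, bits):
            chars[pos - 1] = bit
        code = "".join(chars)
        strata[code] = cohort.loc[codes == code]
    return strata


def _build_model(code: str, sub: pd.DataFrame, alpha: float, min_positives: int) -> StratumModel:
    ais = sub["ais"].to_numpy(dtype=float)
    y = sub["cesd_positive"].to_numpy(dtype=float)
    n = int(len(sub))
    n_pos = int(np.nansum(y))
    if n < min_positives or n_pos == 0 or n_pos == n:
        return StratumModel(code, n, n_pos, STATUS_NO_VARIATION, None, ais, y)
    try:
        fit = fit_probit(ais, y)
    except (NoVariationError, IdentifiabilityError):
        return StratumModel(code, n, n_pos, STATUS_NO_VARIATION, None, ais, y)
    if not fit.converged or not fit.inference_available:
        return StratumModel(code, n, n_pos, STATUS_FIT_FAILED, fit, ais, y)
    if fit.p1 > alpha:
        return StratumModel(code, n, n_pos, STATUS_NOT_SIGNIFICANT, fit, ais, y)
    return StratumModel(code, n, n_pos, STATUS_FITTED, fit, ais, y)


def fit_stratified(
    strata: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
    min_positives: int = 5,
    active_positions: Iterable[int] | None = None,
) -> ModelRegistry:
    """Fit one probit model per subgroup and classify it.

    The exclusion rule follows the screening method's practice: a model whose
    AIS-slope p-value exceeds ``alpha`` is kept in the registry but not used
    for cutoffs (the intercept's p-value is ignored — without a slope the
    model cannot produce a cutoff).  ``min_positives`` guards against tiny
    subgroups that cannot support a stable fit.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    if active_positions is None:
        example = next(iter(strata))
        active_positions = [i + 1 for i, c in enumerate(example) if c != "x"]
    registry = ModelRegistry(active_positions, alpha, min_positives)
    for code in sorted(strata):
        validate_stratum_code(code)
        registry.models[code] = _build_model(code, strata[code], alpha, min_positives)
    return registry


def fit_reference_models(
    cohort: pd.DataFrame, alpha: float = 0.05, min_positives: int = 5
) -> list[StratumModel]:
    """Fit the with/without-MD reference pair on its own complete cases."""
    needed = ["ais", "cesd_positive", "md_history"]
    cc = cohort.dropna(subset=[c for c in needed if c in cohort.columns])
    models = []
    for code, md_value in (("0xxxxx", 0.0), ("1xxxxx", 1.0)):
        sub = cc.loc[cc["md_history"] == md_value]
        models.append(_build_model(code, sub, alpha, min_positives))
    return models


def registry_report(registry: ModelRegistry, include_reference: bool = True) -> pd.DataFrame:
    """One row per stratum code: counts, status, coefficients, ACP50/ACP75.

    Excluded models carry NaN in the coefficient/ACP columns.  Deterministic
    for a fixed cohort and configuration (codes in sorted order, references
    appended last).
    """
    rows = []
    models = list(registry.models.values())
    if include_reference:
        models += list(registry.reference.values())
    for m in models:
        row = {
            "code": m.code,
            "n": m.n,
            "n_pos": m.n_pos,
            "status": m.status,
            "beta0": np.nan, "beta1": np.nan,
            "se0": np.nan, "se1": np.nan,
            "p0": np.nan, "p1": np.nan,
            "ci0_low": np.nan, "ci0_high": np.nan,
            "ci1_low": np.nan, "ci1_high": np.nan,
            "acp50": np.nan, "acp75": np.nan,
        }
        if m.fit is not None and m.fit.converged:
            f = m.fit
            row.update(
                beta0=f.beta0, beta1=f.beta1, se0=f.se0, se1=f.se1,
                p0=f.p0, p1=f.p1,
                ci0_low=f.ci0[0], ci0_high=f.ci0[1],
                ci1_low=f.ci1[0], ci1_high=f.ci1[1],
            )
        if m.is_fitted:
            row["acp50"] = m.acp(0.50).ais_value
            row["acp75"] = m.acp(0.75).ais_value
        rows.append(row)
    return pd.DataFrame(rows)
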