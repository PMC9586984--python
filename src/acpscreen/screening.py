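"""Screening-policy evaluation: count tables, PPV, detection, tuning.

A screening policy assigns each stratum an AIS cutoff — either one fixed
value for everybody (e.g. the conventional insomnia cutoff of 6) or the
per-stratum ACP at a common prevalence level q.  A record is screened
("above") iff its integer AIS score is >= the cutoff, so a fractional
cutoff like 8.8 sends scores >= 9 above.  Pooling the above cells across
strata gives the number screened, the number of true (CES-D) positives
detected, and the PPV of the policy, which here coincides with the observed
prevalence of the pooled above category.

The evaluation population is the members of strata with *fitted* models
only; strata excluded by the eligibility rules contribute neither to the
numerator nor the denominator of any policy metric.

``load_counts`` exposes bundled subgroup count tables transcribed from the
published community-cohort screening study (an 8440-person Japanese cohort
screened with CES-D and AIS), so all of its printed prevalence/PPV
arithmetic can be reproduced exactly without the restricted person-level
data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import ndtri

from ._round import percent_half_up, round_half_up
from .errors import NoModelsError, NonInvertibleError, UndefinedFractionError
from .registry import ModelRegistry

__all__ = [
    "Cell",
    "ScreeningResult",
    "PolicyComparison",
    "apply_cutoff",
    "evaluate_policy",
    "result_from_counts",
    "compare_policies",
    "tune_prevalence_level",
    "load_counts",
    "prevalence_3dp",
]

_DATA_FILES = {
    "md_stratified": "counts_md_stratified.tsv",
    "acp_policies": "counts_acp_policies.tsv",
    "sleep_cutoff": "counts_sleep_cutoff.tsv",
}


@dataclass(frozen=True)
class Cell:
    """One below- or above-cutoff category: size and positives."""

    n: int
    n_pos: int

    def __post_init__(self):
        if not 0 <= self.n_pos <= self.n:
            raise ValueError(f"invalid cell n={self.n}, n_pos={self.n_pos}")

    @property
    def prevalence(self) -> float:
        return self.n_pos / self.n if self.n else np.nan


@dataclass(frozen=True)
class ScreeningResult:
    """Pooled outcome of one policy on one evaluation population."""

    counts: pd.DataFrame  # columns: stratum, cutoff, category, n, n_pos
    screened: int         # pooled above n
    detected: int         # pooled above n_pos
    total_n: int
    total_pos: int

    @property
    def ppv_above(self) -> float:
        """Prevalence of the pooled above category = detected/screened."""
        return self.detected / self.screened if self.screened else np.nan

    @property
    def below(self) -> Cell:
        return Cell(self.total_n - self.screened, self.total_pos - self.detected)

    @property
    def above(self) -> Cell:
        return Cell(self.screened, self.detected)


@dataclass(frozen=True)
class PolicyComparison:
    """A policy against a reference on the same population."""

    detected_fraction: float
    screened_fraction: float
    detected_pct: float   # rounded half-up, 1 decimal
    screened_pct: float


def apply_cutoff(ais, y, cutoff: float) -> tuple[Cell, Cell]:
    """Split records at an AIS cutoff: above iff ais >= cutoff."""
    ais = np.asarray(ais, dtype=float)
    y = np.asarray(y, dtype=float)
    above = ais >= cutoff
    below_cell = Cell(int((~above).sum()), int(y[~above].sum()))
    above_cell = Cell(int(above.sum()), int(y[above].sum()))
    return below_cell, above_cell


def _resolve_cutoffs(models, fixed_ais, level):
    if (fixed_ais is None) == (level is None):
        raise ValueError("specify exactly one of fixed_ais or level")
    if fixed_ais is not None:
        return {m.code: float(fixed_ais) for m in models}, f"ais{fixed_ais:g}"
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0,1)")
    return (
        {m.code: m.acp(level).ais_value for m in models},
        f"acp{level * 100:g}",
    )


def evaluate_policy(
    registry: ModelRegistry,
    *,
    fixed_ais: float | None = None,
    level: float | None = None,
) -> ScreeningResult:
    """Apply a cutoff policy to every fitted stratum and pool the cells.

    ``fixed_ais`` screens everybody at one AIS value; ``level`` screens each
    stratum at its own ACP (in (0,1), e.g. 0.5 for ACP50).  ACP cutoffs
    falling outside 0..24 are not clamped: an ACP above 24 simply screens
    nobody in that stratum, one below 0 screens everybody.
    """
    models = registry.fitted_models()
    if not models:
        raise NoModelsError("registry has no fitted models")
    cutoffs, label = _resolve_cutoffs(models, fixed_ais, level)
    rows = []
    screened = detected = total_n = total_pos = 0
    for m in models:
        below, above = apply_cutoff(m.ais, m.y, cutoffs[m.code])
        rows.append({"stratum": m.code, "cutoff": cutoffs[m.code],
                     "category": "below", "n": below.n, "n_pos": below.n_pos})
        rows.append({"stratum": m.code, "cutoff": cutoffs[m.code],
                     "category": "above", "n": above.n, "n_pos": above.n_pos})
        screened += above.n
        detected += above.n_pos
        total_n += m.n
        total_pos += m.n_pos
    counts = pd.DataFrame(rows)
    counts.attrs["policy"] = label
    return ScreeningResult(counts, screened, detected, total_n, total_pos)


def result_from_counts(
    counts: pd.DataFrame, stratification: str, cutoff_label: str
) -> ScreeningResult:
    """Build a ScreeningResult from a pre-aggregated below/above count table.

    ``counts`` uses the bundled layout (columns stratification, cutoff_label,
    category, n, n_pos); the selected rows must contain exactly one below and
    one above category (already pooled across strata).
    """
    sel = counts[(counts["stratification"] == stratification)
                 & (counts["cutoff_label"] == cutoff_label)]
    pooled = sel.groupby("category")[["n", "n_pos"]].sum()
    for cat in ("below", "above"):
        if cat not in pooled.index:
            raise ValueError(f"no {cat!r} rows for {stratification!r}/{cutoff_label!r}")
    below = Cell(int(pooled.loc["below", "n"]), int(pooled.loc["below", "n_pos"]))
    above = Cell(int(pooled.loc["above", "n"]), int(pooled.loc["above", "n_pos"]))
    table = sel.rename(columns={"stratification": "stratum", "cutoff_label": "cutoff"})
    return ScreeningResult(
        table.reset_index(drop=True),
        screened=above.n,
        detected=above.n_pos,
        total_n=below.n + above.n,
        total_pos=below.n_pos + above.n_pos,
    )


def compare_policies(result: ScreeningResult, reference: ScreeningResult) -> PolicyComparison:
    """Detected/screened fractions of a policy relative to a reference policy.

    Percentages are rounded half-up to one decimal, the convention of the
    published comparison (e.g. 662/698 -> 94.8%).
    """
    if result.total_n != reference.total_n or result.total_pos != reference.total_pos:
        raise ValueError("policies evaluated on different populations")
    if reference.detected == 0:
        raise UndefinedFractionError("reference policy detected nobody")
    if reference.screened == 0:
        raise UndefinedFractionError("reference policy screened nobody")
    df = result.detected / reference.detected
    sf = result.screened / reference.screened
    return PolicyComparison(df, sf, percent_half_up(df), percent_half_up(sf))


def tune_prevalence_level(
    registry: ModelRegistry,
    target_detected: int,
    grid_step: float = 0.1,
) -> tuple[float, ScreeningResult]:
    """Find the common prevalence level q* whose ACP cutoffs detect ~target.

    Scans q over [grid_step, 100-grid_step] percent in ``grid_step``
    increments; each stratum is cut at its ACP(q/100); q* minimizes
    |detected(q) - target_detected| with ties broken toward larger q (fewer
    screened).  Returns (q* in percent, the ScreeningResult at q*).
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    models = registry.fitted_models()
    if not models:
        raise NoModelsError("registry has no fitted models")
    total_pos = sum(m.n_pos for m in models)
    if target_detected > total_pos:
        warnings.warn(
            f"target_detected={target_detected} exceeds total positives {total_pos}; "
            "returning the level with maximal detection",
            stacklevel=2,
        )

    n_steps = int(np.floor((100.0 - grid_step) / grid_step + 1e-9))
    qs = grid_step * np.arange(1, n_steps + 1)
    z = ndtri(qs / 100.0)

    detected = np.zeros(qs.size)
    for m in models:
        f = m.fit
        if abs(f.beta1) < 1e-12:
            raise NonInvertibleError(f"stratum {m.code} has zero slope")
        cutoffs = (z - f.beta0) / f.beta1
        order = np.argsort(m.ais, kind="stable")
        ais_sorted = m.ais[order]
        y_sorted = m.y[order]
        # positives with ais >= c, via suffix sums over the sorted scores
        suffix_pos = np.concatenate([np.cumsum(y_sorted[::-1])[::-1], [0.0]])
        idx = np.searchsorted(ais_sorted, cutoffs, side="left")
        detected += suffix_pos[idx]

    diffs = np.abs(detected - target_detected)
    best = diffs.min()
    # multiples of grid_step accumulate float noise (0.1*254 -> 25.400000000000002)
    q_star = float(np.round(qs[np.flatnonzero(diffs == best).max()], 10))
    return q_star, evaluate_policy(registry, level=q_star / 100.0)


def load_counts(name: str) -> pd.DataFrame:
    """Load a bundled published count table.

    Names: ``md_stratified`` (whole cohort split by MD history and its ACP50),
    ``acp_policies`` (ACP50/ACP75 under three- and five-factor stratification)
    and ``sleep_cutoff`` (fixed AIS 6 and the tuned ACP25/ACP26/ACP28.3
    policies).  Columns: stratification, cutoff_label, category, n, n_pos.
    """
    try:
        filename = _DATA_FILES[name]
    except KeyError:
        raise KeyError(f"unknown count table {name!r}; options: {sorted(_DATA_FILES)}")
    path = resources.files("acpscreen.data").joinpath(filename)
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def prevalence_3dp(cell: Cell) -> float:
    """Cell prevalence rounded half-up to 3 decimals (published-table format)."""
    return round_half_up(cell.prevalence, 3)
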