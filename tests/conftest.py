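"""Shared fixtures: hand-built fits, synthetic registries, engineered cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from acpscreen.probit import ProbitFit, fit_probit
from acpscreen.registry import ModelRegistry, StratumModel, fit_reference_models
from acpscreen.synth import simulate_scores


def make_fit(beta0: float, beta1: float, n: int = 100, n_pos: int = 50) -> ProbitFit:
    """A converged ProbitFit with given coefficients (for closed-form checks)."""
    return ProbitFit(
        beta0=beta0, beta1=beta1, se0=0.1, se1=0.05,
        p0=np.nan, p1=np.nan, ci0=(np.nan, np.nan), ci1=(np.nan, np.nan),
        n=n, n_pos=n_pos, loglik=-1.0, converged=True, n_iter=1,
    )


def single_stratum_registry(n: int, seed: int, beta0: float, beta1: float) -> ModelRegistry:
    """Registry with one fitted stratum drawn from one probit law."""
    ais, y = simulate_scores(n, seed, beta0, beta1)
    fit = fit_probit(ais, y)
    registry = ModelRegistry(active_positions=(1,), alpha=0.05, min_positives=5)
    registry.models["0xxxxx"] = StratumModel(
        "0xxxxx", n, int(y.sum()), "fitted", fit, ais, y)
    return registry


def _stratum_block(code: str, n: int, seed: int, beta0: float, beta1: float) -> pd.DataFrame:
    ais, y = simulate_scores(n, seed, beta0, beta1)
    df = pd.DataFrame({"ais": ais, "cesd_positive": y})
    for factor, char in zip(
        ("md_history", "working", "female", "lives_alone", "isolation", "bereavement"), code
    ):
        df[factor] = float(char == "1")
    return df


# The two strata that cannot be modeled and the five whose slope carries no
# signal; every remaining stratum gets a clearly positive common slope.
ZERO_POSITIVE_CODE = "010101"
TINY_CODE = "000111"
FLAT_CODES = ("011111", "010011", "001101", "000001", "010110")


def make_engineered_cohort(seed: int = 20) -> pd.DataFrame:
    """32-stratum MD-free cohort plus an MD block, engineered so that exactly
    one stratum has zero positives, one has only 4 members, and five have a
    flat (zero) outcome-score slope."""
    import itertools

    blocks = []
    sub = np.random.SeedSequence(seed).spawn(64)
    i = 0
    for bits in itertools.product("01", repeat=5):
        code = "0" + "".join(bits)
        block_seed = int(sub[i].generate_state(1)[0] % (2**31)); i += 1
        if code == ZERO_POSITIVE_CODE:
            blocks.append(_stratum_block(code, 300, block_seed, -40.0, 0.0))
        elif code == TINY_CODE:
            blocks.append(_stratum_block(code, 4, block_seed, -2.2, 0.25))
        elif code in FLAT_CODES:
            blocks.append(_stratum_block(code, 250, block_seed, 0.0, 0.0))
        else:
            blocks.append(_stratum_block(code, 400, block_seed, -2.2, 0.25))
    md_seed = int(sub[i].generate_state(1)[0] % (2**31))
    blocks.append(_stratum_block("100000", 400, md_seed, -1.575, 0.25))
    return pd.concat(blocks, ignore_index=True)


@pytest.fixture(scope="session")
def engineered_cohort() -> pd.DataFrame:
    return make_engineered_cohort()


@pytest.fixture(scope="session")
def reference_pair(engineered_cohort):
    return fit_reference_models(engineered_cohort)
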