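"""The prevalence spectrum: strata x AIS matrix of estimated prevalence.

Each fitted stratum contributes one row of estimated prevalences over the
integer AIS grid 0..24; rows are ordered ascending by ACP50 (or ACP75), so
the heatmap reads as a spectrum from high-risk strata (low ACP — a low AIS
score already implies high estimated prevalence) to low-risk strata.  The
color scale is fixed to [0, 1] so heatmaps from different stratifications
are directly comparable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NoModelsError, NonInvertibleError, OrderingError
from .probit import acp, predict_prevalence
from .registry import ModelRegistry

__all__ = ["AIS_GRID", "SpectrumMatrix", "build_spectrum", "order_spectrum",
           "export_spectrum", "read_spectrum_tsv"]

AIS_GRID = np.arange(25)


@dataclass(frozen=True)
class SpectrumMatrix:
    """Ordered strata x AIS-score grid of estimated prevalences."""

    codes: tuple[str, ...]
    values: np.ndarray          # shape (len(codes), 25), in [0,1]
    acp50: np.ndarray
    acp75: np.ndarray
    order_key: str | None = None

    def __post_init__(self):
        if self.values.shape != (len(self.codes), AIS_GRID.size):
            raise ValueError("values shape does not match codes x AIS grid")

    @property
    def n_rows(self) -> int:
        return len(self.codes)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"s{s}" for s in AIS_GRID])
        df.insert(0, "acp75", self.acp75)
        df.insert(0, "acp50", self.acp50)
        df.insert(0, "code", list(self.codes))
        return df


def build_spectrum(registry: ModelRegistry, include_reference: bool = True) -> SpectrumMatrix:
    """Predict prevalence on the AIS grid for every fitted stratum.

    Excluded strata are omitted; reference rows (with/without MD) are
    appended when present and requested, and participate in later ordering
    like any other row.
    """
    models = registry.fitted_models(include_reference=include_reference)
    if not models:
        raise NoModelsError("no fitted models to visualize")
    codes, rows, acp50s, acp75s = [], [], [], []
    for m in models:
        codes.append(m.code)
        rows.append(predict_prevalence(m.fit, AIS_GRID.astype(float)))
        try:
            acp50s.append(acp(m.fit, 0.50).ais_value)
            acp75s.append(acp(m.fit, 0.75).ais_value)
        except NonInvertibleError:
            acp50s.append(np.nan)
            acp75s.append(np.nan)
    return SpectrumMatrix(tuple(codes), np.vstack(rows), np.asarray(acp50s), np.asarray(acp75s))


def order_spectrum(matrix: SpectrumMatrix, key: str = "acp50") -> SpectrumMatrix:
    """Sort rows ascending by ACP at the chosen level, ties by code.

    Stable and idempotent; a row whose ACP is not computable (zero slope)
    raises :class:`OrderingError` naming the stratum.
    """
    if key not in ("acp50", "acp75"):
        raise ValueError(f"unknown ordering key {key!r}")
    acps = getattr(matrix, key)
    bad = np.flatnonzero(~np.isfinite(acps))
    if bad.size:
        raise OrderingError(f"row {matrix.codes[bad[0]]} has no computable {key}")
    order = sorted(range(matrix.n_rows), key=lambda i: (acps[i], matrix.codes[i]))
    return dataclasses.replace(
        matrix,
        codes=tuple(matrix.codes[i] for i in order),
        values=matrix.values[order],
        acp50=matrix.acp50[order],
        acp75=matrix.acp75[order],
        order_key=key,
    )


def export_spectrum(matrix: SpectrumMatrix, path, format: str = "tsv"):
    """Write the spectrum as a TSV matrix or render it as a heatmap image.

    TSV: one row per stratum with its code, ACP annotations and the 25
    prevalences at fixed 6-decimal formatting (bit-reproducible).  PNG/SVG:
    one colored cell per value on a shared [0,1] color scale, stratum codes
    along the left axis.
    """
    if format == "tsv":
        df = matrix.to_frame()
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
        return path
    if format in ("png", "svg"):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        height = max(2.0, 0.28 * matrix.n_rows + 1.2)
        fig, ax = plt.subplots(figsize=(8, height))
        im = ax.imshow(matrix.values, aspect="auto", cmap="viridis",
                       vmin=0.0, vmax=1.0, interpolation="nearest")
        ax.set_xticks(np.arange(0, 25, 2))
        ax.set_yticks(np.arange(matrix.n_rows))
        ax.set_yticklabels(matrix.codes, fontsize=7, family="monospace")
        ax.set_xlabel("AIS score")
        key = matrix.order_key or "registry order"
        ax.set_title(f"Estimated prevalence of CES-D positivity ({key})")
        fig.colorbar(im, ax=ax, label="estimated prevalence")
        fig.tight_layout()
        fig.savefig(path, format=format, dpi=150)
        plt.close(fig)
        return path
    raise ValueError(f"unknown format {format!r} (tsv, png or svg)")


def read_spectrum_tsv(path) -> SpectrumMatrix:
    """Re-read an exported TSV spectrum (round-trips to 1e-6)."""
    df = pd.read_csv(path, sep="\t")
    value_cols = [f"s{s}" for s in AIS_GRID]
    return SpectrumMatrix(
        tuple(df["code"]),
        df[value_cols].to_numpy(dtype=float),
        df["acp50"].to_numpy(dtype=float),
        df["acp75"].to_numpy(dtype=float),
    )
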