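"""End-to-end pipeline: filter -> stratify -> fit -> ACP -> spectrum -> screen.

Mirrors the stepwise workflow of the screening method: complete-case filter
on outcome and score, split off the with/without-MD reference models, then
within the MD-free subgroup stratify by household factors (3 factors, 8
subgroups) and additionally by social factors (5 factors, 32 subgroups),
fit every subgroup, apply the eligibility rules, and evaluate/compare
cutoff policies on the strata that carry fitted models.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import registry as reg
from . import screening, spectrum, synth
from .cohort import (
    FilterLedger,
    Thresholds,
    complete_case_filter,
    derive_variables,
    read_cohort,
)
from .errors import AcpScreenError

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("acpscreen")

#: stage -> (required canonical fields, active stratum positions)
THREE_FACTOR_POSITIONS = (2, 3, 4)      # age group, sex, cohabiting
FIVE_FACTOR_POSITIONS = (2, 3, 4, 5, 6)  # + isolation, bereavement


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    input_path: str | None = None        # cohort CSV; None => simulate
    schema: dict | None = None           # canonical -> CSV column mapping
    out_dir: str = "acpscreen_run"
    seed: int = 0
    n_simulated: int = 20000
    thresholds: Thresholds = field(default_factory=Thresholds)
    alpha: float = 0.05
    min_positives: int = 5
    screening_levels: tuple[float, ...] = (0.50, 0.75)
    fixed_ais: float = 6.0
    spectrum_image_format: str = "png"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "thresholds" in raw:
            raw["thresholds"] = Thresholds(**raw["thresholds"])
        if "screening_levels" in raw:
            raw["screening_levels"] = tuple(raw["screening_levels"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise AcpScreenError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _load_or_simulate(config: RunConfig) -> pd.DataFrame:
    if config.input_path is not None:
        log.info("reading cohort from %s", config.input_path)
        return read_cohort(config.input_path, config.schema)
    log.info("simulating cohort: n=%d seed=%d", config.n_simulated, config.seed)
    return synth.generate_cohort(synth.SynthConfig(n=config.n_simulated, seed=config.seed))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the artifact manifest (also written).

    Artifacts in ``out_dir``: filter ledger TSV, registry reports (3- and
    5-factor), ordered spectrum TSV + image, screening table TSV, manifest
    JSON.  Deterministic for a fixed config+seed (image bytes excluded; the
    TSV underlying the image is covered).
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"complete": False, "artifacts": [], "stages": {}}

    def _write_manifest():
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    try:
        cohort = _load_or_simulate(config)
        cohort = derive_variables(cohort, config.thresholds)

        ledger = FilterLedger()
        cohort, entry = complete_case_filter(
            cohort, ["cesd_positive", "ais"], "outcome_and_score")
        ledger.append(entry)
        cohort_md, entry = complete_case_filter(cohort, ["md_history"], "md_history")
        ledger.append(entry)

        references = reg.fit_reference_models(
            cohort_md, config.alpha, config.min_positives)
        md_free = cohort_md.loc[cohort_md["md_history"] == 0.0].reset_index(drop=True)
        log.info("MD-free subgroup: n=%d", len(md_free))

        registries = {}
        for label, positions, fields in (
            ("three_factor", THREE_FACTOR_POSITIONS, ["working", "female", "lives_alone"]),
            ("five_factor", FIVE_FACTOR_POSITIONS,
             ["working", "female", "lives_alone", "isolation", "bereavement"]),
        ):
            cc, entry = complete_case_filter(md_free, fields, label)
            ledger.append(entry)
            strata = reg.stratify(cc, positions)
            registry = reg.fit_stratified(
                strata, config.alpha, config.min_positives, positions)
            for model in references:
                registry.add_reference(model)
            registries[label] = registry
            n_fitted = len(registry.fitted_models())
            manifest["stages"][label] = {
                "n": len(cc), "n_strata": len(registry), "n_fitted": n_fitted}
            log.info("%s: %d strata, %d fitted", label, len(registry), n_fitted)
            report_path = out / f"registry_{label}.tsv"
            reg.registry_report(registry).to_csv(
                report_path, sep="\t", index=False, float_format="%.6g")
            manifest["artifacts"].append(report_path.name)

        ledger_path = out / "filter_ledger.tsv"
        ledger.to_tsv(ledger_path)
        manifest["artifacts"].append(ledger_path.name)

        main = registries["five_factor"]
        matrix = spectrum.order_spectrum(spectrum.build_spectrum(main), "acp50")
        tsv_path = out / "spectrum_acp50.tsv"
        spectrum.export_spectrum(matrix, tsv_path, "tsv")
        manifest["artifacts"].append(tsv_path.name)
        img_path = out / f"spectrum_acp50.{config.spectrum_image_format}"
        spectrum.export_spectrum(matrix, img_path, config.spectrum_image_format)
        manifest["artifacts"].append(img_path.name)

        rows = []
        fixed = screening.evaluate_policy(main, fixed_ais=config.fixed_ais)
        rows.append(("fixed_ais", config.fixed_ais, fixed))
        for level in config.screening_levels:
            res = screening.evaluate_policy(main, level=level)
            rows.append((f"acp{level * 100:g}", level, res))
        table = pd.DataFrame(
            {
                "policy": [r[0] for r in rows],
                "parameter": [r[1] for r in rows],
                "screened": [r[2].screened for r in rows],
                "detected": [r[2].detected for r in rows],
                "ppv_above": [r[2].ppv_above for r in rows],
                "total_n": [r[2].total_n for r in rows],
                "total_pos": [r[2].total_pos for r in rows],
            }
        )
        screen_path = out / "screening_policies.tsv"
        table.to_csv(screen_path, sep="\t", index=False, float_format="%.6g")
        manifest["artifacts"].append(screen_path.name)

        manifest["complete"] = True
        manifest["elapsed_s"] = round(time.time() - t0, 3)
        _write_manifest()
        manifest["artifacts"].append("manifest.json")
        log.info("pipeline complete in %.1fs", manifest["elapsed_s"])
        return manifest
    except Exception:
        manifest["elapsed_s"] = round(time.time() - t0, 3)
        _write_manifest()
        raise
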