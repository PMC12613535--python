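"""End-to-end orchestration: simulate -> outcomes -> analyse -> report.

Produces a run manifest (config hash, seeds, file digests, warnings) so a
re-run with the same configuration can be verified byte-for-byte.  A blinded
mode relabels the arms A/B in every human-readable output while leaving the
analysis untouched; the unmasking key is written to a separate file.
"""

from __future__ import annotations

import hashlib
import json
import warnings as _warnings
from pathlib import Path

import pandas as pd
import yaml

from .config import CohortConfig, McmcSettings, PriorSpec
from .cohort import apply_missingness, apply_protocol_deviations, generate_cohort
from .inference import fit_rr_model, summarise_effect
from .missingness import missingness_report
from .outcomes import derive_outcomes, resolve_confirmation
from .reporting import (baseline_table, consort_counts,
                        deviation_and_safety_summary, population_filter)

ARM_MASK = {"placebo": "A", "epidex": "B"}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def mask_arms(df: pd.DataFrame, mask: bool = True) -> pd.DataFrame:
    """Deterministically relabel arms A/B for blinded reporting."""
    if not mask or "arm" not in df.columns:
        return df
    out = df.copy()
    out["arm"] = out["arm"].map(ARM_MASK).fillna(out["arm"])
    return out


def unmask_arms(df: pd.DataFrame) -> pd.DataFrame:
    inv = {v: k for k, v in ARM_MASK.items()}
    out = df.copy()
    out["arm"] = out["arm"].map(inv).fillna(out["arm"])
    return out


def run_pipeline(
    config: CohortConfig | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    blinded: bool = False,
    settings: McmcSettings | None = None,
    priors: PriorSpec | None = None,
) -> dict:
    """Execute the full pipeline and return the run manifest."""
    if not isinstance(config, CohortConfig):
        cfg_path = Path(config)
        if not cfg_path.exists():
            raise FileNotFoundError(f"config file not found: {cfg_path}")
        config = CohortConfig(**(yaml.safe_load(cfg_path.read_text()) or {}))
    if seed is not None:
        config = config.model_copy(update={"seed": seed})
    settings = settings or McmcSettings(seed=config.seed)
    priors = priors or PriorSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed, "blinded": blinded,
        "config_hash": hashlib.sha256(
            json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()).hexdigest(),
        "stages": [], "outputs": {}, "warnings": [],
    }

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")

        # stage: simulate
        cohort = generate_cohort(config)
        participants, mlog = apply_missingness(
            cohort.participants, config.missingness_rates, config.seed,
            config.missingness_dependence)
        participants, dlog = apply_protocol_deviations(
            participants, config.deviation_rates, config.seed)
        cohort.participants = participants
        paths = cohort.save(out)
        mlog.to_csv(out / "missingness_log.csv", index=False)
        dlog.to_csv(out / "deviation_log.csv", index=False)
        manifest["stages"].append("simulate")

        # stage: outcomes
        events = resolve_confirmation(cohort.events, participants)
        outcomes = derive_outcomes(participants, events)
        outcomes.to_csv(out / "outcomes.csv", index=False)
        manifest["stages"].append("outcomes")

        # stage: primary analysis (ITT, site-adjusted relative-risk model)
        itt, excl = population_filter(participants, outcomes, "itt", events)
        adf = itt.merge(outcomes[["participant_id", "primary_hosp_7d"]], on="participant_id")
        adf = adf.rename(columns={"primary_hosp_7d": "y", "site_id": "site"})
        adf["y"] = adf["y"].astype(int)
        fit = fit_rr_model(adf, priors, settings, structure="site_hierarchical")
        summary = summarise_effect(fit)
        (out / "primary_effect.json").write_text(json.dumps(summary.to_dict(), indent=2))
        excl.to_csv(out / "itt_exclusions.csv", index=False)
        manifest["stages"].append("analyse_primary")

        # stage: reporting
        bt = baseline_table(mask_arms(participants, blinded))
        bt.to_csv(out / "baseline_table.csv", index=False)
        cc = consort_counts(cohort.screening, participants, outcomes)
        (out / "consort_counts.json").write_text(json.dumps(cc.to_dict(), indent=2, default=str))
        dev = deviation_and_safety_summary(participants, events, outcomes, dlog)
        dev["safety_table"].to_csv(out / "safety_table.csv", index=False)
        mr = missingness_report(participants, outcomes)
        mr.overall.to_csv(out / "missingness_overall.csv", index=False)
        manifest["stages"].append("report")

        if blinded:
            (out / "unmasking_key.json").write_text(json.dumps(ARM_MASK, indent=2))

        manifest["warnings"] = [str(w.message) for w in caught]

    for p in sorted(out.glob("*")):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _digest(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
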