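"""Primary and secondary endpoint analyses on the simulated trial.

Fits the site-adjusted hierarchical relative-risk model to the primary
outcome on the intention-to-treat population, applies the 99% superiority
rule, and repeats the model for the binary secondary endpoints.  Writes
results/effects.json.
"""

import json
import sys

import pandas as pd

from epidex.config import McmcSettings, PriorSpec
from epidex.inference import fit_rr_model, summarise_effect
from epidex.reporting import population_filter

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2026

ENDPOINTS = ["primary_hosp_7d", "hosp_at_enrolment", "allcause_admission_21d"]


def main():
    participants = pd.read_csv("results/simulated/participants.csv")
    outcomes = pd.read_csv("results/outcomes.csv")
    events = pd.read_csv("results/simulated/events.csv").fillna(
        {"respiratory_support": "", "ae_code": ""})
    itt, excl = population_filter(participants, outcomes, "itt", events)
    print(f"ITT population: {len(itt)} of {len(participants)} randomised "
          f"({len(excl)} excluded)")
    settings = McmcSettings(n_chains=2, n_warmup=800, n_draws=1500, seed=SEED)
    results = {}
    for endpoint in ENDPOINTS:
        df = itt.merge(outcomes[["participant_id", endpoint, f"missing_{endpoint}"]],
                       on="participant_id")
        df = df[~df[f"missing_{endpoint}"]].rename(
            columns={endpoint: "y", "site_id": "site"})
        df["y"] = df["y"].astype(int)
        fit = fit_rr_model(df, PriorSpec(kind="normal_logrr"), settings,
                           "site_hierarchical")
        s = summarise_effect(fit, threshold=0.99)
        results[endpoint] = s.to_dict()
        print(f"{endpoint}: RR {s.mean_rr:.3f} "
              f"[{s.hdi_rr[0]:.3f}, {s.hdi_rr[1]:.3f}], "
              f"P(superior) {s.prob_superiority:.3f} -> {s.decision}")
    with open("results/effects.json", "w") as fh:
        json.dump(results, fh, indent=2)


if __name__ == "__main__":
    main()
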