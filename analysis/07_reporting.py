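"""Trial reporting: populations, baseline table, flow counts, deviations, safety.

Builds the three analysis populations (verifying their nesting), the
descriptive baseline table with the per-variable normality rule, the
participant-flow counts from the screening log, and the protocol-deviation
and safety summaries on intention-to-treat denominators.  Writes tables under
results/.
"""

import json

import pandas as pd

from epidex.reporting import (baseline_table, consort_counts,
                              deviation_and_safety_summary, population_filter)


def main():
    participants = pd.read_csv("results/simulated/participants.csv")
    outcomes = pd.read_csv("results/outcomes.csv")
    events = pd.read_csv("results/simulated/events.csv").fillna(
        {"respiratory_support": "", "ae_code": ""})
    screening = pd.read_csv("results/simulated/screening.csv").fillna(
        {"exclusion_reason": ""})
    dev_log = pd.read_csv("results/simulated/deviation_log.csv")

    pops = {}
    for pop in ("itt", "per_protocol", "per_protocol_restricted"):
        sub, _ = population_filter(participants, outcomes, pop, events)
        pops[pop] = set(sub["participant_id"])
        print(f"{pop}: {len(sub)} participants")
    assert pops["per_protocol_restricted"] <= pops["per_protocol"] <= pops["itt"]

    bt = baseline_table(participants)
    bt.to_csv("results/baseline_table.csv", index=False)
    print(f"baseline table: {len(bt)} rows "
          f"({(bt['summary_type'] == 'median_iqr').sum()} variables summarised as median/IQR)")

    cc = consort_counts(screening, participants, outcomes)
    with open("results/consort_counts.json", "w") as fh:
        json.dump(cc.to_dict(), fh, indent=2, default=str)
    print(f"flow: screened {cc.screened}, eligible {cc.eligible}, "
          f"randomised {cc.randomised}, analysed {cc.analysed}")

    dev = deviation_and_safety_summary(participants, events, outcomes, dev_log)
    dev["safety_table"].to_csv("results/safety_table.csv", index=False)
    print("protocol deviations by arm (% of ITT):",
          {k: round(v, 1) for k, v in dev["deviation_percent_by_arm"].items()})


if __name__ == "__main__":
    main()
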