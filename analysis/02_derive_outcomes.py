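"""Derive every endpoint from the simulated participants and events.

Applies the event-confirmation rules (caregiver reports at study hospitals
require medical-record confirmation), then the hospitalisation definition
(inpatient admission, or an ED / combined ED+observation stay of 12 h or
more) within the 7-day and 21-day windows.  Writes results/outcomes.csv.
"""

import pandas as pd

from epidex import derive_outcomes, resolve_confirmation
from epidex.outcomes import check_outcome_nesting

IN = "results/simulated"


def main():
    participants = pd.read_csv(f"{IN}/participants.csv")
    events = pd.read_csv(f"{IN}/events.csv").fillna({
        "respiratory_support": "", "ae_code": "", "cause": "", "source": ""})
    ev = resolve_confirmation(events, participants)
    outcomes = derive_outcomes(participants, ev)
    check_outcome_nesting(outcomes)
    outcomes.to_csv("results/outcomes.csv", index=False)

    rate = outcomes.merge(participants[["participant_id", "arm"]], on="participant_id") \
        .groupby("arm")["primary_hosp_7d"].mean()
    print("derived outcomes; primary hospitalisation rate by arm:")
    print(rate)
    print(f"unconfirmed caregiver reports excluded: {(~ev['confirmed']).sum()}")
    print(f"missing primary outcomes: {outcomes['missing_primary_hosp_7d'].sum()}")


if __name__ == "__main__":
    main()
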