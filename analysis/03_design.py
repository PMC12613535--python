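"""Sample-size determination and decision-rule operating characteristics.

Reproduces the recruitment arithmetic (410 analysable per arm inflated by 5%
attrition to 432/864), runs the average-length-criterion search under a
point-mass prior at the design risks, and simulates type I error and power
of the 99%-posterior-probability rule under the uniform reference prior and
under the shipped informative stand-in prior.  Writes results/design.json.
"""

import json
import sys

from epidex.config import DesignParams, PriorSpec, elicited_like_prior
from epidex.design import alc_sample_size, inflate_for_attrition, operating_characteristics

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2026


def main():
    per_arm, total = inflate_for_attrition(410, 0.05)
    print(f"recruitment targets: {per_arm} per arm, {total} total")

    point = PriorSpec(kind="point", point_placebo=0.35, point_active=0.27)
    alc = alc_sample_size(DesignParams(
        criterion_length=0.09, n_grid=[600, 700, 800, 900, 1000],
        n_outer=600, posterior_draws=5000, prior=point, seed=SEED))
    print("ALC (point-mass prior): average 95% HDI length by n:")
    for n, ln in zip(alc.grid, alc.avg_lengths):
        print(f"  n={n:5d}  length={ln:.4f}")
    print(f"selected n/arm: {alc.selected_n_per_arm} -> recruit {alc.recruit_per_arm}/arm")

    out = {"recruit_per_arm": per_arm, "recruit_total": total,
           "alc": {"grid": alc.grid, "lengths": alc.avg_lengths,
                   "selected": alc.selected_n_per_arm}}
    for label, prior in (("flat", PriorSpec(kind="flat")),
                         ("standin", elicited_like_prior())):
        t1 = operating_characteristics(410, 0.35, 0.35, prior, 0.99, 2000, seed=SEED)
        pw = operating_characteristics(410, 0.35, 0.27, prior, 0.99, 2000, seed=SEED + 1)
        print(f"{label} prior: type I {100 * t1.rejection_proportion:.2f}%  "
              f"power {100 * pw.rejection_proportion:.1f}%")
        out[f"oc_{label}"] = {"type1": t1.rejection_proportion,
                              "power": pw.rejection_proportion}
    with open("results/design.json", "w") as fh:
        json.dump(out, fh, indent=2)


if __name__ == "__main__":
    main()
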