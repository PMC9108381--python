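#!/usr/bin/env python
"""Cost every treatment arm from tariff line items.

Prices the four packaged arms — conservative management in the
catheter- and endoscopic-candidate subgroups, the MISTIE III catheter
arm and the Kellner endoscopic arm — and prints the line-item breakdown
in the layout of the published cost tables. Conservative-arm surgery is
the rescue craniotomy weighted by the rescue probability; the social
line covers a 3-month rehabilitation-facility stay for the fraction
discharged there (unreported for MISTIE III).
"""

import json
from pathlib import Path

from ichecon.costing import TariffTable, conservative_arm_cost, mis_arm_cost
from ichecon.synthetic_cohort import available_arms, literature_arm

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    tariff = TariffTable.default()
    breakdowns = {}
    for name in available_arms():
        arm = literature_arm(name)
        cb = mis_arm_cost(arm, tariff) if arm.surgery_prob == 1.0 else conservative_arm_cost(arm, tariff)
        breakdowns[name] = cb.as_dict()

    lines = [
        "surgery_subtotal",
        "surgery_weighted",
        "icu",
        "stroke_unit",
        "ward",
        "hospital_total",
        "social",
        "total_with_social",
    ]
    names = sorted(breakdowns)
    print(f"{'cost line (EUR)':<22}" + "".join(f"{n:>22}" for n in names))
    for line in lines:
        cells = [
            f"{breakdowns[n][line]:>22,.2f}" if breakdowns[n][line] is not None else f"{'-':>22}"
            for n in names
        ]
        print(f"{line:<22}" + "".join(cells))

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "arm_costs.json").write_text(json.dumps(breakdowns, indent=2) + "\n", encoding="utf-8")
    rows = ["arm," + ",".join(lines)]
    for n in names:
        rows.append(n + "," + ",".join(
            "" if breakdowns[n][l] is None else f"{breakdowns[n][l]:.2f}" for l in lines
        ))
    (RESULTS / "arm_costs.csv").write_text("\n".join(rows) + "\n", encoding="utf-8")
    print(f"\nwrote {RESULTS / 'arm_costs.json'} and arm_costs.csv")


if __name__ == "__main__":
    main()
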