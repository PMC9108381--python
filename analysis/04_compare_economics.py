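#!/usr/bin/env python
"""Deterministic cost-utility comparison of the two MIS techniques.

For each technique (catheter vs MISTIE III, endoscopic vs Kellner)
recomputes the incremental cost from tariff line items, combines it
with the published group QALYs, and reports ICER, quadrant, net health
benefit at λ = €30,000/QALY, and the MIS-arm QALY that would be needed
for the ICER to meet that threshold.
"""

import json
from pathlib import Path

from ichecon.econ import DEFAULT_LAMBDA
from ichecon.scenarios import TECHNIQUES, reference_comparison

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = {}
    for technique in TECHNIQUES:
        ref = reference_comparison(technique, lam=DEFAULT_LAMBDA)
        out[technique] = ref.as_dict()
        c = ref.comparison
        print(f"--- {technique} evacuation vs conventional management ---")
        print(f"cost MIS / conventional : €{c.cost_mis:,.2f} / €{c.cost_conv:,.2f}")
        print(f"QALY MIS / conventional : {c.qaly_mis:.3f} / {c.qaly_conv:.3f}")
        print(f"incremental cost        : €{c.delta_cost:,.2f}")
        print(f"incremental QALY        : {c.delta_qaly:.3f}  (quadrant {c.quadrant})")
        icer = f"€{c.icer:,.2f}/QALY" if isinstance(c.icer, float) else c.icer
        print(f"ICER                    : {icer}")
        print(f"NHB at €30,000/QALY     : {c.nhb:.4f} QALY")
        print(f"required MIS QALY at λ  : {c.required_qaly_mis:.2f}")
        print()

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "comparison.json").write_text(json.dumps(out, indent=2) + "\n", encoding="utf-8")
    print(f"wrote {RESULTS / 'comparison.json'}")


if __name__ == "__main__":
    main()
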