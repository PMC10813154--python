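"""Generate a small synthetic 15-lead cohort and inspect one record.

Builds two healthy-control and two infarction-like records (10 s at
1000 Hz), prints their geometry, and shows that the class morphologies
differ where they should: the MI-like template carries an elevated ST
segment and a reduced R wave.
"""

import numpy as np

from ecgdyn import GroupLabel, SyntheticSpec, generate_cohort

spec = SyntheticSpec(
    n_per_class={GroupLabel.HC: 2, GroupLabel.MI: 2}, seed=1)
records, manifest = generate_cohort(spec)

print(f"cohort: {manifest['n_records']} records, "
      f"{manifest['duration_s']} s at {manifest['fs']:.0f} Hz")
for rec in records:
    lead_ii = rec.leads["II"]
    print(f"  {rec.record_id}: group={rec.group}, "
          f"{len(rec.lead_names)} leads, N={rec.n_samples}, "
          f"lead II peak={lead_ii.max():.2f} mV")

hc = next(r for r in records if r.group == GroupLabel.HC)
mi = next(r for r in records if r.group == GroupLabel.MI)
print(f"\nR-peak amplitude, lead II: HC {hc.leads['II'].max():.2f} mV "
      f"vs MI {mi.leads['II'].max():.2f} mV")
print("The MI-like template trades R-wave height for an ST-segment "
      "bump, which is what the downstream features pick up.")
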