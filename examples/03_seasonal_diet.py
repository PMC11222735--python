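"""Seasonal diet profiles by percent weighted occurrence.

Applies the scoring rules (trace scores zeroed, grass-like level-2 scores
zeroed), then summarises each season's diet under the scaled 0-5 metric
and the digestion-corrected metric, plus the share of the diet coming
from resource pulses (fruit plus fawn-classified deer).
"""

from scatpulse import (apply_zeroing, default_config,
                       placeholder_correction_factors, seasonal_summary,
                       simulate_dataset)

ds = simulate_dataset(default_config(), seed=1)
zeroed = apply_zeroing(ds.diet_scores)
seasons = dict(zip(ds.scats["sample_id"], ds.scats["season"]))

table, pulse_share = seasonal_summary(zeroed, seasons,
                                      placeholder_correction_factors())

wide = (table.query("metric == 'weighted'")
        .pivot(index="item", columns="season", values="percent")
        .round(1))
print("% weighted occurrence by season (columns sum to 100):")
print(wide.to_string())
print("\nshare of each season's diet from resource pulses:")
print(pulse_share.round(1).to_string(index=False))
print("\nSummer is dominated by the fawn and blackberry pulses, fall by "
      "persimmon; the digestion-corrected metric upweights mammal prey "
      "because hair and bone survive digestion disproportionately.")
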