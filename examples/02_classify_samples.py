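"""Classify drop samples as subsidized or unsubsidized.

A sample is subsidized when the reference marsh was dry at the sample time
(condition 1), or was wet but the inflow area's daily mean depth exceeded
the deepest daily mean flooding seen in the reference over the whole pulse
(condition 2).
"""

from marshpulse import (classify_samples, default_community_config,
                        default_hydro_config, default_pulse_windows,
                        generate_sampling_campaign, generate_water_levels)

inflow, reference = generate_water_levels(default_hydro_config(seed=1))
windows = default_pulse_windows()
samples, catches, truth = generate_sampling_campaign(
    default_community_config(seed=102), (inflow, reference), windows)

cls = classify_samples(samples, inflow, reference, windows)
for pid, grp in cls.groupby("pulse_id"):
    share = 100 * grp["subsidized"].mean()
    by_cond = grp["condition"].value_counts().to_dict()
    print(f"{pid:>9}: {int(grp['subsidized'].sum())}/{len(grp)} subsidized "
          f"({share:.0f}%), conditions {by_cond}")

agree = all(dict(zip(cls.sample_id, cls.subsidized))[k] == v
            for k, v in truth.subsidized.items())
print("matches independent rule implementation:", agree)
# condition 0 means unsubsidized: flooding explained by reference hydrology
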