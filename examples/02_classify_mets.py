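"""Classify checkup records under the Japanese MetS criteria.

The rule needs excess visceral fat (waist >= 85 cm male / >= 90 cm female)
plus at least two of: triglycerides >= 150 or HDL < 40; blood pressure
>= 130/85; fasting glucose >= 110.  Missing measurements make individual
factors — and sometimes the verdict — indeterminate rather than negative.
"""

import pandas as pd

import metscate as mc

records = pd.DataFrame([
    # mets: visceral fat + lipid + pressure
    dict(sex="male", waist=92, tg_fasting=180, tg_casual=None, hdl=55,
         sbp=142, dbp=88, bs_fasting=95, bs_casual=None, hba1c=None),
    # no_mets: three factors but the waist gate fails
    dict(sex="male", waist=80, tg_fasting=200, tg_casual=None, hdl=35,
         sbp=150, dbp=95, bs_fasting=130, bs_casual=None, hba1c=None),
    # indeterminate: one factor positive, one negative, one unmeasurable
    dict(sex="female", waist=93, tg_fasting=160, tg_casual=None, hdl=60,
         sbp=118, dbp=72, bs_fasting=None, bs_casual=None, hba1c=None),
    # glycemia resolved by the HbA1c substitution rule (>= 6.0%)
    dict(sex="female", waist=95, tg_fasting=None, tg_casual=155, hdl=38,
         sbp=120, dbp=70, bs_fasting=None, bs_casual=None, hba1c=6.4),
])

result = mc.classify_frame(records)
print(pd.concat([records[["sex", "waist"]], result], axis=1).to_string())
print("\n'verdict' combines the four flags; 'indeterminate' rows cannot be "
      "resolved either way and are excluded from outcome analyses.")
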