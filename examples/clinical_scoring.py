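"""Score the clinical scales: Gesell DA/DQ bands and CARS severity.

Worked example for one child: items passed at the 48- and 54-month Gesell
milestones in the gross-motor domain, and a 15-item CARS sheet.
"""

from wrikit import (
    CarsRecord,
    GesellDomainRecord,
    classify_dq,
    compute_developmental_age,
    compute_dq,
    score_cars,
)

rec = GesellDomainRecord("GM", {48.0: 2, 54.0: 2}, ca_months=60.0)
da = compute_developmental_age(rec)
dq = compute_dq(da, rec.ca_months)
print(f"developmental age  : {da:.0f} months   (pass-weighted mean of 48 and 54)")
print(f"developmental quot.: {dq:.0f}          (100 * DA / CA at CA = 60 months)")
print(f"DQ band            : {classify_dq(dq)}  (<76 delay, 76-85 borderline, >=86 normal)")

items = (3.0, 2.5, 2.0, 3.0, 2.0, 2.5, 3.0, 2.0, 1.5, 2.0, 2.5, 2.0, 1.5, 2.0, 2.5)
total, severity = score_cars(CarsRecord(items))
print(f"CARS total         : {total:.1f} -> {severity} (30-36 is mild/moderate)")
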