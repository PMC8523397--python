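"""Apply the rule-based osteoarthritis definitions to MOAKS score records.

A knee is tfOA-positive when it has both primary features (definite
osteophyte + full-thickness cartilage loss) or one primary plus two of three
secondary features. The example also shows the inverse sampler: records
drawn for requested labels classify back to those labels exactly.
"""

from tibrad.moaks import (
    KneeLabels,
    MoaksRecord,
    classify_tibiofemoral_oa,
    label_knee,
    percent,
)
from tibrad.phantom import generate_moaks_record

both_primaries = MoaksRecord(
    osteophyte={"medial_tibia": 2}, cartilage={"medial_femur": 3}
)
one_primary_two_secondaries = MoaksRecord(
    osteophyte={"medial_tibia": 2},
    bml={"medial_tibia_central": 1},
    bml_or_cyst_nonattachment=True,
    meniscus_degeneration_grade=1,
)
no_primary = MoaksRecord(osteophyte={"medial_tibia": 1}, cartilage={"medial_tibia_central": 2})

for name, rec in (
    ("definite osteophyte + full-thickness loss", both_primaries),
    ("one primary + BML + meniscal degeneration", one_primary_two_secondaries),
    ("grade-1 osteophyte + partial loss only", no_primary),
):
    print(f"{name:45s} -> tfOA = {classify_tibiofemoral_oa(rec)}")

wanted = KneeLabels(tfoa=True, medial_cartilage_damage=True,
                    medial_osteophyte=False, medial_bml=True)
rec = generate_moaks_record(wanted, seed=3)
print("\ninverse-sampled record round-trips:", label_knee(rec) == wanted)

# Cohort-scale label arithmetic: counts over 665 knees as percentages.
for what, count in (("tfOA", 76), ("medial cartilage damage", 91),
                    ("medial osteophyte", 85), ("medial BML", 70)):
    print(f"{count}/665 knees with {what}: {percent(count, 665)}%")
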