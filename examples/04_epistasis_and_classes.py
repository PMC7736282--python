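"""Melting-temperature epistasis and fitness classification of variants.

Takes measured variant metrics (T_m1, activity ratio, unfolding red-shift),
computes additive ΔT_m expectations for the double mutants and classifies
every variant by foldedness, stability and activity.
"""

from mtasekit import ClassificationThresholds, classify, epistasis
from mtasekit.epistasis import VariantRecord

variants = [
    VariantRecord.from_name("WT", tm1=60.0, activity=1.00, red_shift=7.8),
    VariantRecord.from_name("K41D", tm1=54.0, activity=0.05, red_shift=7.8),
    VariantRecord.from_name("A201K", tm1=54.0, activity=1.00, red_shift=7.8),
    VariantRecord.from_name("A201R", tm1=60.0, activity=1.20, red_shift=7.8),
    VariantRecord.from_name("K41D-A201K", tm1=46.0, activity=0.0,
                            red_shift=7.8, below_detection=True),
    VariantRecord.from_name("K41D-A201R", tm1=58.0, activity=1.70,
                            red_shift=7.8),
    VariantRecord.from_name("A201Q", tm1=52.0, activity=0.0, red_shift=5.0,
                            below_detection=True),
]

wt = variants[0]
classes = {v.name: classify(v, wt, ClassificationThresholds()).value
           for v in variants}
print(f"{'variant':<12} {'dTm obs':>8} {'dTm exp':>8} {'epistasis':>9}  class")
for r in epistasis(variants):
    print(
        f"{r.variant:<12} {r.observed_delta_tm:>8.1f} "
        f"{r.expected_delta_tm:>8.1f} {r.deviation:>9.1f}  {classes[r.variant]}"
    )
# A negative deviation means the double mutant is less stable than the sum
# of its singles predicts (negative epistasis); the rescue double
# K41D-A201R deviates positively and stays wild-type-like.
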