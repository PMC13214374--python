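"""ACMG/AMP evidence gates and five-tier combining for two variants.

A rare variant with strong in-silico support picks up PM2 and PP3 and
stays VUS until the functional assay adds PS3_strong, which moves it to
LP; a common variant is benign on frequency alone.
"""

from aequovar.acmg import (VariantAnnotation, apply_functional_evidence,
                           combine_criteria, evaluate_insilico_criteria,
                           evaluate_population_criteria)
from aequovar.classify import FunctionalCategory

rare = VariantAnnotation(variant_id="p.R283W", grpmax_filtering_af=1e-6,
                         popmax_af=1e-6, revel=0.85, spliceai=0.01)
common = VariantAnnotation(variant_id="p.V528I", grpmax_filtering_af=0.06)

for ann, category in [(rare, FunctionalCategory.ABNORMAL),
                      (common, FunctionalCategory.NORMAL)]:
    base = (evaluate_population_criteria(ann)
            + evaluate_insilico_criteria(ann))
    functional = apply_functional_evidence(ann, category)
    print(f"{ann.variant_id}: baseline {[i.label for i in base]} "
          f"-> {combine_criteria(base).name}")
    print(f"{'':>10} + functional {[i.label for i in functional]} "
          f"-> {combine_criteria(base + functional).name}")

print("\nThe functional readout is what moves the rare variant out of VUS.")
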