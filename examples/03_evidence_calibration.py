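"""OddsPath calibration of PS3/BS3 and the BS1 allele-frequency bound.

The abnormal readout of the validation set earns PS3 at strong strength;
the normal readout would earn BS3 at moderate strength but is
conservatively capped at supporting. The maximum credible allele
frequency for recessive retinitis pigmentosa sets the BS1 gate.
"""

from aequovar.calibration import (DiseaseModel, OddsPathInput,
                                  compute_oddspath, map_oddspath_to_strength,
                                  max_credible_af)

abnormal = compute_oddspath(OddsPathInput(30, 20, 28, 0))
normal = compute_oddspath(OddsPathInput(30, 20, 2, 19))
print(f"abnormal readout: P1={abnormal.p1:.2f}, P2={abnormal.p2:.3f}, "
      f"OddsPath={abnormal.oddspath:.1f} -> PS3_"
      f"{map_oddspath_to_strength(abnormal.oddspath, 'pathogenic').value}")
print(f"normal readout:   P1={normal.p1:.2f}, P2={normal.p2:.3f}, "
      f"OddsPath={normal.oddspath:.2f} -> BS3_"
      f"{map_oddspath_to_strength(normal.oddspath, 'benign').value} (capped)")

model = DiseaseModel(prevalence=1 / 4000, genetic_heterogeneity=0.08,
                     allelic_heterogeneity=0.63, penetrance=0.9)
print(f"\nBS1 bound: grpmax filtering AF > {max_credible_af(model):.3g} "
      "is evidence against pathogenicity for recessive RP.")
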