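"""Transcript utilities: TIS lifting and splice-consequence prediction.

CNGA1 protein annotations differ by a 12-bp in-frame upstream TIS (686 aa
on the MANE transcript vs 690 aa on the legacy one). Minigene assays
reveal exon skipping and cryptic acceptors whose protein consequence
follows from coding-frame arithmetic.
"""

from aequovar.transcripts import (TisOffset, lift_protein_annotation,
                                  predict_cryptic_acceptor_consequence,
                                  predict_skipping_consequence,
                                  synthetic_cnga1_domains,
                                  synthetic_cnga1_model)

offset = TisOffset(12)
print(f"686-aa MANE protein -> "
      f"{lift_protein_annotation(686, offset, 'mane_to_legacy')} aa legacy protein")
print(f"residue 100 (MANE numbering) = residue "
      f"{lift_protein_annotation(100, offset, 'mane_to_legacy')} (legacy)")

model = synthetic_cnga1_model()
domains = synthetic_cnga1_domains()
for label, event in [(["9"], "skip exon 9"), (["9", "10"], "skip exons 9/10")]:
    out = predict_skipping_consequence(model, label, domains)
    print(f"{event}: {out.frame_status}, deleted_aa={out.deleted_aa}, "
          f"PTC={out.ptc_predicted}, domains={list(out.affected_domains)}")

out = predict_cryptic_acceptor_consequence(model, "11", 194, domains)
print(f"cryptic acceptor deleting 194 nt of exon 11: {out.frame_status}, "
      f"PTC={out.ptc_predicted}")
print("\nIn-frame events delete whole residues; any removal not divisible "
      "by 3 shifts the frame and predicts a premature stop.")
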