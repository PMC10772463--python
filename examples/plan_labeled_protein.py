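"""Plan an intrinsically labeled protein production run.

Two milk protein concentrate batches from the same cow infusion carry
different tracer enrichments (milk collected during vs. after the
infusion). We solve the blend that hits the enrichment a steady-state
feeding design needs.
"""

from aaflux import ProteinBatch, mix_batches, plan_protein_enrichment, solve_mix_ratio

# The plasma leucine plateau produced by a 0.12 μmol·kg⁻¹·min⁻¹ infusion on
# top of a 1.38 μmol·kg⁻¹·min⁻¹ basal appearance rate — the enrichment the
# ingested protein must match so that absorption does not disturb the plateau.
target = plan_protein_enrichment(f_iv=0.12, basal_ra=1.38)
print(f"required protein enrichment: {target:.1f} MPE")

high = ProteinBatch("during-infusion", {"leucine": 10.8, "phenylalanine": 38.3})
low = ProteinBatch("post-infusion", {"leucine": 2.4, "phenylalanine": 7.7})
w = solve_mix_ratio(high, low, target, "leucine")
print(f"high-batch mass fraction: {w:.4f}  (≈ {100*w:.0f}:{100*(1-w):.0f} blend)")

mixed = mix_batches([high, low], [w, 1 - w], batch_id="production")
for aa, e in mixed.enrichments_mpe.items():
    print(f"blended {aa}: {e:.1f} MPE")
# The leucine enrichment lands exactly on target; the phenylalanine
# enrichment of the same blend follows from the batch values.
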