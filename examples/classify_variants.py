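"""Classify a small ctDNA variant table into biomarker profiles.

Each patient's variant calls are reduced to four binary biomarkers (AR
SNV/GSR, clonal TP53 alteration, homologous recombination deficiency,
TMPRSS2-ERG fusion), a subgroup index 0-15 and the biomarker signatures
used for adaptive randomization.
"""

from adaptrial.biomarkers import SIGNATURES, VariantCall, classify_patient

patients = {
    # AR hotspot mutation counts regardless of clonality
    "P1": ([VariantCall("AR", "hotspot_snv", clonal=False)], 0.12, False),
    # subclonal TP53 alteration does NOT qualify; clonal BRCA2 deletion does
    "P2": (
        [
            VariantCall("TP53", "high_impact_snv", clonal=False),
            VariantCall("BRCA2", "homozygous_deletion", clonal=True),
        ],
        0.45,
        False,
    ),
    # no qualifying alterations, low ctDNA fraction
    "P3": ([], 0.03, False),
    # microsatellite instability excludes from biomarker-driven randomization
    "P4": ([VariantCall("TP53", "hotspot_snv", clonal=True)], 0.30, True),
}

print(f"{'patient':<8}{'subgroup':<9}{'band':<8}{'eligible':<9}signatures")
for pid, (variants, fraction, msi) in patients.items():
    p = classify_patient(variants, fraction, msi)
    sigs = ",".join(s for s in SIGNATURES if s in p.signatures)
    print(f"{pid:<8}{p.subgroup_index:<9}{p.ctdna_band:<8}{str(p.eligible):<9}{sigs}")

# The subgroup index encodes the four biomarkers as AR*8 + TP53*4 + HRD*2 +
# TERG*1; every eligible patient is in the "all" signature, and signatures
# overlap (a patient can be HRD and TP53-altered at once).
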