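"""Generate a seeded synthetic liquid-biopsy cohort with planted ground truth.

Writes one SnpEff-annotated VCF per sample (46 samples: HCC plasma/tumor/EV,
LC and NHC control plasma, one normal liver, two CCA subjects), a cohort
metadata sheet, and a ground-truth JSON naming every planted variant class.
"""

from pathlib import Path

from ctvar import SimDesign, simulate_cohort

out = Path("scratch/example_cohort")
design = SimDesign(seed=42)
cohort, truth = simulate_cohort(design, out)

print(f"cohort: {len(cohort)} samples -> {out}/")
for group, specimen in cohort.strata():
    n = len(cohort.stratum_samples(group, specimen))
    print(f"  {group:>4}/{specimen:<12} {n} samples")
print(f"planted tumor-centric variants : {len(truth.tumor_centric)}")
print(f"planted control-shared 'traps' : {len(truth.control_shared)}")
print(f"planted EV-enriched variants   : {len(truth.ev_enriched)}")
# The tumor-centric class is the recovery target of the concordance cascade;
# the control-shared class must be vetoed by the LC/NHC/normal-liver arms.
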