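"""Audic-Claverie differential expression on simulated two-library counts.

Simulates a small study (2,000 genes, 10% truly DE at ~4-fold, one-library-
specific genes included), runs the exact test with BH FDR, and compares the
calls with the known ground truth.
"""

import twolibde as tl

cfg = tl.SimulationConfig(
    n_genes=2000, lib_size_a=2_000_000, lib_size_b=2_000_000,
    frac_de=0.10, lfc_mean=2.0, lfc_sd=0.3,
    frac_specific_a=0.02, frac_specific_b=0.03,
    dispersion=0.0, seed=7,
)
table, truth = tl.generate_counts(cfg)

de = tl.de_table(table, fdr_threshold=0.001, lfc_threshold=1.0)
merged = de.merge(truth, on="gene_id")

n_up = (de["call"] == "up").sum()
n_down = (de["call"] == "down").sum()
# specific_a/b genes are genuine signal too: present in only one library
true_de = merged["label"].isin(["up", "down", "specific_a", "specific_b"])
called = merged["call"] != "not_significant"
sens = (called & true_de).sum() / true_de.sum()
fdp = (called & ~true_de).sum() / max(called.sum(), 1)

print(f"genes tested          : {len(de)} (of {len(table)}; silent genes skipped)")
print(f"DEGs at FDR<=0.001    : {n_up} up, {n_down} down in the pregnant library")
print(f"specific genes called : "
      f"{(de['specific'] == 'pregnant_only').sum()} pregnant-only, "
      f"{(de['specific'] == 'nonpregnant_only').sum()} nonpregnant-only")
print(f"sensitivity / FDP     : {sens:.1%} / {fdp:.2%}")
print()
print("Sensitivity is the fraction of truly DE genes recovered; FDP the")
print("fraction of calls that are false — near zero at this strict FDR.")
print()
print(de.head(5).to_string(index=False))
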