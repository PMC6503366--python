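"""RPKM quantification and log2 fold change for a tiny two-library table."""

import twolibde as tl

# three genes; library A = nonpregnant (1M mapped reads), B = pregnant (2M)
table = tl.CountTable(
    gene_id=["PGR", "STAR", "INHA"],
    length_bp=[2000, 1000, 1500],
    count_a=[20, 5, 400],
    count_b=[160, 10, 100],
    lib_total_a=1_000_000,
    lib_total_b=2_000_000,
)

expr = tl.expression_table(table)
print(expr.to_string(index=False))
print()
print("rpkm = 1e9 * count / (lib_total * length); log2_ratio is pregnant (B)")
print("over nonpregnant (A), so PGR at log2 = 2 is 4-fold higher in pregnancy.")
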