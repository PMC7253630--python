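"""Call integer copy numbers from qPCR Ct triplicates.

A fragment present in 5 copies amplifies ~log2(5/2) cycles earlier than the
two-copy autosomal reference; the call snaps the continuous estimate onto
the locus's copy-number ladder on a log2 scale.
"""

from ylineage import QpcrMeasurement, call_copy_number, cnv_polymorphism

ladder = (1, 2, 5, 10, 20)

m = QpcrMeasurement(
    sample_id="S001",
    locus_id="17",
    ct_target=(18.70, 18.68, 18.74),
    ct_reference=(20.01, 19.99, 20.02),
)
call = call_copy_number(m, ladder)
print(f"continuous CN = {call.cn_continuous:.2f} -> integer CN = {call.cn_integer}"
      f" (QC {call.qc_flag})")

bad = QpcrMeasurement("S002", "17", (18.7, 19.1, 18.6), (20.0, 20.0, 20.0))
print("noisy triplicate ->", call_copy_number(bad, ladder).qc_flag,
      "(range > 0.3 cycles: excluded, never imputed)")

cns = [5] * 18 + [10] * 2
print(f"CN polymorphism of {{5:18, 10:2}}: {cnv_polymorphism(cns):.3f} "
      "(unbiased gene diversity over copy-number states)")
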