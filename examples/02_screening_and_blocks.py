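"""Screening-set preprocessing: QC, chi-square ranking, LD blocks.

Takes a simulated dataset through the pre-processing protocol: SNP
quality control, ranking by the 2-df Pearson chi-square genotype test,
selection of the top 500 markers and complete-linkage LD-block
construction at r2 >= 0.8.  SNPs left outside blocks become independent
covariates of the classifier.
"""

from hnbgwas import scenario_preset, simulate_dataset, stratified_split
from hnbgwas.ld import build_ld_blocks, chi2_scan, select_top_k, snp_qc

dataset, truth = simulate_dataset(scenario_preset(2, seed=11))
screening, replication = stratified_split(dataset, 0.70, seed=11)
print(f"screening set: {screening.n_samples} samples; "
      f"replication set: {replication.n_samples}")

qc_passed, report = snp_qc(screening)  # missingness, MAF, HWE-in-controls
print(f"QC: {qc_passed.n_snps}/{screening.n_snps} SNPs pass "
      f"({(~report['pass']).sum()} dropped)")

scan = chi2_scan(qc_passed).sort_values("p")
print("strongest association:",
      scan.iloc[0]["snp"], f"chi2 = {scan.iloc[0]['chi2']:.1f}",
      f"p = {scan.iloc[0]['p']:.2e}")

top = select_top_k(qc_passed, k=500)
schema = build_ld_blocks(qc_passed, top, r2_threshold=0.8)
sizes = [len(b.snp_ids) for b in schema.blocks]
print(f"schema at r2 >= 0.8: {len(schema.blocks)} blocks "
      f"(sizes {min(sizes)}-{max(sizes)}), {len(schema.covariates)} covariates")

# the schema is a frozen object: serialize it for the replication set
print("schema JSON bytes:", len(schema.to_json()))
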