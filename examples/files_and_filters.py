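"""Reading cohort files and applying the pre-derivation filters.

Writes a small genotype/phenotype/annotation trio to a temporary directory,
reads it back, restricts the panel to candidate genes, and applies the
minimum-observation filter — the same plumbing `ppskit derive` runs before
the selection algorithm.
"""

import tempfile
from pathlib import Path

import ppskit as pk

tmp = Path(tempfile.mkdtemp())

(tmp / "genotypes.csv").write_text(
    "subject_id,rs10,rs11,rs12\n"
    "P01,1,2,3\nP02,1,2,1\nP03,2,1,1\nP04,2,1,3\nP05,1,2,2\nP06,2,1,2\n"
)
(tmp / "phenotypes.csv").write_text(
    "subject_id,sse_pri,sse_active\nP01,3,5\nP02,4,4\nP03,2,3\nP04,6,2\nP05,1,4\nP06,3,3\n"
)
(tmp / "annotation.csv").write_text(
    "snp_id,gene\nrs10,DRD2\nrs11,HTR1A\nrs12,OXTR\n"
)

genotypes = pk.read_genotype_table(tmp / "genotypes.csv")
outcome = pk.read_phenotype_table(tmp / "phenotypes.csv")
annotation = pk.read_annotation(tmp / "annotation.csv")

print(f"read {genotypes.n_subjects} subjects x {genotypes.n_snps} SNPs")
print("delta SSE:", {k: int(v) for k, v in outcome.delta_sse.items()})
print("responder labels (1=non-responder, 2=responder):",
      {k: int(v) for k, v in outcome.delta_sse_d.items()})

panel = pk.filter_candidate_snps(genotypes, annotation, ["DRD2", "HTR1A"])
print("candidate-gene panel:", panel.snp_ids)

# rs12 would also fail the minimum-observation rule (category 3 seen twice):
usable = pk.exclude_low_count_snps(genotypes, min_obs=3)
print("SNPs with every observed category seen >= 3 times:", usable.snp_ids)
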