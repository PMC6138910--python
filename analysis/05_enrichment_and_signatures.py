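"""Pathway enrichment of bi-allelic conversion and signature associations.

Genes ranked by bi-allelic conversion fraction (>= 3 germline LOF carriers
required) feed the preranked permutation GSEA; the mismatch-repair set is
expected on top. The dual-hit MMR carriers' exposures are tested against
the mismatch-repair-like signature with the label-permutation Wilcoxon
test.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
run_dir = ROOT / "scratch" / "run"

gsea = pd.read_csv(run_dir / "gsea.tsv", sep="\t")
gsea.head(8).to_csv(ROOT / "results" / "05_gsea_top.tsv", sep="\t", index=False)
print("top gene sets by permutation p:")
print(gsea.head(5)[["gene_set", "size", "es", "nes", "p", "q"]].to_string(index=False))

assoc = pd.read_csv(run_dir / "signature_assoc.tsv", sep="\t")
assoc = assoc.sort_values("p")
assoc.head(8).to_csv(
    ROOT / "results" / "05_signature_assoc_top.tsv", sep="\t", index=False
)
print("\nsignature associations for dual-hit MMR carriers (top 5):")
print(assoc.head(5)[["signature", "stat", "p", "q"]].to_string(index=False))
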