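"""Per-gene MSI scan across the DNA-damage-repair panel.

One model per gene and layer (germline LOF / somatic LOF / methylation),
microsatellite-overlapping frameshifts removed from the somatic layer and
bi-allelic MMR carriers excluded from the cohort, Bonferroni control within
layer. The silenced translesion-synthesis gene should be the unique
methylation-layer hit.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
scan = pd.read_csv(ROOT / "scratch" / "run" / "ddr_scan.tsv", sep="\t")

hits = scan.loc[scan["bonferroni_significant"]].sort_values("p")
hits.to_csv(ROOT / "results" / "04_ddr_scan_hits.tsv", sep="\t", index=False)

n_tested = (scan["flag"] != "untestable").sum()
print(f"tested {n_tested} gene x layer models across {scan['gene'].nunique()} genes")
print("Bonferroni-significant hits:")
print(
    hits[["gene", "layer", "coef", "p", "n_carriers"]].to_string(index=False)
    if len(hits)
    else "  none"
)
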