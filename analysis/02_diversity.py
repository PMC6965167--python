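#!/usr/bin/env python
"""Per-population allele diversity: N, N_a, h_o, h_e, F_IS and the
Hardy–Weinberg exact-test p-value, plus high-frequency allele summaries.

Reads the dataset written by 01_simulate_study.py; writes the diversity
table (the Table-3-style summary) under results/diversity/.
"""

from pathlib import Path

import pandas as pd

from mhcdivkit.pipeline import RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = RunConfig(
        fasta=str(ROOT / "data" / "alleles.fasta"),
        genotypes=str(ROOT / "data" / "genotypes.tsv"),
        mask=str(ROOT / "data" / "mask.txt"),
        stages=("validate", "diversity"),
        mc_steps=20_000,
        master_seed=1,
        out_dir=str(ROOT / "diversity"),
    )
    run_pipeline(cfg)
    table = pd.read_csv(ROOT / "diversity" / "diversity_table.tsv", sep="\t")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    low_ho = table["h_o"] < table["h_e"]
    print(
        f"\n{low_ho.sum()}/{len(table)} populations show a heterozygote "
        "deficit (h_o < h_e), the signature the inbreeding model injects."
    )


if __name__ == "__main__":
    main()
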