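#!/usr/bin/env python
"""Over-representation analysis of each co-expression module.

Tests every term of the gene-to-term mapping against each module's gene set
with the one-sided hypergeometric tail (BH-corrected within module, FDR <
0.05, top 10 reported).  Writes enrichment.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from salmotx.enrichment import enrich


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    modules = pd.read_csv(
        args.outdir / "modules.tsv", sep="\t", index_col="locus"
    )["module"]
    mapping_frame = pd.read_csv(args.datadir / "gene2term.tsv", sep="\t")
    mapping = {
        term: set(group["gene"])
        for term, group in mapping_frame.groupby("term")
    }
    background = set(modules.index)

    rows = []
    for module in sorted(modules.unique()):
        if module == "grey":
            continue
        genes = set(modules[modules == module].index)
        for r in enrich(genes, background, mapping, module_name=module):
            rows.append(
                {
                    "module": r.module, "term": r.term,
                    "term_size": r.term_size, "overlap": r.overlap,
                    "module_size": r.module_size, "p": r.p, "fdr": r.fdr,
                }
            )
    table = pd.DataFrame(
        rows, columns=["module", "term", "term_size", "overlap",
                       "module_size", "p", "fdr"]
    )
    table.to_csv(args.outdir / "enrichment.tsv", sep="\t", index=False)

    if table.empty:
        print("no term enriched at FDR < 0.05")
    else:
        for module, group in table.groupby("module"):
            top = group.iloc[0]
            print(f"  {module}: top term {top['term']} "
                  f"(overlap {top['overlap']}/{top['term_size']}, "
                  f"FDR {top['fdr']:.2g})")


if __name__ == "__main__":
    main()
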