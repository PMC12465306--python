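#!/usr/bin/env python
"""Unsigned weighted co-expression network and module detection.

Variance-filters the VST matrix, selects the soft power by scale-free fit,
builds the |cor|^beta adjacency and TOM, detects modules, and correlates
each module eigengene with the binarized tissue indicators.  Writes
soft_power.tsv, modules.tsv, eigengenes.tsv and module_trait.tsv.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from salmotx import expression as ex
from salmotx import network as nw
from salmotx.annotation import SampleTable


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    counts = pd.read_csv(args.datadir / "counts.tsv", sep="\t", index_col="locus")
    samples = SampleTable.read_tsv(args.datadir / "samples.tsv")

    filtered = ex.filter_low(counts)
    vst = ex.vst(filtered, ex.size_factors(filtered))
    high = nw.variance_filter(vst, keep_fraction=0.75)
    print(f"variance filter kept {len(high)}/{len(vst)} loci (top 75%)")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        soft = nw.pick_soft_power(high)
    pd.DataFrame(
        {"power": soft.powers, "scale_free_r2": soft.r_squared,
         "mean_connectivity": soft.mean_connectivity}
    ).to_csv(args.outdir / "soft_power.tsv", sep="\t", index=False)
    note = "" if soft.reached_target else " (no power reached R^2 > 0.8)"
    print(f"soft power beta = {soft.selected}{note}")

    adjacency = nw.adjacency(high, soft.selected)
    detection = nw.detect_modules(1.0 - nw.tom(adjacency), high)
    detection.modules.rename("module").rename_axis("locus").to_csv(
        args.outdir / "modules.tsv", sep="\t"
    )
    detection.eigengenes.rename_axis("sample").to_csv(
        args.outdir / "eigengenes.tsv", sep="\t"
    )
    print("module sizes:",
          detection.modules.value_counts().to_dict())

    trait = nw.module_trait(detection.eigengenes, samples)
    combined = trait.r.round(4).astype(str) + " (p=" + trait.p.map(
        lambda p: f"{p:.2g}"
    ) + ")"
    combined.rename_axis("module").to_csv(
        args.outdir / "module_trait.tsv", sep="\t"
    )
    for module in trait.r.index:
        best = trait.r.loc[module].idxmax()
        flag = "significant" if trait.significant.loc[module, best] else "ns"
        print(f"  {module}: best tissue {best} "
              f"(r={trait.r.loc[module, best]:.2f}, {flag})")


if __name__ == "__main__":
    main()
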