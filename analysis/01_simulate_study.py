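#!/usr/bin/env python
"""Simulate the toy study and write every input the later stages consume.

Outputs (under results/data/): reference.gtf, assembled.gtf, genome.fa,
counts.tsv, samples.tsv, gene2term.tsv, and the ground-truth tables
(truth_codes.tsv, truth_loci.tsv, truth_pairs.tsv) used by the narrative
checks in the downstream scripts.
"""

import argparse
from pathlib import Path

import pandas as pd

from salmotx.annotation import write_gtf
from salmotx.synthetic import (
    SimulationConfig,
    simulate_annotation,
    simulate_counts,
    simulate_sequences,
    write_fasta,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed)
    reference, assembled, truth = simulate_annotation(cfg)
    genome = simulate_sequences(cfg, reference, assembled, truth)
    counts, samples = simulate_counts(cfg, truth)

    write_gtf(reference, args.outdir / "reference.gtf")
    write_gtf(assembled, args.outdir / "assembled.gtf")
    write_fasta(genome, args.outdir / "genome.fa")
    counts.rename_axis("locus").to_csv(args.outdir / "counts.tsv", sep="\t")
    samples.write_tsv(args.outdir / "samples.tsv")

    pd.Series(truth.class_code_of, name="class_code").rename_axis(
        "transcript"
    ).to_csv(args.outdir / "truth_codes.tsv", sep="\t")
    pd.DataFrame(
        {
            "category": pd.Series(truth.category_of),
            "tissue_specific": pd.Series(truth.tissue_specific_of),
            "module": pd.Series(truth.module_of),
        }
    ).rename_axis("locus").to_csv(args.outdir / "truth_loci.tsv", sep="\t")
    pd.DataFrame(truth.pairs).to_csv(
        args.outdir / "truth_pairs.tsv", sep="\t", index=False
    )

    # plant a term mapping over the locus universe: one term per planted
    # module plus diffuse decoy terms, for the enrichment stage
    rows = []
    for lid, m in truth.module_of.items():
        if m is not None:
            rows.append((lid, f"TERM:module{m}", f"planted module {m} program"))
    loci = sorted(truth.category_of)
    for j, lid in enumerate(loci):
        rows.append((lid, f"TERM:decoy{j % 12}", f"decoy set {j % 12}"))
    pd.DataFrame(rows, columns=["gene", "term", "name"]).to_csv(
        args.outdir / "gene2term.tsv", sep="\t", index=False
    )

    print(f"simulated study with seed {args.seed}:")
    print(f"  reference loci: {len(reference)} "
          f"({reference.n_transcripts} transcripts)")
    print(f"  assembled loci: {len(assembled)} "
          f"({assembled.n_transcripts} transcripts)")
    print(f"  counts: {counts.shape[0]} loci x {counts.shape[1]} samples")
    print(f"  planted pairs: {len(truth.pairs)}")
    print(f"  wrote inputs to {args.outdir}")


if __name__ == "__main__":
    main()
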