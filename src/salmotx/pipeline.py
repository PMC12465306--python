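"""End-to-end study runner over a synthetic or user-supplied dataset.

Chains the stages in the order a post-assembly analysis runs them:
transcript classification -> coding-potential triage of intergenic loci ->
expression statistics (DE, tau, tissue-specific calls) -> co-expression
modules -> candidate lincRNA-gene pairs.  Each stage's outputs are kept on
the result object so drivers and tests can inspect any intermediate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from salmotx import expression as ex
from salmotx import network as nw
from salmotx.annotation import GenomeAnnotation, SampleTable
from salmotx.coding import (
    CodingPotentialResult,
    CutoffReport,
    LocusCategory,
    MotifDomainScanner,
    annotate_domains,
    categorize_loci,
    find_orfs,
    score_transcripts,
    train_codpot,
)
from salmotx.compare import TranscriptComparison, classify_all, summarize_codes
from salmotx.pairs import LncRnaPair, candidate_pairs, pair_report
from salmotx.position import annotate_all, locus_rollup
from salmotx.synthetic import (
    DOMAIN_MOTIF,
    SimulationConfig,
    GroundTruth,
    get_transcript_sequence,
    locus_lengths,
    simulate_annotation,
    simulate_counts,
    simulate_sequences,
)


@dataclass
class StudyResult:
    reference: GenomeAnnotation
    assembled: GenomeAnnotation
    samples: SampleTable
    comparisons: dict[str, TranscriptComparison]
    code_summary: dict[str, tuple[int, float]]
    cutoff_report: CutoffReport
    coding_results: list[CodingPotentialResult]
    categories: dict[str, str]
    counts: pd.DataFrame
    filtered_counts: pd.DataFrame
    de_results: dict
    tissue_specific: pd.DataFrame
    soft_power: nw.SoftThresholdResult
    modules: pd.Series
    eigengenes: pd.DataFrame
    module_trait: nw.ModuleTraitTable
    pairs: list[LncRnaPair]
    pair_table: pd.DataFrame
    truth: GroundTruth | None = None
    genome: dict[str, str] = field(default_factory=dict)


def run_synthetic_study(
    config: SimulationConfig,
    codpot_seed: int | None = None,
    keep_fraction: float = 0.75,
) -> StudyResult:
    """Simulate a study and run every downstream stage on it."""
    reference, assembled, truth = simulate_annotation(config)
    genome = simulate_sequences(config, reference, assembled, truth)
    counts, samples = simulate_counts(config, truth)
    result = run_study(
        reference,
        assembled,
        genome,
        counts,
        samples,
        motifs=[DOMAIN_MOTIF],
        codpot_seed=config.seed if codpot_seed is None else codpot_seed,
        keep_fraction=keep_fraction,
    )
    result.truth = truth
    result.genome = genome
    return result


def run_study(
    reference: GenomeAnnotation,
    assembled: GenomeAnnotation,
    genome: dict[str, str],
    counts: pd.DataFrame,
    samples: SampleTable,
    motifs: list[str],
    codpot_seed: int | None = None,
    keep_fraction: float = 0.75,
) -> StudyResult:
    # 1. classify assembled transcripts against the reference
    comparisons = classify_all(assembled, reference)
    code_summary = summarize_codes(comparisons)

    # 2. coding potential of intergenic transcripts
    mrnas = [
        get_transcript_sequence(genome, t)
        for locus in reference
        for t in locus.transcripts
        if t.biotype == "protein_coding"
    ]
    model, cutoff_report = train_codpot(mrnas[:100], seed=codpot_seed)
    u_seqs = {
        t.id: get_transcript_sequence(genome, t)
        for locus in assembled
        for t in locus.transcripts
        if comparisons[t.id].class_code == "u"
    }
    coding_results = score_transcripts(model, u_seqs)
    orfs = {tid: find_orfs(seq, 100, tid) for tid, seq in u_seqs.items()}
    annotate_domains(orfs, u_seqs, MotifDomainScanner(motifs))
    categories = {
        c.locus_id: c.category
        for c in categorize_loci(
            assembled, comparisons, orfs, coding_results, reference
        )
    }
    for locus in reference:
        categories.setdefault(
            locus.id,
            "known_coding"
            if locus.biotype == "protein_coding"
            else "known_lncRNA"
            if locus.biotype == "lncRNA"
            else "excluded",
        )

    # 3. expression: DE, tau, tissue-specific calls
    filtered = ex.filter_low(counts)
    de_results = ex.all_pairwise_de(filtered, samples)
    upregulated = ex.upregulated_single_tissue(de_results)
    lengths = locus_lengths(reference, assembled).reindex(filtered.index)
    tau_table = ex.tau_profiles(filtered, lengths.dropna(), samples)
    tissue_specific = ex.call_tissue_specific(upregulated, tau_table)

    # 4. co-expression modules
    factors = ex.size_factors(filtered)
    vst_matrix = ex.vst(filtered, factors)
    high_var = nw.variance_filter(vst_matrix, keep_fraction)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        soft = nw.pick_soft_power(high_var)
        adj = nw.adjacency(high_var, soft.selected)
        detection = nw.detect_modules(1.0 - nw.tom(adj), high_var)
        trait = nw.module_trait(detection.eigengenes, samples)

    # 5. candidate lincRNA-gene pairs
    lnc_loci = [
        locus
        for locus in assembled
        if categories.get(locus.id) in {"lincRNA", "known_lncRNA"}
    ]
    lnc_transcripts = [t for locus in lnc_loci for t in locus.transcripts]
    positions = annotate_all(lnc_transcripts, reference)
    locus_positions = locus_rollup(
        positions, {t.id: locus.id for locus in lnc_loci for t in locus.transcripts}
    )
    partner_locus_of = {
        t.id: locus.id for locus in reference for t in locus.transcripts
    }
    pairs = candidate_pairs(
        locus_positions, detection.modules, categories, partner_locus_of
    )
    table = pair_report(pairs, tissue_specific)

    return StudyResult(
        reference=reference,
        assembled=assembled,
        samples=samples,
        comparisons=comparisons,
        code_summary=code_summary,
        cutoff_report=cutoff_report,
        coding_results=coding_results,
        categories=categories,
        counts=counts,
        filtered_counts=filtered,
        de_results=de_results,
        tissue_specific=tissue_specific,
        soft_power=soft,
        modules=detection.modules,
        eigengenes=detection.eigengenes,
        module_trait=trait,
        pairs=pairs,
        pair_table=table,
    )
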