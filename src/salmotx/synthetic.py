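"""Synthetic toy study generator with full ground truth.

Generates a miniature genome, a reference annotation with protein-coding and
lncRNA biotypes on both strands, assembled transcripts constructed to
receive known class codes, planted intergenic loci that are coding (long ORF
plus a planted domain motif) or non-coding (k-let-shuffled coding sequence),
divergent lincRNA-gene arrangements, and a negative-binomial count matrix
over four tissue groups with planted tissue-specific loci and planted
latent-factor co-expression modules.  Everything derives from one global
seed; the same seed yields byte-identical GTF/FASTA/count outputs.

The defaults define the study conditions the rest of the package is tested
against: four tissues, 12 samples per tissue, NB dispersion 0.05, planted
log2 fold change of 3 for tissue-specific loci, and 4 latent-factor modules
of 60 loci each, one per tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from salmotx.annotation import (
    Exon,
    GenomeAnnotation,
    Locus,
    SampleTable,
    Transcript,
)
from salmotx.coding import find_orfs, klet_shuffle

DEFAULT_TISSUES = ("immature_testis", "mature_testis", "ovary", "pituitary")
DOMAIN_MOTIF = "TGGCATGAGGAT"  # 4 non-stop codons planted in coding ORFs

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA"}
]
# biased codon usage shared by every simulated coding sequence, mimicking the
# codon-usage bias that lets hexamer features discriminate mRNA from shuffles
_CODON_WEIGHTS = np.exp(-np.arange(len(_NON_STOP_CODONS)) / 12.0)
_CODON_WEIGHTS /= _CODON_WEIGHTS.sum()


class CapacityError(ValueError):
    """Requested features do not fit on the configured contigs."""


@dataclass
class SimulationConfig:
    seed: int = 0
    n_contigs: int = 3
    contig_length: int = 4_000_000
    n_reference_genes: int = 30
    fraction_lncrna: float = 0.2
    n_assembled_per_class: dict[str, int] = field(
        default_factory=lambda: {"=": 5, "c": 3, "j": 5, "e": 2, "o": 2,
                                 "i": 3, "x": 3, "u": 5}
    )
    n_planted_coding_intergenic: int = 10
    n_planted_lincrna: int = 10
    n_divergent_pairs: int = 4
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    samples_per_tissue: int = 12
    nb_dispersion: float = 0.05
    planted_log2fc: float = 3.0
    tissue_leak: float = 2e-4
    n_tissue_specific_per_tissue: int = 25
    n_modules: int = 4
    module_size: int = 60
    module_tissue_shift: float = 3.0
    noise_sd: float = 0.2
    n_background_loci: int = 420

    def validate(self) -> None:
        if any(v < 0 for v in self.n_assembled_per_class.values()):
            raise ValueError("class counts must be >= 0")
        for name in (
            "n_contigs", "contig_length", "n_reference_genes",
            "n_planted_coding_intergenic", "n_planted_lincrna",
            "n_divergent_pairs", "samples_per_tissue", "n_modules",
            "module_size", "n_background_loci",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nb_dispersion <= 0 or self.noise_sd < 0:
            raise ValueError("nb_dispersion must be > 0 and noise_sd >= 0")


@dataclass
class GroundTruth:
    class_code_of: dict[str, str] = field(default_factory=dict)
    category_of: dict[str, str] = field(default_factory=dict)
    coding_transcripts: list[str] = field(default_factory=list)
    noncoding_transcripts: list[str] = field(default_factory=list)
    tissue_specific_of: dict[str, str | None] = field(default_factory=dict)
    module_of: dict[str, int | None] = field(default_factory=dict)
    pairs: list[dict] = field(default_factory=list)


class _Placer:
    """Sequential feature placement along contigs with explicit margins."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.contig_ids = [f"ctg{i + 1}" for i in range(config.n_contigs)]
        self.cursor = {c: 1_000 for c in self.contig_ids}
        self.idx = 0

    def place(self, length: int, margin: int) -> tuple[str, int]:
        """Reserve ``length`` bp plus a preceding margin; returns (contig, start)."""
        for _ in range(len(self.contig_ids)):
            contig = self.contig_ids[self.idx % len(self.contig_ids)]
            self.idx += 1
            start = self.cursor[contig] + margin
            if start + length < self.config.contig_length - 1_000:
                self.cursor[contig] = start + length
                return contig, start
        raise CapacityError(
            f"contigs of {self.config.contig_length} bp are too short for the "
            "requested features; increase contig_length or n_contigs"
        )


def _make_gene_exons(
    rng: np.random.Generator, contig: str, start: int
) -> list[Exon]:
    n_exons = int(rng.integers(3, 5))
    exons = []
    pos = start
    for _ in range(n_exons):
        elen = int(rng.integers(150, 400))
        exons.append(Exon(contig, pos, pos + elen - 1))
        pos += elen + int(rng.integers(300, 2000))
    return exons


def _gene_span_estimate() -> int:
    return 4 * 400 + 4 * 2000  # upper bound for one gene's genomic footprint


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[GenomeAnnotation, GenomeAnnotation, GroundTruth]:
    """Reference annotation, assembled annotation, and ground truth.

    Assembled transcripts are constructed so that classification recovers
    exactly the planted class code; divergent lincRNA-gene pairs are placed
    head-to-head in isolated neighborhoods with alternating TSS gaps below
    5 kb (bi-directional promoter truth) and between 5 and 60 kb (cis-acting
    truth).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    placer = _Placer(config, rng)
    truth = GroundTruth()

    ref_loci: list[Locus] = []
    asm_loci: list[Locus] = []
    coding_refs: list[Locus] = []  # multi-exon protein-coding genes to copy from

    # --- reference genes -------------------------------------------------
    for g in range(config.n_reference_genes):
        contig, start = placer.place(_gene_span_estimate(), margin=20_000)
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = (
            "lncRNA" if rng.random() < config.fraction_lncrna else "protein_coding"
        )
        gid = f"REFG{g + 1:05d}"
        t = Transcript(
            id=f"{gid}.t1",
            contig=contig,
            strand=strand,
            exons=_make_gene_exons(rng, contig, start),
            biotype=biotype,
        )
        locus = Locus(gid, contig, strand, [t], origin="reference")
        ref_loci.append(locus)
        if biotype == "protein_coding":
            coding_refs.append(locus)
        truth.category_of[gid] = (
            "known_coding" if biotype == "protein_coding" else "known_lncRNA"
        )
    if not coding_refs:
        raise CapacityError("no protein-coding reference genes were generated")

    asm_n = 0

    def new_asm_id() -> tuple[str, str]:
        nonlocal asm_n
        asm_n += 1
        return f"ASMG{asm_n:05d}", f"ASMT{asm_n:05d}"

    def add_asm(
        exons: list[Exon], strand: str, code: str, contig: str
    ) -> str:
        gid, tid = new_asm_id()
        t = Transcript(tid, contig, strand, exons, biotype="unknown")
        asm_loci.append(Locus(gid, contig, strand, [t], origin="assembled"))
        truth.class_code_of[tid] = code
        return gid

    # --- assembled transcripts with planted class codes -------------------
    for code in sorted(config.n_assembled_per_class):
        n = config.n_assembled_per_class[code]
        for rep in range(n):
            if code == "u":
                contig, start = placer.place(2_000, margin=15_000)
                strand = "+" if rng.random() < 0.5 else "-"
                e1 = Exon(contig, start, start + 300)
                e2 = Exon(contig, start + 800, start + 1100)
                add_asm([e1, e2], strand, "u", contig)
                continue
            ref = coding_refs[(rep + hash(code)) % len(coding_refs)].transcripts[0]
            exons = ref.exons
            if code == "=":
                delta = int(rng.integers(10, 80))
                new = [Exon(ref.contig, max(1, exons[0].start - delta), exons[0].end)]
                new += exons[1:-1]
                new.append(Exon(ref.contig, exons[-1].start, exons[-1].end + delta))
                add_asm(new, ref.strand, "=", ref.contig)
            elif code == "c":
                add_asm(list(exons[1:]), ref.strand, "c", ref.contig)
            elif code == "j":
                ext_start = exons[-1].end + int(rng.integers(400, 900))
                new = list(exons) + [Exon(ref.contig, ext_start, ext_start + 200)]
                add_asm(new, ref.strand, "j", ref.contig)
            elif code == "e":
                e0 = exons[0]
                add_asm(
                    [Exon(ref.contig, max(1, e0.start - 5), e0.end)],
                    ref.strand, "e", ref.contig,
                )
            elif code == "o":
                e0, e1 = exons[0], exons[1]
                add_asm(
                    [Exon(ref.contig, e0.start + 50, e1.start + 50)],
                    ref.strand, "o", ref.contig,
                )
            elif code == "i":
                i0, i1 = ref.introns[0]
                add_asm(
                    [Exon(ref.contig, i0 + 50, min(i1 - 50, i0 + 350))],
                    ref.strand, "i", ref.contig,
                )
            elif code == "x":
                e0 = exons[0]
                anti = "-" if ref.strand == "+" else "+"
                add_asm([Exon(ref.contig, e0.start, e0.end)], anti, "x", ref.contig)
            else:
                raise ValueError(f"unsupported planted class code {code!r}")

    # --- planted intergenic loci (coding / lincRNA) -----------------------
    for kind, n in (
        ("coding", config.n_planted_coding_intergenic),
        ("lincRNA", config.n_planted_lincrna),
    ):
        for _ in range(n):
            contig, start = placer.place(1_200, margin=15_000)
            strand = "+" if rng.random() < 0.5 else "-"
            exon = Exon(contig, start, start + 899)
            gid = add_asm([exon], strand, "u", contig)
            tid = asm_loci[-1].transcripts[0].id
            if kind == "coding":
                truth.category_of[gid] = "new_coding"
                truth.coding_transcripts.append(tid)
            else:
                truth.category_of[gid] = "lincRNA"
                truth.noncoding_transcripts.append(tid)

    # --- divergent lincRNA-gene pairs ------------------------------------
    for p in range(config.n_divergent_pairs):
        small = p % 2 == 0
        tss_gap = int(rng.integers(60, 4_500)) if small else int(
            rng.integers(6_000, 60_000)
        )
        lnc_len = 700
        contig, lnc_start = placer.place(
            lnc_len + tss_gap + _gene_span_estimate(), margin=150_000
        )
        lnc_exon = Exon(contig, lnc_start, lnc_start + lnc_len - 1)
        lnc_gid = add_asm([lnc_exon], "-", "u", contig)
        lnc_tid = asm_loci[-1].transcripts[0].id
        truth.category_of[lnc_gid] = "lincRNA"
        truth.noncoding_transcripts.append(lnc_tid)

        g = len(ref_loci) + 1
        gid = f"REFG{g:05d}"
        gene_start = lnc_exon.end + tss_gap  # '+' partner: TSS = first exon start
        gene = Transcript(
            id=f"{gid}.t1",
            contig=contig,
            strand="+",
            exons=_make_gene_exons(rng, contig, gene_start),
            biotype="protein_coding",
        )
        partner = Locus(gid, contig, "+", [gene], origin="reference")
        ref_loci.append(partner)
        coding_refs.append(partner)
        truth.category_of[gid] = "known_coding"
        truth.pairs.append(
            {
                "lnc_locus": lnc_gid,
                "partner_locus": gid,
                "tss_gap": gene_start - lnc_exon.end,
                "functional_class": (
                    "bidirectional_promoter"
                    if gene_start - lnc_exon.end < 5_000
                    else "cis_acting"
                ),
            }
        )

    # --- background expressed loci (known genes without structure games) --
    for b in range(config.n_background_loci):
        contig, start = placer.place(_gene_span_estimate() // 2, margin=12_000)
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"BKGG{b + 1:05d}"
        exons = [
            Exon(contig, start, start + 250),
            Exon(contig, start + 800, start + 1050),
        ]
        t = Transcript(f"{gid}.t1", contig, strand, exons, biotype="protein_coding")
        ref_loci.append(Locus(gid, contig, strand, [t], origin="reference"))
        truth.category_of[gid] = "known_coding"

    contigs = {c: config.contig_length for c in placer.contig_ids}
    reference = GenomeAnnotation(ref_loci, contigs)
    assembled = GenomeAnnotation(asm_loci, contigs)
    _plant_expression_truth(config, truth)
    return reference, assembled, truth


def _plant_expression_truth(config: SimulationConfig, truth: GroundTruth) -> None:
    """Assign tissue-specific tissues and module ids over the locus universe."""
    rng = np.random.default_rng([config.seed, 4])
    universe = sorted(truth.category_of)
    truth.tissue_specific_of = {lid: None for lid in universe}
    truth.module_of = {lid: None for lid in universe}

    pair_loci = {p["lnc_locus"] for p in truth.pairs} | {
        p["partner_locus"] for p in truth.pairs
    }
    free = [lid for lid in universe if lid not in pair_loci]
    rng.shuffle(free)

    it = iter(free)
    for t_idx, tissue in enumerate(config.tissues):
        for _ in range(config.n_tissue_specific_per_tissue):
            try:
                lid = next(it)
            except StopIteration:
                raise CapacityError(
                    "not enough loci for the requested tissue-specific planting"
                )
            truth.tissue_specific_of[lid] = tissue

    # modules cycle through tissues; pair members join the module of their pair
    for m in range(config.n_modules):
        for _ in range(config.module_size):
            try:
                lid = next(it)
            except StopIteration:
                raise CapacityError(
                    "not enough loci for the requested module planting"
                )
            truth.module_of[lid] = m
    if config.n_modules > 0:
        for i, pair in enumerate(truth.pairs):
            m = i % config.n_modules
            truth.module_of[pair["lnc_locus"]] = m
            truth.module_of[pair["partner_locus"]] = m
            pair["module"] = m


# --- sequences ----------------------------------------------------------


def _random_coding_seq(
    rng: np.random.Generator, total_len: int, with_motif: bool
) -> str:
    """UTR + ATG + non-stop codons (+ planted motif) + stop + UTR."""
    utr5 = 30
    n_codons = int(rng.integers(110, 160))
    body = ["ATG"]
    motif_at = int(rng.integers(5, 40)) if with_motif else -1
    i = 1
    while i < n_codons:
        if i == motif_at:
            body.extend(
                DOMAIN_MOTIF[j : j + 3] for j in range(0, len(DOMAIN_MOTIF), 3)
            )
            i += len(DOMAIN_MOTIF) // 3
        else:
            body.append(
                _NON_STOP_CODONS[
                    rng.choice(len(_NON_STOP_CODONS), p=_CODON_WEIGHTS)
                ]
            )
            i += 1
    seq = (
        _random_nt(rng, utr5)
        + "".join(body)
        + "TAA"
        + _random_nt(rng, max(0, total_len - utr5 - 3 * len(body) - 3))
    )
    return seq[:total_len] if len(seq) >= total_len else seq + _random_nt(
        rng, total_len - len(seq)
    )


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def get_transcript_sequence(genome: dict[str, str], t: Transcript) -> str:
    """Spliced sense-strand sequence of a transcript."""
    seq = "".join(genome[t.contig][e.start - 1 : e.end] for e in t.exons)
    return revcomp(seq) if t.strand == "-" else seq


def _write_transcript_sequence(
    genome: dict[str, list[str]], t: Transcript, sense_seq: str
) -> None:
    """Plant a sense-strand spliced sequence into the genome at t's exons."""
    assert len(sense_seq) == t.length
    genomic = revcomp(sense_seq) if t.strand == "-" else sense_seq
    pos = 0
    for e in t.exons:
        chunk = genomic[pos : pos + e.length]
        genome[t.contig][e.start - 1 : e.end] = list(chunk)
        pos += e.length


def simulate_sequences(
    config: SimulationConfig,
    reference: GenomeAnnotation,
    assembled: GenomeAnnotation,
    truth: GroundTruth,
    max_attempts: int = 50,
) -> dict[str, str]:
    """Genome sequences with planted coding structure.

    Reference protein-coding transcripts and planted coding intergenic
    transcripts receive a long ORF (the latter also the domain motif);
    planted non-coding transcripts are 7-let shuffles of freshly drawn
    coding sequences, re-shuffled until no ORF of >= 100 aa remains.
    """
    rng = np.random.default_rng([config.seed, 2])
    genome = {
        c: list(_random_nt(rng, length))
        for c, length in sorted(reference.contigs.items())
    }
    for locus in reference:
        for t in locus.transcripts:
            if t.biotype == "protein_coding":
                _write_transcript_sequence(
                    genome, t, _random_coding_seq(rng, t.length, with_motif=False)
                )
    coding_set = set(truth.coding_transcripts)
    noncoding_set = set(truth.noncoding_transcripts)
    for locus in assembled:
        for t in locus.transcripts:
            if t.id in coding_set:
                _write_transcript_sequence(
                    genome, t, _random_coding_seq(rng, t.length, with_motif=True)
                )
            elif t.id in noncoding_set:
                source = _random_coding_seq(rng, t.length, with_motif=False)
                for _ in range(max_attempts):
                    shuffled = klet_shuffle(
                        source, k=7, seed=int(rng.integers(2**31))
                    )
                    if not find_orfs(shuffled, min_aa=100):
                        break
                else:
                    raise RuntimeError(
                        "could not destroy ORF structure by shuffling within "
                        f"{max_attempts} attempts"
                    )
                _write_transcript_sequence(genome, t, shuffled)
    return {c: "".join(chars) for c, chars in genome.items()}


def write_fasta(genome: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=contig, description="")
        for contig, seq in sorted(genome.items())
    ]
    seqio_write(records, str(path), "fasta")


# --- counts -------------------------------------------------------------


def simulate_counts(
    config: SimulationConfig,
    truth: GroundTruth,
) -> tuple[pd.DataFrame, SampleTable]:
    """Negative-binomial counts over the categorized locus universe.

    Per-locus base means are log-normal; tissue-specific loci have their
    mean multiplied by 2**planted_log2fc in their tissue and damped by
    ``tissue_leak`` elsewhere (near-zero leak gives them the on/off profile
    real tissue-specific genes show, which the tau index requires); module
    members load on a shared per-sample latent factor that is shifted in the
    module's tissue, inducing both within-module correlation and
    eigengene-tissue correlation.  Variance is mu + alpha * mu^2.
    """
    rng = np.random.default_rng([config.seed, 3])
    loci = sorted(truth.category_of)
    samples = [
        f"{tissue}_{i + 1}"
        for tissue in config.tissues
        for i in range(config.samples_per_tissue)
    ]
    if config.samples_per_tissue < 2:
        raise ValueError("need >= 2 samples per tissue")
    tissue_of = {
        s: s.rsplit("_", 1)[0] for s in samples
    }
    sample_table = SampleTable(tissue_of)
    tissue_idx = {t: i for i, t in enumerate(config.tissues)}
    module_tissue = {
        m: config.tissues[m % len(config.tissues)]
        for m in range(config.n_modules)
    }

    base = np.exp(rng.normal(np.log(100.0), 1.0, size=len(loci)))
    factors = rng.normal(0.0, 1.0, size=(config.n_modules, len(samples)))
    for m in range(config.n_modules):
        for j, s in enumerate(samples):
            if tissue_of[s] == module_tissue[m]:
                factors[m, j] += config.module_tissue_shift

    log_mu = np.tile(np.log(base)[:, None], (1, len(samples)))
    for i, lid in enumerate(loci):
        tissue = truth.tissue_specific_of.get(lid)
        if tissue is not None:
            for j, s in enumerate(samples):
                if tissue_of[s] == tissue:
                    log_mu[i, j] += np.log(2.0) * config.planted_log2fc
                else:
                    # tissue-specific loci are essentially off elsewhere
                    # (tissue_leak = 1 recovers a purely multiplicative effect)
                    log_mu[i, j] += np.log(config.tissue_leak)
        m = truth.module_of.get(lid)
        if m is not None:
            log_mu[i, :] += factors[m, :]
    log_mu += rng.normal(0.0, config.noise_sd, size=log_mu.shape)

    mu = np.exp(log_mu)
    r = 1.0 / config.nb_dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    return (
        pd.DataFrame(counts, index=loci, columns=samples),
        sample_table,
    )


def simulate_presence(
    config: SimulationConfig,
    truth: GroundTruth,
    samples: SampleTable,
    comparisons: dict | None = None,
) -> dict[str, set[str]]:
    """Per-sample presence tables for intergenic transcripts.

    Roughly a third of intergenic transcripts are made tissue-exclusive
    (present in every sample of one tissue only), a third broadly supported,
    and a third sparsely or never detected.
    """
    rng = np.random.default_rng([config.seed, 5])
    intergenic = sorted(
        tid for tid, code in truth.class_code_of.items() if code == "u"
    )
    presence: dict[str, set[str]] = {s: set() for s in samples.samples}
    tissues = samples.tissues
    for i, tid in enumerate(intergenic):
        mode = i % 3
        if mode == 0:
            tissue = tissues[i % len(tissues)]
            for s in samples.samples_of(tissue):
                presence[s].add(tid)
        elif mode == 1:
            chosen = rng.choice(
                samples.samples, size=min(8, len(samples.samples)), replace=False
            )
            for s in chosen:
                presence[s].add(tid)
        elif rng.random() < 0.5:
            presence[rng.choice(samples.samples)].add(tid)
    return presence


def locus_lengths(*annotations: GenomeAnnotation) -> pd.Series:
    """Union-of-exons length per locus over one or more annotations."""
    lengths = {}
    for ann in annotations:
        for locus in ann:
            lengths[locus.id] = locus.exon_union_length
    return pd.Series(lengths, name="length")
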