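"""Candidate lincRNA-gene pair prioritization.

A lncRNA locus and its nearest coding locus become a candidate cis-regulatory
pair when they lie within 100 kb of each other (boundary gap) and fall in the
same co-expression module (grey excluded).  Pairs are classified by
orientation and TSS distance:

bidirectional_promoter   antisense, upstream, TSS distance < 5 kb
                         (divergent, head-to-head arrangement suggesting a
                         shared promoter)
dubious_5prime_extension sense, upstream, TSS distance < 5 kb (possibly a
                         5'UTR extension of the neighboring gene rather than
                         an independent lncRNA)
cis_acting               everything else emitted

The module also ships a curated table of published candidate lincRNA-gene
pairs from Atlantic salmon gonad and pituitary tissues
(``data/salmon_lincrna_pairs.tsv``) used as a fixed input for rule checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from salmotx.position import PositionAnnotation

MAX_PAIR_GAP = 100_000
PROMOTER_TSS_DISTANCE = 5_000

PAIR_CLASSES = ("bidirectional_promoter", "cis_acting", "dubious_5prime_extension")


@dataclass
class LncRnaPair:
    lnc_locus: str
    partner_locus: str
    module: str
    direction: str
    location: str
    gap_bp: int
    tss_distance_bp: int
    functional_class: str = ""


def classify_pair(
    direction: str, location: str, tss_distance_bp: int
) -> str:
    """Functional class from orientation, location, and TSS distance."""
    if location == "upstream" and tss_distance_bp < PROMOTER_TSS_DISTANCE:
        if direction == "antisense":
            return "bidirectional_promoter"
        return "dubious_5prime_extension"
    return "cis_acting"


def candidate_pairs(
    positions: dict[str, PositionAnnotation],
    modules: pd.Series,
    categories: dict[str, str],
    partner_locus_of: dict[str, str],
    max_gap: int = MAX_PAIR_GAP,
) -> list[LncRnaPair]:
    """One candidate pair per lncRNA locus.

    ``positions`` maps lncRNA locus id -> its locus-level positional
    annotation; ``partner_locus_of`` maps partner transcript id -> locus id;
    ``categories`` maps locus id -> category.  lncRNA loci are restricted to
    {known_lncRNA, lincRNA} and partners to coding categories; loci in the
    grey module (or absent from the module table) are excluded.
    """
    lnc_ok = {"known_lncRNA", "lincRNA"}
    partner_ok = {"known_coding", "new_coding"}
    pairs: list[LncRnaPair] = []
    for lnc_locus in sorted(positions):
        pos = positions[lnc_locus]
        if pos.partner_id is None or pos.genic_context == "genic":
            continue
        if categories.get(lnc_locus) not in lnc_ok:
            continue
        partner_locus = partner_locus_of.get(pos.partner_id)
        if partner_locus is None or categories.get(partner_locus) not in partner_ok:
            continue
        m_lnc = modules.get(lnc_locus)
        m_par = modules.get(partner_locus)
        if m_lnc is None or m_par is None or m_lnc == "grey" or m_lnc != m_par:
            continue
        if pos.gap_bp > max_gap:
            continue
        pairs.append(
            LncRnaPair(
                lnc_locus=lnc_locus,
                partner_locus=partner_locus,
                module=m_lnc,
                direction=pos.direction,
                location=pos.location,
                gap_bp=pos.gap_bp,
                tss_distance_bp=pos.tss_distance_bp,
                functional_class=classify_pair(
                    pos.direction, pos.location, pos.tss_distance_bp
                ),
            )
        )
    pairs.sort(key=lambda p: (p.module, p.lnc_locus))
    return pairs


def _tau_cell(locus: str, tau_calls: pd.DataFrame | None) -> str:
    if tau_calls is None or locus not in tau_calls.index:
        return ""
    row = tau_calls.loc[locus]
    tissue = row.get("upregulated_single_tissue")
    mark = "*" if pd.notna(tissue) else ""
    code = _TISSUE_CODES.get(tissue, tissue) if pd.notna(tissue) else ""
    tau = row.get("tau")
    tau_s = f"{tau:.2f}" if pd.notna(tau) else ""
    return f"{tau_s} ({code}){mark}" if code else tau_s


_TISSUE_CODES = {
    "immature_testis": "it",
    "mature_testis": "mt",
    "ovary": "ov",
    "pituitary": "pt",
}


def pair_report(
    pairs: list[LncRnaPair],
    tau_calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tabular pair report with tau annotations.

    The tau cell follows the ``0.92 (it)*`` convention: tau value, tissue
    code in parentheses, and ``*`` when the locus is upregulated in a single
    tissue.  Loci missing from the tau table get a blank cell.
    """
    import warnings

    rows = []
    for p in pairs:
        for locus in (p.lnc_locus, p.partner_locus):
            if tau_calls is not None and locus not in tau_calls.index:
                warnings.warn(f"locus {locus} missing from tau table")
        rows.append(
            {
                "module": p.module,
                "lnc_locus": p.lnc_locus,
                "functional_class": p.functional_class,
                "lnc_tau": _tau_cell(p.lnc_locus, tau_calls),
                "direction": p.direction,
                "location": p.location,
                "gap_bp": p.gap_bp,
                "tss_distance_bp": p.tss_distance_bp,
                "partner_locus": p.partner_locus,
                "partner_tau": _tau_cell(p.partner_locus, tau_calls),
            }
        )
    columns = [
        "module", "lnc_locus", "functional_class", "lnc_tau", "direction",
        "location", "gap_bp", "tss_distance_bp", "partner_locus", "partner_tau",
    ]
    return pd.DataFrame(rows, columns=columns)


def pair_summary(pairs: list[LncRnaPair]) -> pd.DataFrame:
    """Counts per module and per functional class."""
    df = pd.DataFrame(
        [(p.module, p.functional_class) for p in pairs],
        columns=["module", "functional_class"],
    )
    return df.value_counts().rename("n_pairs").reset_index()


def load_curated_pairs() -> pd.DataFrame:
    """Curated Atlantic salmon candidate lincRNA-gene pair table.

    Columns include the lncRNA and partner coordinates, module, direction
    (sense/antisense), location (upstream/downstream of the partner TSS),
    printed distance in bp, the published functional class, and the tau of
    both members.  Distances of upstream pairs are TSS-to-TSS.
    """
    with resources.files("salmotx.data").joinpath(
        "salmon_lincrna_pairs.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def reclassify_curated(table: pd.DataFrame) -> pd.Series:
    """Apply :func:`classify_pair` to each row of a curated pair table,
    treating the printed distance as the TSS distance for upstream pairs."""
    return table.apply(
        lambda row: classify_pair(
            row["direction"], row["location"], int(row["distance_bp"])
        ),
        axis=1,
    )
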