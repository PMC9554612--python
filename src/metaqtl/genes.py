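"""Candidate-gene extraction, expression filtering, known-gene co-location.

Promising regions (≥3 member QTLs by default) are scanned for gene models
overlapping their candidate windows (any ≥1 bp inclusive overlap counts).
Candidates are then filtered on expression: a gene is kept when it exceeds
2 TPM (strictly) in at least one *relevant* tissue — by default grain,
spike and senescing flag leaf, the tissues where grain-protein genes act.
Finally, genes already known to control the trait can be tested for
co-location with the full region intervals.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from metaqtl.anchoring import PhysicalInterval
from metaqtl.meta import MetaQTL

logger = logging.getLogger(__name__)

GENE_COLUMNS = ("gene_id", "chr", "start_bp", "end_bp")

DEFAULT_RELEVANT_TISSUES = ("grain", "spike", "flag-leaf-senescence")
DEFAULT_TPM_THRESHOLD = 2.0
DEFAULT_MIN_MEMBER_QTLS = 3


def load_gene_table(path) -> pd.DataFrame:
    """Gene models from a TSV (gene_id, chr, start_bp, end_bp[, description])."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chr": str})
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table missing column(s): {', '.join(missing)}")
    if "description" not in df.columns:
        df["description"] = ""
    return df


def load_gff3_genes(path) -> pd.DataFrame:
    """Gene features from a GFF3 file via gffutils (in-memory database)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        desc = feat.attributes.get("description", [""])[0] or feat.attributes.get(
            "Name", [""]
        )[0]
        rows.append(
            {
                "gene_id": feat.id,
                "chr": feat.seqid,
                "start_bp": feat.start,
                "end_bp": feat.end,
                "description": desc,
            }
        )
    return pd.DataFrame(rows, columns=list(GENE_COLUMNS) + ["description"])


def genes_in_windows(
    genes: pd.DataFrame,
    windows: Sequence[PhysicalInterval],
    member_counts: Mapping[str, int] | Sequence[MetaQTL],
    min_member_qtls: int = DEFAULT_MIN_MEMBER_QTLS,
) -> dict[str, list[str]]:
    """Gene ids per promising region.

    Only regions backed by at least ``min_member_qtls`` initial QTLs are
    scanned; a gene belongs to a window when its [start, end] overlaps the
    window by ≥1 bp (inclusive bounds).
    """
    if not isinstance(member_counts, Mapping):
        member_counts = {r.mqtl_id: r.n_members for r in member_counts}
    out: dict[str, list[str]] = {}
    for w in windows:
        if not w.anchored or member_counts.get(w.mqtl_id, 0) < min_member_qtls:
            continue
        ws = w.win_start_bp if w.win_start_bp is not None else w.start_bp
        we = w.win_end_bp if w.win_end_bp is not None else w.end_bp
        hit = genes[
            (genes["chr"].astype(str) == w.chromosome)
            & (genes["start_bp"] <= we)
            & (genes["end_bp"] >= ws)
        ]
        out[w.mqtl_id] = hit["gene_id"].tolist()
    return out


def filter_expressed(
    gene_lists: Mapping[str, Sequence[str]],
    expr: pd.DataFrame,
    sample_tissues: Mapping[str, str],
    relevant_tissues: Sequence[str] = DEFAULT_RELEVANT_TISSUES,
    tpm_threshold: float = DEFAULT_TPM_THRESHOLD,
) -> dict[str, list[str]]:
    """Keep genes expressed above threshold in ≥1 relevant tissue.

    ``expr`` is a genes × samples TPM matrix (gene ids as index);
    ``sample_tissues`` maps sample/column name to a tissue tag. The TPM
    comparison is strict (> threshold). Genes absent from the matrix count
    as not expressed (warned).
    """
    relevant = set(relevant_tissues)
    if not relevant:
        raise ValueError("relevant tissue set must not be empty")
    cols = [c for c in expr.columns if sample_tissues.get(c) in relevant]
    if not cols:
        raise ValueError("no expression samples belong to the relevant tissues")

    out: dict[str, list[str]] = {}
    missing: set[str] = set()
    for mqtl_id, gene_ids in gene_lists.items():
        kept = []
        for g in gene_ids:
            if g not in expr.index:
                missing.add(g)
                continue
            if (expr.loc[g, cols] > tpm_threshold).any():
                kept.append(g)
        out[mqtl_id] = kept
    if missing:
        logger.warning(
            "%d gene(s) absent from the expression matrix treated as not expressed",
            len(missing),
        )
    return out


def known_gene_colocalization(
    known: pd.DataFrame, regions: Sequence[PhysicalInterval]
) -> pd.DataFrame:
    """Pairs of (region, known gene) overlapping on the full interval.

    ``known`` uses the gene-table schema. Overlap is inclusive; a gene one
    bp outside the interval does not co-localize.
    """
    rows = []
    for r in regions:
        if not r.anchored:
            continue
        hit = known[
            (known["chr"].astype(str) == r.chromosome)
            & (known["start_bp"] <= r.end_bp)
            & (known["end_bp"] >= r.start_bp)
        ]
        for _, g in hit.iterrows():
            rows.append({"mqtl_id": r.mqtl_id, "gene_id": g["gene_id"]})
    return pd.DataFrame(rows, columns=["mqtl_id", "gene_id"])


def expression_long_table(
    gene_lists: Mapping[str, Sequence[str]],
    expr: pd.DataFrame,
    sample_tissues: Mapping[str, str],
) -> pd.DataFrame:
    """Tall (region, gene, sample, tissue, tpm) table for heat-mapping."""
    rows = []
    for mqtl_id, gene_ids in gene_lists.items():
        for g in gene_ids:
            if g not in expr.index:
                continue
            for c in expr.columns:
                rows.append(
                    {
                        "mqtl_id": mqtl_id, "gene_id": g, "sample": c,
                        "tissue": sample_tissues.get(c, ""), "tpm": float(expr.loc[g, c]),
                    }
                )
    return pd.DataFrame(rows, columns=["mqtl_id", "gene_id", "sample", "tissue", "tpm"])
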