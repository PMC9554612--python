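"""Cross-verification of regions against GWAS marker–trait associations.

A region is *GWAS-verified* when at least one significant SNP (MTA) falls
inside its full physical interval — same chromosome, start ≤ bp ≤ end,
inclusive at both ends. The comparison uses the full anchored interval, not
the 2 Mb candidate-gene window. Duplicate MTAs (same snp_id and bp) are
collapsed before counting.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import pandas as pd

from metaqtl.anchoring import PhysicalInterval

MTA_COLUMNS = ("snp_id", "chr", "bp")


def load_mta_table(path) -> pd.DataFrame:
    """Read an MTA TSV with at least snp_id/chr/bp columns."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chr": str})
    missing = [c for c in MTA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MTA table missing column(s): {', '.join(missing)}")
    return df


def verify_regions(
    regions: Sequence[PhysicalInterval], mtas: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Match MTAs to regions by physical co-location.

    Returns ``(pairs, counts)``: a region↔SNP pair table and a dict with
    ``n_verified_regions``, ``n_colocalized_mtas`` and per-region SNP lists.
    Unanchored regions are skipped with a warning.
    """
    mtas = mtas.drop_duplicates(subset=["snp_id", "bp"])
    skipped = [r.mqtl_id for r in regions if not r.anchored]
    if skipped:
        warnings.warn(f"skipping unanchored region(s): {', '.join(skipped)}")

    rows = []
    for r in regions:
        if not r.anchored:
            continue
        hit = mtas[
            (mtas["chr"].astype(str) == r.chromosome)
            & (mtas["bp"] >= r.start_bp)
            & (mtas["bp"] <= r.end_bp)
        ]
        for _, s in hit.iterrows():
            rows.append({"mqtl_id": r.mqtl_id, "snp_id": s["snp_id"], "bp": int(s["bp"])})
    pairs = pd.DataFrame(rows, columns=["mqtl_id", "snp_id", "bp"])

    per_region = {
        m: sorted(g["snp_id"].tolist()) for m, g in pairs.groupby("mqtl_id")
    }
    counts = {
        "n_verified_regions": pairs["mqtl_id"].nunique(),
        "n_colocalized_mtas": pairs[["snp_id", "bp"]].drop_duplicates().shape[0],
        "per_region": per_region,
    }
    return pairs, counts
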