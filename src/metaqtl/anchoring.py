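"""Genetic-to-physical anchoring of meta-QTL regions.

A region's genetic CI is converted to a base-pair footprint by looking up
its two flanking markers in a marker physical-position table (built offline
by aligning marker sequences to the reference genome). The peak bp is
linear cM↔bp interpolation between the two anchors. Coordinates are
1-based inclusive; downstream overlap tests are inclusive at both ends.

Candidate-gene windows follow the 2 Mb rule: regions with a physical span
under 2 Mb are scanned whole; larger regions are reduced to a 2 Mb window
around the interpolated peak, clipped to the region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from metaqtl.linkage import ConsensusMap
from metaqtl.meta import MetaQTL

logger = logging.getLogger(__name__)

MB = 1_000_000

#: search radius (cM) outside the CI for fallback anchor markers
FALLBACK_CM = 5.0


class AnchorConflictError(ValueError):
    """The two anchor markers sit on different physical chromosomes."""


def load_marker_table(path) -> dict[str, tuple[str, int]]:
    """Read a marker/chr/bp TSV into a lookup dict."""
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chr": str, "bp": int})
    return {m: (c, int(b)) for m, c, b in zip(df["marker"], df["chr"], df["bp"])}


@dataclass
class PhysicalInterval:
    """bp-space footprint of a region, with candidate-gene window."""

    mqtl_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    peak_bp: int
    anchored: bool = True
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)
    win_start_bp: int | None = None
    win_end_bp: int | None = None

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp


def anchor_mqtl(
    m: MetaQTL,
    cmap: ConsensusMap,
    table: Mapping[str, tuple[str, int]],
) -> PhysicalInterval:
    """Anchor one region to physical coordinates.

    Anchors are the region's CI flanking markers; when one is absent from
    the table, the nearest anchorable marker inside the CI is used, then the
    nearest outside within 5 cM (substitutions are noted). Output is
    orientation-safe: start/end are the sorted anchor bp.
    """
    notes: list[str] = []
    chrom_markers = cmap.entries.get(m.chromosome, [])
    pos = dict(chrom_markers)

    lo = _anchorable(m.flank_lo, table, notes) or _fallback(
        chrom_markers, table, m.ci_lo, m.ci_hi, side="lo", notes=notes
    )
    hi = _anchorable(m.flank_hi, table, notes) or _fallback(
        chrom_markers, table, m.ci_lo, m.ci_hi, side="hi", notes=notes
    )
    if lo is None and hi is not None:
        lo = hi
    if hi is None and lo is not None:
        hi = lo
    if lo is None or hi is None:
        logger.warning("%s: no anchorable marker, excluded downstream", m.mqtl_id)
        return PhysicalInterval(
            m.mqtl_id, m.chromosome, 0, 0, 0, anchored=False,
            notes=notes + ["UNANCHORED"],
        )

    chr_lo, bp_lo = table[lo]
    chr_hi, bp_hi = table[hi]
    if chr_lo != chr_hi:
        raise AnchorConflictError(
            f"{m.mqtl_id}: anchors {lo}({chr_lo}) and {hi}({chr_hi}) disagree on chromosome"
        )

    start, end = sorted((bp_lo, bp_hi))
    cm_lo, cm_hi = pos.get(lo, m.ci_lo), pos.get(hi, m.ci_hi)
    if bp_lo == bp_hi or cm_lo == cm_hi:
        peak = bp_lo
        degenerate = bp_lo == bp_hi
        if degenerate:
            notes.append("DEGENERATE_SPAN")
    else:
        frac = (m.position - cm_lo) / (cm_hi - cm_lo)
        peak = round(bp_lo + frac * (bp_hi - bp_lo))
        degenerate = False
    peak = int(min(max(peak, start), end))

    return PhysicalInterval(
        m.mqtl_id, chr_lo, int(start), int(end), peak,
        anchored=True, degenerate=degenerate, notes=notes,
    )


def _anchorable(marker, table, notes) -> str | None:
    if marker is not None and marker in table:
        return marker
    return None


def _fallback(chrom_markers, table, ci_lo, ci_hi, side, notes) -> str | None:
    """Nearest anchorable marker inside the CI, then outside within 5 cM."""
    target = ci_lo if side == "lo" else ci_hi
    inside = [(m, p) for m, p in chrom_markers if ci_lo <= p <= ci_hi and m in table]
    if inside:
        m = min(inside, key=lambda t: abs(t[1] - target))[0]
        notes.append(f"SUBSTITUTED_{side.upper()}:{m}")
        return m
    near = [
        (m, p)
        for m, p in chrom_markers
        if m in table and 0 < (ci_lo - p if side == "lo" else p - ci_hi) <= FALLBACK_CM
    ]
    if near:
        m = min(near, key=lambda t: abs(t[1] - target))[0]
        notes.append(f"SUBSTITUTED_OUTSIDE_{side.upper()}:{m}")
        return m
    return None


def gene_window(p: PhysicalInterval, window_mb: float = 2.0) -> tuple[int, int]:
    """Candidate-gene window for an anchored interval (also stored on it).

    Span < ``window_mb`` → the full interval; otherwise ``window_mb``
    centered on the peak, clipped to the interval.
    """
    if not p.anchored:
        raise ValueError(f"{p.mqtl_id}: cannot window an unanchored interval")
    half = int(window_mb * MB / 2)
    if p.span_bp < window_mb * MB:
        win = (p.start_bp, p.end_bp)
    else:
        win = (
            max(p.start_bp, p.peak_bp - half),
            min(p.end_bp, p.peak_bp + half),
        )
    p.win_start_bp, p.win_end_bp = win
    return win


def intervals_to_bed(intervals) -> pd.DataFrame:
    """Candidate windows as 0-based half-open BED rows (file convention only)."""
    rows = []
    for p in intervals:
        if not p.anchored:
            continue
        ws = p.win_start_bp if p.win_start_bp is not None else p.start_bp
        we = p.win_end_bp if p.win_end_bp is not None else p.end_bp
        rows.append({"chrom": p.chromosome, "start": ws - 1, "end": we, "name": p.mqtl_id})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
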