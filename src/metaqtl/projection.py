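"""Projection of QTLs from their source maps onto the consensus map.

Each QTL is re-expressed in consensus coordinates by local flanking-marker
scaling: the nearest pair of markers bracketing the peak that is shared by
the source and consensus maps (in the same order) defines an affine
transform, and the peak and both CI endpoints are mapped through it.
Endpoints outside the anchor interval extrapolate with the same ratio. The
95% CI also yields the per-QTL position standard deviation used by the
mixture model downstream: ``sigma = CI_width / 3.92`` (a 95% normal
interval spans ±1.96σ).

QTLs that cannot be projected are rejected with a reason code, mirroring
the real-data situation where a sizeable fraction of literature QTLs share
no markers with the consensus map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from metaqtl.catalog import QTLRecord
from metaqtl.linkage import ConsensusMap, LinkageMap

#: Rejection reason codes.
NO_COMMON_MARKERS = "NO_COMMON_MARKERS"
INVERTED_ANCHORS = "INVERTED_ANCHORS"
EXTREME_RATIO = "EXTREME_RATIO"
CHR_ABSENT = "CHR_ABSENT"
ZERO_SPAN = "ZERO_SPAN"

#: Guard band on the consensus/source distance ratio; outside it the local
#: map scales are considered pathological and the QTL is rejected.
DEFAULT_RATIO_BOUNDS = (0.1, 10.0)

#: 95% CI width in units of sigma (2 × 1.96).
CI95_SIGMA_FACTOR = 3.92


@dataclass(frozen=True)
class ProjectedQTL:
    """A QTL re-expressed on the consensus map."""

    record: QTLRecord
    consensus_peak: float
    consensus_ci_lo: float
    consensus_ci_hi: float
    anchor_lo: str
    anchor_hi: str
    scale_ratio: float
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if not (self.consensus_ci_lo <= self.consensus_peak <= self.consensus_ci_hi):
            raise ValueError(
                f"{self.record.qtl_id}: projected peak outside projected CI"
            )
        if self.sigma <= 0:
            raise ValueError(f"{self.record.qtl_id}: nonpositive projected CI width")

    @property
    def qtl_id(self) -> str:
        return self.record.qtl_id

    @property
    def study_id(self) -> str:
        return self.record.study_id

    @property
    def chromosome(self) -> str:
        return self.record.chromosome

    @property
    def sigma(self) -> float:
        """Position standard deviation implied by the projected 95% CI."""
        return (self.consensus_ci_hi - self.consensus_ci_lo) / CI95_SIGMA_FACTOR

    @property
    def variance(self) -> float:
        return self.sigma ** 2


@dataclass(frozen=True)
class Rejection:
    qtl_id: str
    reason: str


@dataclass
class ProjectionReport:
    n_input: int
    n_projected: int
    n_rejected: int
    rejections: list[Rejection] = field(default_factory=list)

    def reasons(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.rejections:
            out[r.reason] = out.get(r.reason, 0) + 1
        return out


def project_qtl(
    q: QTLRecord,
    source: LinkageMap,
    cmap: ConsensusMap,
    ratio_bounds: tuple[float, float] = DEFAULT_RATIO_BOUNDS,
) -> ProjectedQTL | Rejection:
    """Project one completed QTL; returns a :class:`Rejection` on failure.

    Anchor choice: the closest shared markers bracketing the peak on the
    source map; if the peak lies outside all shared markers, the two nearest
    shared markers are used and the transform extrapolates (flagged).
    """
    if q.peak is None or q.ci_lo is None or q.ci_hi is None:
        raise ValueError(f"{q.qtl_id}: record must be completed before projection")
    chrom = q.chromosome
    cons_pos = cmap.positions(chrom)
    if not cons_pos:
        return Rejection(q.qtl_id, CHR_ABSENT)
    src_pos = source.positions(chrom)
    shared = sorted(set(src_pos) & set(cons_pos), key=src_pos.__getitem__)
    if len(shared) < 2:
        return Rejection(q.qtl_id, NO_COMMON_MARKERS)

    lower = [m for m in shared if src_pos[m] <= q.peak]
    upper = [m for m in shared if src_pos[m] >= q.peak]
    extrapolated = False
    if lower and upper:
        m_lo, m_hi = lower[-1], upper[0]
        if m_lo == m_hi:  # peak exactly on a shared marker
            if len(lower) >= 2:
                m_lo = lower[-2]
            else:
                m_hi = upper[1]
    else:  # peak outside the shared-marker span: nearest two, extrapolate
        extrapolated = True
        m_lo, m_hi = (shared[0], shared[1]) if upper else (shared[-2], shared[-1])

    s_lo, s_hi = src_pos[m_lo], src_pos[m_hi]
    c_lo, c_hi = cons_pos[m_lo], cons_pos[m_hi]
    if s_hi == s_lo:
        return Rejection(q.qtl_id, ZERO_SPAN)
    if c_hi <= c_lo:
        return Rejection(q.qtl_id, INVERTED_ANCHORS)
    ratio = (c_hi - c_lo) / (s_hi - s_lo)
    if not (ratio_bounds[0] <= ratio <= ratio_bounds[1]):
        return Rejection(q.qtl_id, EXTREME_RATIO)

    def tx(x: float) -> float:
        return c_lo + (x - s_lo) * ratio

    return ProjectedQTL(
        record=q,
        consensus_peak=tx(q.peak),
        consensus_ci_lo=tx(q.ci_lo),
        consensus_ci_hi=tx(q.ci_hi),
        anchor_lo=m_lo,
        anchor_hi=m_hi,
        scale_ratio=ratio,
        extrapolated=extrapolated,
    )


def project_catalog(
    records: Sequence[QTLRecord],
    maps: Mapping[str, LinkageMap],
    cmap: ConsensusMap,
    ratio_bounds: tuple[float, float] = DEFAULT_RATIO_BOUNDS,
) -> tuple[list[ProjectedQTL], ProjectionReport]:
    """Project a whole compendium; ``maps`` is keyed by study id.

    Order-stable. Raises if any record's study id has no source map.
    """
    unresolved = sorted({q.study_id for q in records} - set(maps))
    if unresolved:
        raise KeyError(f"no source map for study id(s): {', '.join(unresolved)}")
    projected: list[ProjectedQTL] = []
    rejections: list[Rejection] = []
    for q in records:
        result = project_qtl(q, maps[q.study_id], cmap, ratio_bounds)
        if isinstance(result, ProjectedQTL):
            projected.append(result)
        else:
            rejections.append(result)
    report = ProjectionReport(
        n_input=len(records),
        n_projected=len(projected),
        n_rejected=len(rejections),
        rejections=rejections,
    )
    return projected, report
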