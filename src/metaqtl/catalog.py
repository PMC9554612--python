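"""QTL compendium: record model, validation, completion rules and summaries.

A compendium row describes one QTL reported by one linkage-mapping study:
its chromosome, flanking markers, peak position and 95% confidence interval
(CI) in centiMorgans, the LOD support score, the percentage of phenotypic
variance explained (PVE, i.e. R²×100), and the mapping population behind it.

Literature tables are incomplete in predictable ways, so three completion
rules are applied before analysis:

* a missing peak is the midpoint of the two flanking-marker positions;
* a missing LOD score is set to the customary detection threshold of 3.0;
* a missing CI is estimated from population type, size N and PVE with the
  simulation-derived widths ``530/(N·R²)`` (F2/backcross), ``287/(N·R²)``
  (doubled haploids) and ``163/(N·R²)`` (recombinant inbred lines), centered
  symmetrically on the peak.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

POPULATION_TYPES = ("RIL", "DH", "F2", "BC", "NIL")

#: Simulation-derived constants of the 95%-CI width formula constant/(N·R²).
#: Near-isogenic lines carry no published constant; they derive from inbred
#: lines and use the RIL value.
CI_CONSTANTS: dict[str, float] = {
    "F2": 530.0,
    "BC": 530.0,
    "DH": 287.0,
    "RIL": 163.0,
    "NIL": 163.0,
}

#: Default LOD assigned when a study reports a QTL without a score.
DEFAULT_LOD = 3.0

#: Canonical compendium column order (TSV interface).
CATALOG_COLUMNS = (
    "qtl_id", "study_id", "pop_type", "pop_size", "chr",
    "flank_lo", "flank_hi", "peak_cM", "ci_lo_cM", "ci_hi_cM", "lod", "pve_pct",
)

_MANDATORY = ("qtl_id", "study_id", "pop_type", "pop_size", "chr")


class CatalogSchemaError(ValueError):
    """The compendium file is missing a mandatory column."""


class CatalogRowError(ValueError):
    """A compendium row fails validation; carries the offending row number."""


class CompletionError(ValueError):
    """A record cannot be completed (no peak and no resolvable flanks)."""


@dataclass(frozen=True)
class QTLRecord:
    """One initial QTL with study provenance and genetic location.

    Positions are in cM; ``pve`` is a percentage in (0, 100].
    Optional fields are ``None`` until filled by :func:`complete_record`.
    """

    qtl_id: str
    study_id: str
    population_type: str
    population_size: int
    chromosome: str
    flank_lo: str | None = None
    flank_hi: str | None = None
    peak: float | None = None
    ci_lo: float | None = None
    ci_hi: float | None = None
    lod: float | None = None
    pve: float | None = None

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError(f"{self.qtl_id}: chromosome label is empty")
        if self.population_type not in POPULATION_TYPES:
            raise ValueError(
                f"{self.qtl_id}: unknown population type {self.population_type!r}"
            )
        if self.population_size < 2:
            raise ValueError(f"{self.qtl_id}: population size must be >= 2")
        if self.pve is not None and not (0.0 < self.pve <= 100.0):
            raise ValueError(f"{self.qtl_id}: pve must lie in (0, 100], got {self.pve}")
        if self.peak is not None and self.peak < 0:
            raise ValueError(f"{self.qtl_id}: peak cM must be >= 0")
        if self.lod is not None and self.lod < 0:
            raise ValueError(f"{self.qtl_id}: lod must be >= 0")
        if (
            self.ci_lo is not None
            and self.ci_hi is not None
            and self.ci_lo > self.ci_hi
        ):
            raise ValueError(f"{self.qtl_id}: ci_lo > ci_hi")

    @property
    def subgenome(self) -> str:
        """Sub-genome letter, the trailing character of the chromosome label."""
        return self.chromosome[-1]

    @property
    def ci_width(self) -> float | None:
        if self.ci_lo is None or self.ci_hi is None:
            return None
        return self.ci_hi - self.ci_lo

    @property
    def is_complete(self) -> bool:
        return None not in (self.peak, self.ci_lo, self.ci_hi, self.lod)


def estimate_ci(population_type: str, n: int, r2: float) -> float:
    """95%-CI width (cM) from population type, size ``n`` and ``r2``.

    ``r2`` is the *fraction* of variance explained, in (0, 1]. Callers that
    hold PVE as a percentage divide by 100 before calling (the catalog's
    completion rule does this internally).
    """
    if population_type not in CI_CONSTANTS:
        raise ValueError(f"unknown population type {population_type!r}")
    if n < 2:
        raise ValueError("population size must be >= 2")
    if not (0.0 < r2 <= 1.0):
        raise ValueError(f"r2 must lie in (0, 1], got {r2}")
    return CI_CONSTANTS[population_type] / (n * r2)


def complete_record(
    q: QTLRecord,
    marker_positions: Mapping[str, float] | None = None,
) -> QTLRecord:
    """Fill missing peak, LOD and CI by the completion rules.

    ``marker_positions`` maps marker names on the record's source map to cM
    and is only consulted when the peak is absent. Present values are never
    overwritten, so the operation is idempotent.
    """
    peak = q.peak
    if peak is None:
        lo = _resolve(marker_positions, q.flank_lo)
        hi = _resolve(marker_positions, q.flank_hi)
        if lo is None or hi is None:
            raise CompletionError(
                f"{q.qtl_id}: peak absent and flanking positions unresolvable"
            )
        peak = (lo + hi) / 2.0

    lod = q.lod if q.lod is not None else DEFAULT_LOD

    ci_lo, ci_hi = q.ci_lo, q.ci_hi
    if ci_lo is None or ci_hi is None:
        if q.pve is None:
            raise CompletionError(f"{q.qtl_id}: CI absent and no PVE to estimate it")
        width = estimate_ci(q.population_type, q.population_size, q.pve / 100.0)
        ci_lo = max(0.0, peak - width / 2.0)
        ci_hi = peak + width / 2.0

    return replace(q, peak=peak, lod=lod, ci_lo=ci_lo, ci_hi=ci_hi)


def _resolve(positions: Mapping[str, float] | None, marker: str | None) -> float | None:
    if positions is None or marker is None:
        return None
    if marker in positions:
        return positions[marker]
    # case-insensitive fallback; no fuzzier normalization
    folded = marker.casefold()
    for name, pos in positions.items():
        if name.casefold() == folded:
            return pos
    return None


def load_catalog(path) -> list[QTLRecord]:
    """Read a compendium TSV into validated records.

    Empty cells are missing values. Duplicate ``qtl_id`` values are
    auto-suffixed (``.2``, ``.3`` …) and logged; row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise CatalogSchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[QTLRecord] = []
    seen: Counter[str] = Counter()
    for i, row in enumerate(df.to_dict("records")):
        rownum = i + 2  # 1-based, after header
        qtl_id = row["qtl_id"].strip()
        seen[qtl_id] += 1
        if seen[qtl_id] > 1:
            new_id = f"{qtl_id}.{seen[qtl_id]}"
            logger.warning("row %d: duplicate qtl_id %r renamed to %r", rownum, qtl_id, new_id)
            qtl_id = new_id
        try:
            records.append(
                QTLRecord(
                    qtl_id=qtl_id,
                    study_id=row["study_id"].strip(),
                    population_type=row["pop_type"].strip(),
                    population_size=int(row["pop_size"]),
                    chromosome=row["chr"].strip(),
                    flank_lo=row.get("flank_lo", "").strip() or None,
                    flank_hi=row.get("flank_hi", "").strip() or None,
                    peak=_num(row.get("peak_cM")),
                    ci_lo=_num(row.get("ci_lo_cM")),
                    ci_hi=_num(row.get("ci_hi_cM")),
                    lod=_num(row.get("lod")),
                    pve=_num(row.get("pve_pct")),
                )
            )
        except ValueError as exc:
            raise CatalogRowError(f"row {rownum}: {exc}") from exc
    return records


def catalog_to_frame(records: Iterable[QTLRecord]) -> pd.DataFrame:
    """Round-trip records back to the TSV column layout."""
    rows = [
        {
            "qtl_id": q.qtl_id, "study_id": q.study_id, "pop_type": q.population_type,
            "pop_size": q.population_size, "chr": q.chromosome,
            "flank_lo": q.flank_lo, "flank_hi": q.flank_hi, "peak_cM": q.peak,
            "ci_lo_cM": q.ci_lo, "ci_hi_cM": q.ci_hi, "lod": q.lod, "pve_pct": q.pve,
        }
        for q in records
    ]
    return pd.DataFrame(rows, columns=list(CATALOG_COLUMNS))


def _num(value: str | None) -> float | None:
    if value is None:
        return None
    value = value.strip()
    if not value:
        return None
    return float(value)


# CI/LOD/PVE histogram bin labels used in catalog summaries.
CI_BINS = ("<5", "5-20", ">20")
PVE_BINS = ("<10", "10-20", ">20")
LOD_BINS = ("<=10", ">10")


@dataclass
class CatalogSummary:
    """Descriptive counts over a completed compendium."""

    n_records: int
    per_chromosome: dict[str, int] = field(default_factory=dict)
    per_subgenome: dict[str, int] = field(default_factory=dict)
    ci_bins: dict[str, int] = field(default_factory=dict)
    lod_bins: dict[str, int] = field(default_factory=dict)
    pve_bins: dict[str, int] = field(default_factory=dict)


def summarize_catalog(records: Sequence[QTLRecord]) -> CatalogSummary:
    """Chromosome/sub-genome counts and CI/LOD/PVE histograms.

    CI bins: <5, 5–20, >20 cM (boundaries fall in the middle bin);
    PVE bins: <10, 10–20, >20 percent; LOD split at 10.
    Bin counts always sum to the record count.
    """
    per_chrom: Counter[str] = Counter()
    per_sub: Counter[str] = Counter()
    ci_bins = dict.fromkeys(CI_BINS, 0)
    pve_bins = dict.fromkeys(PVE_BINS, 0)
    lod_bins = dict.fromkeys(LOD_BINS, 0)

    for q in records:
        per_chrom[q.chromosome] += 1
        per_sub[q.subgenome] += 1
        w = q.ci_width
        if w is not None:
            ci_bins["<5" if w < 5 else ("5-20" if w <= 20 else ">20")] += 1
        if q.pve is not None:
            pve_bins["<10" if q.pve < 10 else ("10-20" if q.pve <= 20 else ">20")] += 1
        if q.lod is not None:
            lod_bins[">10" if q.lod > 10 else "<=10"] += 1

    return CatalogSummary(
        n_records=len(records),
        per_chromosome=dict(per_chrom),
        per_subgenome=dict(per_sub),
        ci_bins=ci_bins,
        lod_bins=lod_bins,
        pve_bins=pve_bins,
    )
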