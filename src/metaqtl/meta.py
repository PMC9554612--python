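"""Meta-QTL construction: clustering projected QTLs into consensus regions.

Per chromosome, projected QTLs are clustered with the known-variance
Gaussian mixture (see :mod:`metaqtl.mixture`); the chosen model's
max-posterior assignment partitions the QTLs, and each cluster becomes a
region whose consensus position is the inverse-variance weighted mean of
member peaks with variance 1/Σ(1/s_i²) and a ±1.96σ 95% CI.

Accounting follows the field's conventions:

* members whose own peak falls outside the region's 95% CI are set aside as
  *non-supporting* (one refinement pass: remove, recompute, stop);
* clusters reduced to a single QTL are *singletons*, not regions;
* a region whose members come from ≥2 distinct studies is an **MQTL**;
  one fed by a single study is a **QTL hotspot**.

Region ids are ordinal by position within the chromosome: ``MQTL3A.2`` is
the second MQTL on 3A; hotspots are ``QTLhotspot_3A`` (suffixed ``.n`` only
when a chromosome carries several).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from metaqtl.linkage import ConsensusMap
from metaqtl.mixture import HeteroscedasticGaussianMixture, fit_mixture, select_model
from metaqtl.projection import ProjectedQTL

CLASS_MQTL = "MQTL"
CLASS_HOTSPOT = "HOTSPOT"

#: two-sided 95% normal quantile
_Z95 = 1.96


@dataclass
class MetaQTL:
    """A consensus genomic region built from ≥2 clustered QTLs."""

    mqtl_id: str
    chromosome: str
    position: float
    ci_lo: float
    ci_hi: float
    members: list[str]
    n_studies: int
    avg_lod: float
    avg_pve: float
    klass: str
    flank_lo: str | None = None
    flank_hi: str | None = None

    def __post_init__(self) -> None:
        if not (self.ci_lo <= self.position <= self.ci_hi):
            raise ValueError(f"{self.mqtl_id}: position outside CI")
        if len(self.members) < 2:
            raise ValueError(f"{self.mqtl_id}: a region needs >= 2 members")

    @property
    def ci_width(self) -> float:
        return self.ci_hi - self.ci_lo

    @property
    def n_members(self) -> int:
        return len(self.members)


def _consensus(members: Sequence[ProjectedQTL]) -> tuple[float, float, float]:
    """Inverse-variance weighted position, its variance, and the 95% half-width."""
    w = np.array([1.0 / m.variance for m in members])
    x = np.array([m.consensus_peak for m in members])
    pos = float((w * x).sum() / w.sum())
    var = float(1.0 / w.sum())
    return pos, var, _Z95 * np.sqrt(var)


def build_metaqtls(
    fit: HeteroscedasticGaussianMixture,
    members: Sequence[ProjectedQTL],
    chromosome: str,
    cmap: ConsensusMap | None = None,
) -> tuple[list[MetaQTL], list[ProjectedQTL], list[ProjectedQTL]]:
    """Turn one chromosome's mixture fit into regions.

    Returns ``(regions, singletons, non_supporting)``. Region ids are
    assigned afterwards by :func:`_assign_ids` in position order.
    """
    if len(members) != fit.responsibilities_.shape[0]:
        raise ValueError("fit and members disagree on n")
    labels = np.argmax(fit.responsibilities_, axis=1)

    singletons: list[ProjectedQTL] = []
    non_supporting: list[ProjectedQTL] = []
    clusters: list[list[ProjectedQTL]] = []
    for k in range(fit.n_components):
        group = [m for m, lab in zip(members, labels) if lab == k]
        if not group:
            continue
        pos, _, half = _consensus(group)
        # one refinement pass: drop members peaking outside the 95% CI
        supported = [
            m for m in group if pos - half <= m.consensus_peak <= pos + half
        ]
        outside = [m for m in group if m not in supported]
        non_supporting.extend(outside)
        if len(supported) == 1:
            # a cluster melted by refinement leaves a lone singleton
            singletons.extend(supported)
        elif len(supported) >= 2:
            clusters.append(supported)

    regions: list[MetaQTL] = []
    for group in clusters:
        pos, _, half = _consensus(group)
        studies = {m.study_id for m in group}
        klass = CLASS_MQTL if len(studies) >= 2 else CLASS_HOTSPOT
        lo, hi = pos - half, pos + half
        flank_lo, flank_hi = _flanking_markers(cmap, chromosome, lo, hi)
        regions.append(
            MetaQTL(
                mqtl_id="",  # assigned below in position order
                chromosome=chromosome,
                position=pos,
                ci_lo=lo,
                ci_hi=hi,
                members=[m.qtl_id for m in group],
                n_studies=len(studies),
                avg_lod=float(np.mean([m.record.lod for m in group])),
                avg_pve=float(np.mean([m.record.pve for m in group])),
                klass=klass,
                flank_lo=flank_lo,
                flank_hi=flank_hi,
            )
        )
    regions.sort(key=lambda r: r.position)
    _assign_ids(regions, chromosome)
    return regions, singletons, non_supporting


def _assign_ids(regions: list[MetaQTL], chromosome: str) -> None:
    n_hot = sum(1 for r in regions if r.klass == CLASS_HOTSPOT)
    i_mqtl = i_hot = 0
    for r in regions:
        if r.klass == CLASS_MQTL:
            i_mqtl += 1
            r.mqtl_id = f"MQTL{chromosome}.{i_mqtl}"
        else:
            i_hot += 1
            r.mqtl_id = (
                f"QTLhotspot_{chromosome}"
                if n_hot == 1
                else f"QTLhotspot_{chromosome}.{i_hot}"
            )


def _flanking_markers(
    cmap: ConsensusMap | None, chrom: str, lo: float, hi: float
) -> tuple[str | None, str | None]:
    """Nearest consensus markers outside the region CI."""
    if cmap is None:
        return None, None
    markers = cmap.entries.get(chrom, [])
    below = [(m, p) for m, p in markers if p < lo]
    above = [(m, p) for m, p in markers if p > hi]
    return (below[-1][0] if below else None), (above[0][0] if above else None)


def meta_analyze(
    projected: Sequence[ProjectedQTL],
    cmap: ConsensusMap | None = None,
    k_max: int = 10,
    n_restarts: int = 5,
    seed: int = 0,
) -> tuple[list[MetaQTL], list[ProjectedQTL], list[ProjectedQTL], dict]:
    """Full per-chromosome meta-analysis over a projected compendium.

    For each chromosome, fits K = 1..min(n, k_max) mixtures, picks K by the
    five-criterion vote, and builds regions. Returns
    ``(regions, singletons, non_supporting, diagnostics)`` with diagnostics
    holding the per-chromosome criteria tables and chosen K.
    """
    by_chrom: dict[str, list[ProjectedQTL]] = {}
    for p in projected:
        by_chrom.setdefault(p.chromosome, []).append(p)

    regions: list[MetaQTL] = []
    singletons: list[ProjectedQTL] = []
    non_supporting: list[ProjectedQTL] = []
    diagnostics: dict[str, dict] = {}

    for chrom in sorted(by_chrom):
        group = by_chrom[chrom]
        if len(group) == 1:
            singletons.extend(group)
            diagnostics[chrom] = {"n": 1, "chosen_k": 0, "criteria": {}}
            continue
        x = np.array([p.consensus_peak for p in group])
        s2 = np.array([p.variance for p in group])
        fits = {
            k: fit_mixture(x, s2, k, n_restarts=n_restarts, seed=seed)
            for k in range(1, min(len(group), k_max) + 1)
        }
        chosen_k, winners = select_model(fits)
        r, s, ns = build_metaqtls(fits[chosen_k], group, chrom, cmap)
        regions.extend(r)
        singletons.extend(s)
        non_supporting.extend(ns)
        diagnostics[chrom] = {
            "n": len(group),
            "chosen_k": chosen_k,
            "winners": winners,
            "criteria": {k: f.criteria_ for k, f in fits.items()},
        }
    return regions, singletons, non_supporting, diagnostics


def regions_to_frame(regions: Sequence[MetaQTL]) -> pd.DataFrame:
    """Region table in the standard reporting layout."""
    rows = [
        {
            "name": r.mqtl_id,
            "chr": r.chromosome,
            "position_cM": r.position,
            "ci_95": r.ci_width,
            "flanking_markers": "/".join(filter(None, (r.flank_lo, r.flank_hi))),
            "n_qtls": r.n_members,
            "avg_lod": r.avg_lod,
            "avg_pve": r.avg_pve,
            "class": r.klass,
        }
        for r in regions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "name", "chr", "position_cM", "ci_95", "flanking_markers",
            "n_qtls", "avg_lod", "avg_pve", "class",
        ],
    )


def summarize_regions(
    regions: Sequence[MetaQTL], projected: Sequence[ProjectedQTL]
) -> dict:
    """Descriptive region statistics, including the CI fold reduction
    (mean initial projected-QTL CI width over mean region CI width)."""
    init_widths = [p.consensus_ci_hi - p.consensus_ci_lo for p in projected]
    region_widths = [r.ci_width for r in regions]
    fold = (
        float(np.mean(init_widths) / np.mean(region_widths))
        if regions and projected and np.mean(region_widths) > 0
        else None
    )
    per_chrom: dict[str, int] = {}
    per_sub: dict[str, int] = {}
    bins = {"=2": 0, "3-4": 0, ">=5": 0}
    for r in regions:
        per_chrom[r.chromosome] = per_chrom.get(r.chromosome, 0) + 1
        sub = r.chromosome[-1]
        per_sub[sub] = per_sub.get(sub, 0) + 1
        if r.n_members == 2:
            bins["=2"] += 1
        elif r.n_members <= 4:
            bins["3-4"] += 1
        else:
            bins[">=5"] += 1

    def _stats(vals):
        if not vals:
            return {"min": None, "max": None, "mean": None}
        return {"min": float(np.min(vals)), "max": float(np.max(vals)),
                "mean": float(np.mean(vals))}

    return {
        "n_regions": len(regions),
        "n_mqtl": sum(1 for r in regions if r.klass == CLASS_MQTL),
        "n_hotspot": sum(1 for r in regions if r.klass == CLASS_HOTSPOT),
        "fold_reduction": fold,
        "per_chromosome": per_chrom,
        "per_subgenome": per_sub,
        "member_bins": bins,
        "ci_width": _stats(region_widths),
        "avg_lod": _stats([r.avg_lod for r in regions]),
        "avg_pve": _stats([r.avg_pve for r in regions]),
    }
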