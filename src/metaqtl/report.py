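"""Breeders'-MQTL filtering and summary reports over region tables.

The breeders' filter distils a region table down to the handful of regions
a marker-assisted breeding program could use directly: a tight confidence
interval (CI < 2.5 cM), a sizeable effect (average PVE > 10%), solid
support (average LOD > 3.5), and dependence on at least three initial QTLs
from more than one study (hotspots are excluded). All numeric comparisons
are strict except the member count (≥).

The package ships two reference region tables (the 57-MQTL and 7-hotspot
tables of the wheat grain-protein meta-analysis this toolkit reproduces) as
TSV fixtures, plus a JSON record of that study's printed count arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from metaqtl.meta import CLASS_HOTSPOT, CLASS_MQTL, MetaQTL, regions_to_frame

REGION_COLUMNS = (
    "name", "chr", "position_cM", "ci_95", "flanking_markers",
    "n_qtls", "avg_lod", "avg_pve", "class",
)


@dataclass(frozen=True)
class BreederCriteria:
    """Thresholds of the breeders'-MQTL filter (strict comparisons)."""

    max_ci: float = 2.5      # cM, CI width strictly below
    min_pve: float = 10.0    # percent, strictly above
    min_lod: float = 3.5     # strictly above
    min_members: int = 3     # at least this many initial QTLs
    require_multi_study: bool = True  # exclude single-study hotspots

    def __post_init__(self) -> None:
        if min(self.max_ci, self.min_pve, self.min_lod, self.min_members) <= 0:
            raise ValueError("all thresholds must be positive")


def _as_frame(regions) -> pd.DataFrame:
    if isinstance(regions, pd.DataFrame):
        return regions
    return regions_to_frame(list(regions))


def breeders_filter(
    regions: pd.DataFrame | Sequence[MetaQTL],
    criteria: BreederCriteria = BreederCriteria(),
) -> list[str]:
    """Region names passing the breeders' criteria, in table order."""
    df = _as_frame(regions)
    keep = (
        (df["ci_95"] < criteria.max_ci)
        & (df["avg_pve"] > criteria.min_pve)
        & (df["avg_lod"] > criteria.min_lod)
        & (df["n_qtls"] >= criteria.min_members)
    )
    if criteria.require_multi_study and "class" in df.columns:
        keep &= df["class"] == CLASS_MQTL
    return df.loc[keep, "name"].tolist()


def region_report(regions: pd.DataFrame | Sequence[MetaQTL]) -> dict:
    """Deterministic summary of a region table.

    Covers counts (total, per class, per chromosome and sub-genome),
    member-count bins, min/max/mean of CI width, average LOD and PVE, and
    the cross-tab of the four breeders' criteria.
    """
    df = _as_frame(regions)
    if df.empty:
        return {
            "n_regions": 0, "per_class": {}, "per_chromosome": {},
            "per_subgenome": {}, "member_bins": {}, "stats": {}, "criteria_crosstab": {},
        }
    df = df.copy()
    df["subgenome"] = df["chr"].astype(str).str[-1]

    def _stats(col: str) -> dict:
        v = np.sort(df[col].astype(float).to_numpy())  # order-independent mean
        return {"min": float(v[0]), "max": float(v[-1]), "mean": float(v.mean())}

    bins = {
        "=2": int((df["n_qtls"] == 2).sum()),
        "3-4": int(df["n_qtls"].between(3, 4).sum()),
        ">=5": int((df["n_qtls"] >= 5).sum()),
    }
    crit = BreederCriteria()
    flags = pd.DataFrame(
        {
            "ci": df["ci_95"] < crit.max_ci,
            "pve": df["avg_pve"] > crit.min_pve,
            "lod": df["avg_lod"] > crit.min_lod,
            "members": df["n_qtls"] >= crit.min_members,
        }
    )
    crosstab = {
        f"{int(a)}{int(b)}{int(c)}{int(d)}": int(n)
        for (a, b, c, d), n in flags.value_counts().sort_index().items()
    }
    per_class = (
        df["class"].value_counts().sort_index().to_dict() if "class" in df else {}
    )
    return {
        "n_regions": int(len(df)),
        "per_class": {str(k): int(v) for k, v in per_class.items()},
        "per_chromosome": {
            str(k): int(v) for k, v in df["chr"].value_counts().sort_index().items()
        },
        "per_subgenome": {
            str(k): int(v)
            for k, v in df["subgenome"].value_counts().sort_index().items()
        },
        "member_bins": bins,
        "stats": {
            "ci_95": _stats("ci_95"),
            "avg_lod": _stats("avg_lod"),
            "avg_pve": _stats("avg_pve"),
        },
        "criteria_crosstab": crosstab,
    }


def report_markdown(report: dict) -> str:
    """Render a region report as a small Markdown document."""
    lines = [f"# Region report", "", f"Total regions: {report['n_regions']}", ""]
    for key in ("per_class", "per_chromosome", "per_subgenome", "member_bins"):
        if report.get(key):
            lines.append(f"## {key.replace('_', ' ')}")
            for k, v in report[key].items():
                lines.append(f"- {k}: {v}")
            lines.append("")
    if report.get("stats"):
        lines.append("## statistics")
        for col, st in report["stats"].items():
            lines.append(
                f"- {col}: min {st['min']:.2f}, max {st['max']:.2f}, mean {st['mean']:.2f}"
            )
    return "\n".join(lines) + "\n"


def _data_path(name: str):
    return resources.files("metaqtl.data").joinpath(name)


def load_printed_regions(which: str = "all") -> pd.DataFrame:
    """Packaged reference region tables: ``mqtl``, ``hotspot`` or ``all``."""
    frames = []
    if which in ("mqtl", "all"):
        with resources.as_file(_data_path("mqtl_table.tsv")) as p:
            t = pd.read_csv(p, sep="\t")
        t["class"] = CLASS_MQTL
        frames.append(t)
    if which in ("hotspot", "all"):
        with resources.as_file(_data_path("hotspot_table.tsv")) as p:
            t = pd.read_csv(p, sep="\t")
        t["class"] = CLASS_HOTSPOT
        frames.append(t)
    if not frames:
        raise ValueError(f"unknown table selector {which!r}")
    return pd.concat(frames, ignore_index=True)


def load_printed_counts() -> dict:
    """Packaged count arithmetic of the reference wheat analysis."""
    with resources.as_file(_data_path("printed_counts.json")) as p:
        return json.loads(p.read_text())
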