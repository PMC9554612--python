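"""Linkage maps and order-consistent consensus-map merging.

A consensus map places every marker from a set of component linkage maps on
one coordinate system per chromosome while (a) preserving each component
map's marker order and (b) minimizing the mean absolute error between
consensus inter-marker distances and the distances observed in each
component map. Both requirements are linear, so the merge is a linear
program:

    minimize   Σ_j (1/n_j) Σ_{(a,b) adjacent in map j} | (y_b − y_a) − d_j(a,b) |
    subject to y_b − y_a ≥ min_gap   for every retained ordered pair (a,b)
               y ≥ 0

where y are the consensus positions and d_j the component distances. When
component maps disagree on marker order the ordinal constraint set contains
directed cycles; a greedy approximate minimum feedback arc set removes the
least-supported constraint from each remaining cycle (exact minimization is
NP-hard). Positions are shifted so each chromosome starts at 0 cM. Because
the MAE objective often has a flat optimal face (e.g. two maps disagreeing
on a distance leave an interval of equally good positions), a deterministic
tie-break picks the midpoint of that face: the position-sum minimal and
maximal optimal solutions are computed and averaged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse import coo_matrix

logger = logging.getLogger(__name__)

#: Minimum consensus spacing making strict order LP-representable.
DEFAULT_MIN_GAP = 1e-6


@dataclass
class LinkageMap:
    """Ordered marker→cM assignments per chromosome.

    ``entries`` maps a chromosome label to an ordered list of
    ``(marker, position_cM)`` with strictly increasing positions and unique
    marker names within the chromosome.
    """

    map_id: str
    entries: dict[str, list[tuple[str, float]]]

    def __post_init__(self) -> None:
        for chrom, markers in self.entries.items():
            names = [m for m, _ in markers]
            if len(set(names)) != len(names):
                raise ValueError(f"{self.map_id}/{chrom}: duplicate marker names")
            pos = [p for _, p in markers]
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValueError(
                    f"{self.map_id}/{chrom}: positions must strictly increase"
                )

    def positions(self, chrom: str) -> dict[str, float]:
        """Marker→cM lookup for one chromosome ({} if absent)."""
        return dict(self.entries.get(chrom, []))

    @property
    def chromosomes(self) -> list[str]:
        return list(self.entries)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, map_id: str | None = None) -> "LinkageMap":
        """Build from a tidy table with columns map_id, chr, marker, position_cM."""
        if map_id is None:
            ids = df["map_id"].unique()
            if len(ids) != 1:
                raise ValueError("frame holds several map_ids; pass map_id explicitly")
            map_id = str(ids[0])
        entries: dict[str, list[tuple[str, float]]] = {}
        for chrom, sub in df.groupby("chr", sort=False):
            sub = sub.sort_values("position_cM", kind="stable")
            entries[str(chrom)] = list(
                zip(sub["marker"].astype(str), sub["position_cM"].astype(float))
            )
        return cls(map_id=map_id, entries=entries)

    @classmethod
    def read_tsv(cls, path, map_id: str | None = None) -> "LinkageMap":
        return cls.from_frame(pd.read_csv(path, sep="\t"), map_id=map_id)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"map_id": self.map_id, "chr": c, "marker": m, "position_cM": p}
            for c, markers in self.entries.items()
            for m, p in markers
        ]
        return pd.DataFrame(rows, columns=["map_id", "chr", "marker", "position_cM"])


@dataclass
class ConsensusMap(LinkageMap):
    """A merged map carrying per-marker provenance (which components hold it)."""

    provenance: dict[str, dict[str, tuple[str, ...]]] = field(default_factory=dict)

    def n_source_maps(self, chrom: str, marker: str) -> int:
        return len(self.provenance.get(chrom, {}).get(marker, ()))

    def to_frame(self) -> pd.DataFrame:
        df = super().to_frame()
        df["n_source_maps"] = [
            self.n_source_maps(c, m) for c, m in zip(df["chr"], df["marker"])
        ]
        return df


@dataclass(frozen=True)
class OrdinalConstraint:
    """A directed adjacency a→b on some chromosome, with supporting map ids."""

    chrom: str
    a: str
    b: str
    maps: tuple[str, ...]


def _adjacency_constraints(maps: Sequence[LinkageMap]) -> dict[str, dict[tuple[str, str], set[str]]]:
    """Per chromosome: directed adjacent pair -> supporting map ids."""
    out: dict[str, dict[tuple[str, str], set[str]]] = {}
    for lm in maps:
        for chrom, markers in lm.entries.items():
            edges = out.setdefault(chrom, {})
            for (a, _), (b, _) in zip(markers, markers[1:]):
                edges.setdefault((a, b), set()).add(lm.map_id)
    return out


def resolve_order_conflicts(
    maps: Sequence[LinkageMap],
) -> tuple[list[OrdinalConstraint], list[OrdinalConstraint]]:
    """Split ordinal constraints into an acyclic retained set and removals.

    Constraints are the directed adjacencies of every component map. Cycles
    (maps disagreeing on order) are broken greedily: from each remaining
    cycle delete the edge supported by the fewest component maps, breaking
    ties toward edges whose supporting maps carry fewer markers, then
    lexicographically. Removed constraints are reported so the caller can
    log them.
    """
    map_sizes = {
        lm.map_id: sum(len(v) for v in lm.entries.values()) for lm in maps
    }
    retained: list[OrdinalConstraint] = []
    removed: list[OrdinalConstraint] = []
    for chrom, edges in _adjacency_constraints(maps).items():
        g = nx.DiGraph()
        for (a, b), support in edges.items():
            g.add_edge(a, b, support=frozenset(support))
        while True:
            try:
                cycle = nx.find_cycle(g)
            except nx.NetworkXNoCycle:
                break
            def _key(edge: tuple[str, str]) -> tuple:
                a, b = edge[0], edge[1]
                support = g.edges[a, b]["support"]
                return (len(support), sum(map_sizes[m] for m in support), a, b)
            worst = min(((e[0], e[1]) for e in cycle), key=_key)
            removed.append(
                OrdinalConstraint(chrom, worst[0], worst[1], tuple(sorted(g.edges[worst]["support"])))
            )
            g.remove_edge(*worst)
        for a, b, data in g.edges(data=True):
            retained.append(OrdinalConstraint(chrom, a, b, tuple(sorted(data["support"]))))
    return retained, removed


def merge_maps(
    maps: Sequence[LinkageMap],
    min_gap: float = DEFAULT_MIN_GAP,
    map_id: str = "consensus",
) -> ConsensusMap:
    """Merge component linkage maps into one consensus map.

    Solves the mean-absolute-error LP per chromosome (see module docstring)
    with scipy's HiGHS backend. All markers of all component maps are
    retained; only conflicting *ordinal constraints* are dropped, not
    markers. Chromosomes carrying fewer than two markers in total are passed
    through with a warning.
    """
    if not maps:
        raise ValueError("merge_maps needs at least one linkage map")

    retained, removed = resolve_order_conflicts(maps)
    if removed:
        logger.warning(
            "removed %d conflicting ordinal constraint(s): %s",
            len(removed),
            "; ".join(f"{c.chrom}:{c.a}->{c.b}" for c in removed[:10]),
        )
    retained_by_chrom: dict[str, list[OrdinalConstraint]] = {}
    for c in retained:
        retained_by_chrom.setdefault(c.chrom, []).append(c)
    removed_pairs = {(c.chrom, c.a, c.b) for c in removed}

    chroms: list[str] = []
    for lm in maps:
        for chrom in lm.entries:
            if chrom not in chroms:
                chroms.append(chrom)

    entries: dict[str, list[tuple[str, float]]] = {}
    provenance: dict[str, dict[str, tuple[str, ...]]] = {}
    for chrom in chroms:
        prov: dict[str, list[str]] = {}
        for lm in maps:
            for m, _ in lm.entries.get(chrom, []):
                prov.setdefault(m, []).append(lm.map_id)
        provenance[chrom] = {m: tuple(v) for m, v in prov.items()}

        markers = list(prov)
        if len(markers) < 2:
            warnings.warn(f"chromosome {chrom}: fewer than 2 markers, passed through")
            entries[chrom] = [(markers[0], 0.0)] if markers else []
            continue

        entries[chrom] = _merge_chromosome(
            chrom, markers, maps, retained_by_chrom.get(chrom, []), removed_pairs, min_gap
        )

    return ConsensusMap(map_id=map_id, entries=entries, provenance=provenance)


def _merge_chromosome(
    chrom: str,
    markers: list[str],
    maps: Sequence[LinkageMap],
    constraints: list[OrdinalConstraint],
    removed_pairs: set[tuple[str, str, str]],
    min_gap: float,
) -> list[tuple[str, float]]:
    idx = {m: i for i, m in enumerate(markers)}
    n_y = len(markers)

    # objective |.| terms: one auxiliary variable per (map, adjacent pair);
    # pairs whose ordinal constraint was removed as conflicting are excluded
    # from the objective too (their distance contradicts the retained order).
    terms: list[tuple[int, int, float, float]] = []  # (ia, ib, d, weight)
    for lm in maps:
        chrom_markers = lm.entries.get(chrom, [])
        if len(chrom_markers) < 2:
            continue
        w = 1.0 / (len(chrom_markers) - 1)
        for (a, pa), (b, pb) in zip(chrom_markers, chrom_markers[1:]):
            if (chrom, a, b) in removed_pairs:
                continue
            terms.append((idx[a], idx[b], pb - pa, w))

    n_t = len(terms)
    n_var = n_y + n_t
    cost = np.zeros(n_var)
    for t, (_, _, _, w) in enumerate(terms):
        cost[n_y + t] = w

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    rhs: list[float] = []
    r = 0
    for t, (ia, ib, d, _) in enumerate(terms):
        # (y_b − y_a) − t ≤ d
        rows += [r, r, r]
        cols += [ib, ia, n_y + t]
        vals += [1.0, -1.0, -1.0]
        rhs.append(d)
        r += 1
        # (y_a − y_b) − t ≤ −d
        rows += [r, r, r]
        cols += [ia, ib, n_y + t]
        vals += [1.0, -1.0, -1.0]
        rhs.append(-d)
        r += 1
    for c in constraints:
        # y_a − y_b ≤ −min_gap
        rows += [r, r]
        cols += [idx[c.a], idx[c.b]]
        vals += [1.0, -1.0]
        rhs.append(-min_gap)
        r += 1

    # generous position box: consensus length cannot exceed the summed
    # component lengths
    box = sum(
        lm.entries[chrom][-1][1] - lm.entries[chrom][0][1]
        for lm in maps
        if len(lm.entries.get(chrom, [])) >= 2
    ) + 10.0
    bounds = [(0.0, box)] * n_y + [(0.0, None)] * n_t

    a_ub = coo_matrix((vals, (rows, cols)), shape=(r, n_var))
    b_ub = np.asarray(rhs)
    res = linprog(cost, A_ub=a_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - LP is always feasible by construction
        raise RuntimeError(f"consensus LP failed on {chrom}: {res.message}")

    # tie-break among equally optimal solutions: midpoint of the optimal
    # face, obtained by re-solving for the position-sum extremes subject to
    # optimality of the MAE objective, then averaging (the optimal set is
    # convex, so the average stays optimal). The map is pinned at an anchor
    # marker (the first marker of the phase-1 solution) so the extremes
    # explore genuine spacing freedom, not whole-map translation.
    f_star = float(res.fun)
    anchor = min(range(n_y), key=lambda i: (res.x[i], markers[i]))
    opt_row_cols = list(range(n_y, n_var))
    a_opt = coo_matrix(
        (
            vals + [cost[j] for j in opt_row_cols],
            (rows + [r] * n_t, cols + opt_row_cols),
        ),
        shape=(r + 1, n_var),
    )
    b_opt = np.append(b_ub, f_star + 1e-9 * max(1.0, abs(f_star)))
    a_eq = coo_matrix(([1.0], ([0], [anchor])), shape=(1, n_var))
    tie_bounds = [(-box, box)] * n_y + [(0.0, None)] * n_t
    sum_y = np.zeros(n_var)
    sum_y[:n_y] = 1.0
    lo = linprog(sum_y, A_ub=a_opt, b_ub=b_opt, A_eq=a_eq, b_eq=[0.0],
                 bounds=tie_bounds, method="highs")
    hi = linprog(-sum_y, A_ub=a_opt, b_ub=b_opt, A_eq=a_eq, b_eq=[0.0],
                 bounds=tie_bounds, method="highs")
    if lo.success and hi.success:
        y = (lo.x[:n_y] + hi.x[:n_y]) / 2.0
    else:  # pragma: no cover - numerically degenerate optimality cut
        y = res.x[:n_y]

    # markers untouched by any objective term or constraint (chromosome has a
    # single marker in every map that carries them): interpolate between the
    # nearest constrained neighbours using mean source position.
    constrained = set()
    for ia, ib, _, _ in terms:
        constrained.update((ia, ib))
    for c in constraints:
        constrained.update((idx[c.a], idx[c.b]))
    if len(constrained) < n_y:
        y = _place_unconstrained(chrom, markers, maps, y, constrained)

    y = y - y.min()
    order = sorted(range(n_y), key=lambda i: (y[i], markers[i]))
    out: list[tuple[str, float]] = []
    last = -np.inf
    for i in order:
        pos = float(y[i])
        if pos <= last:  # enforce strict increase for degenerate ties
            pos = last + min_gap
        out.append((markers[i], pos))
        last = pos
    return out


def _place_unconstrained(
    chrom: str,
    markers: list[str],
    maps: Sequence[LinkageMap],
    y: np.ndarray,
    constrained: set[int],
) -> np.ndarray:
    """Place isolated markers by their mean source position, rescaled into
    the solved coordinate range."""
    y = y.copy()
    solved = sorted(constrained, key=lambda i: y[i])
    lo, hi = y[solved[0]], y[solved[-1]]
    src_vals = []
    for i in range(len(markers)):
        pos = [
            lm.positions(chrom)[markers[i]]
            for lm in maps
            if markers[i] in lm.positions(chrom)
        ]
        src_vals.append(float(np.mean(pos)))
    for i in range(len(markers)):
        if i not in constrained:
            y[i] = float(np.clip(src_vals[i], lo, hi))
    return y


@dataclass
class ChromosomeStats:
    chrom: str
    n_markers: int
    length_cM: float
    density: float | None  # markers/cM; None on degenerate length


def map_stats(cmap: LinkageMap) -> dict:
    """Per-chromosome length/count/density plus sub-genome and totals.

    Density is markers/cM; a single-marker (zero-length) chromosome reports
    ``density=None``.
    """
    per_chrom: dict[str, ChromosomeStats] = {}
    for chrom, markers in cmap.entries.items():
        n = len(markers)
        length = markers[-1][1] - markers[0][1] if n >= 2 else 0.0
        density = (n / length) if length > 0 else None
        per_chrom[chrom] = ChromosomeStats(chrom, n, length, density)

    per_sub: dict[str, dict[str, float]] = {}
    for st in per_chrom.values():
        sub = st.chrom[-1]
        agg = per_sub.setdefault(sub, {"n_markers": 0, "length_cM": 0.0})
        agg["n_markers"] += st.n_markers
        agg["length_cM"] += st.length_cM
    for agg in per_sub.values():
        agg["density"] = (
            agg["n_markers"] / agg["length_cM"] if agg["length_cM"] > 0 else None
        )

    total_n = sum(st.n_markers for st in per_chrom.values())
    total_len = sum(st.length_cM for st in per_chrom.values())
    return {
        "per_chromosome": per_chrom,
        "per_subgenome": per_sub,
        "total_markers": total_n,
        "total_length_cM": total_len,
        "overall_density": (total_n / total_len) if total_len > 0 else None,
    }
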