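"""Synthetic multi-study QTL data with known ground truth.

Emulates the raw material of a QTL meta-analysis: a set of true trait loci
per chromosome, a master marker map with a monotone genetic↔physical
mapping (including a configurable low-recombination "centromere plateau"
where few cM cover much of the physical chromosome, the source of huge
physical spans in real wheat regions), per-study linkage maps obtained by
marker subsampling and multiplicative scale jitter, and per-study QTL
detections with noisy peaks, population-dependent CI widths, exponential
LOD tails, and mostly-small PVE with an occasional large effect.

Defaults mirror the compendium this toolkit was built around: RIL/DH/NIL
populations of 82–414 individuals (RIL-dominated), LOD = 3 + Exp(mean 3)
(range ≈3 to >30), PVE uniform on 4–25%, ten studies with per-locus
detection probability 0.8. Each detected QTL's peak error is drawn with
the standard deviation its own CI implies (CI width / 3.92), so the
compendium is exactly the heteroscedastic mixture the meta-analysis
assumes; under the default population mix those sds average about
``sigma_cM`` = 3 cM, which also sets the minimum true-locus separation.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from metaqtl.catalog import QTLRecord, estimate_ci
from metaqtl.linkage import LinkageMap


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_cM: float
    length_bp: int


@dataclass(frozen=True)
class TruthConfig:
    """Study-condition knobs of the generator (defaults are the conditions)."""

    chromosomes: tuple[Chromosome, ...] = (
        Chromosome("1A", 220.0, 590_000_000),
        Chromosome("2B", 250.0, 800_000_000),
        Chromosome("3D", 180.0, 620_000_000),
    )
    n_true_loci: int = 3            # per chromosome
    min_separation_sigma: float = 4.0
    n_studies: int = 10
    p_det: float = 0.8              # per-study, per-locus detection probability
    sigma_cM: float = 3.0           # sd of peak noise around the true position
    pve_min: float = 4.0            # percent; PVE ~ Uniform(min, max)
    pve_max: float = 25.0
    lod_base: float = 3.0           # LOD = base + Exp(mean lod_scale)
    lod_scale: float = 3.0
    pop_mix: tuple[tuple[str, float], ...] = (("RIL", 0.75), ("DH", 0.23), ("NIL", 0.02))
    pop_size_ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"RIL": (93, 302), "DH": (95, 414), "NIL": (120, 120)}
    )
    marker_spacing_cM: float = 2.0  # master-map grid step
    map_subsample: float = 0.7      # fraction of master markers kept per study
    scale_jitter_sd: float = 0.05   # sd of log scale factor per study map
    centromere_frac: float = 0.1    # cM fraction covering centromere_bp_frac of bp
    centromere_bp_frac: float = 0.7
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "TruthConfig":
        raw = yaml.safe_load(open(path))
        if "chromosomes" in raw:
            raw["chromosomes"] = tuple(Chromosome(**c) for c in raw["chromosomes"])
        if "pop_mix" in raw:
            raw["pop_mix"] = tuple((t, p) for t, p in raw["pop_mix"])
        return cls(**raw)


@dataclass
class Truth:
    """Ground truth: true locus positions (cM) per chromosome."""

    loci: dict[str, np.ndarray]
    config: TruthConfig

    def locus_bp(self, chrom: str) -> np.ndarray:
        c = next(c for c in self.config.chromosomes if c.name == chrom)
        return cm_to_bp(self.loci[chrom], c, self.config)

    def manifest(self) -> dict:
        return {
            "loci_cM": {c: [float(x) for x in v] for c, v in self.loci.items()},
            "loci_bp": {c: [int(x) for x in self.locus_bp(c)] for c in self.loci},
            "seed": self.config.seed,
        }


def cm_to_bp(pos_cM, chrom: Chromosome, config: TruthConfig) -> np.ndarray:
    """Piecewise-linear monotone genetic→physical mapping.

    A central fraction ``centromere_frac`` of the genetic length maps onto
    ``centromere_bp_frac`` of the physical length — a recombination desert.
    """
    L, P = chrom.length_cM, chrom.length_bp
    half = config.centromere_frac / 2.0
    bp_half = config.centromere_bp_frac / 2.0
    xp = np.array([0.0, (0.5 - half) * L, (0.5 + half) * L, L])
    fp = np.array([0.0, (0.5 - bp_half) * P, (0.5 + bp_half) * P, float(P)])
    return np.interp(np.asarray(pos_cM, dtype=float), xp, fp).round().astype(np.int64)


def generate_truth(config: TruthConfig, seed: int | None = None) -> Truth:
    """Draw true locus positions, uniform with a 4σ minimum separation."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    min_sep = config.min_separation_sigma * config.sigma_cM
    loci: dict[str, np.ndarray] = {}
    for chrom in config.chromosomes:
        n = config.n_true_loci
        if n == 0:
            loci[chrom.name] = np.array([])
            continue
        if (n - 1) * min_sep >= chrom.length_cM:
            raise ValueError(
                f"{chrom.name}: cannot place {n} loci >= {min_sep} cM apart "
                f"on {chrom.length_cM} cM"
            )
        for _ in range(10_000):
            cand = np.sort(rng.uniform(0.05 * chrom.length_cM, 0.95 * chrom.length_cM, n))
            if n == 1 or np.diff(cand).min() >= min_sep:
                loci[chrom.name] = cand
                break
        else:  # pragma: no cover
            raise ValueError(f"{chrom.name}: rejection sampling failed")
    return Truth(loci=loci, config=config)


@dataclass
class SyntheticStudySet:
    """Everything generate_studies emits."""

    records: list[QTLRecord]
    study_maps: dict[str, LinkageMap]
    master_map: LinkageMap
    marker_table: dict[str, tuple[str, int]]  # marker -> (chrom, bp)


def generate_studies(truth: Truth, seed: int | None = None) -> SyntheticStudySet:
    """Generate per-study maps and detected QTLs from the truth.

    The master map is a uniform marker grid per chromosome; each study map
    keeps a random subset of markers (always including the chromosome ends,
    so flanks can bracket any peak) rescaled by exp(N(0, jitter)). Each
    study detects each true locus with probability ``p_det``; a detection
    gets a Normal(true, σ²) peak, uniform-tailed PVE, the study's
    population N, a CI from the population-type formula, and an
    exponential-tailed LOD. Flanks are the nearest study-map markers around
    the peak.
    """
    config = truth.config
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)

    # master map and physical table
    master_entries: dict[str, list[tuple[str, float]]] = {}
    marker_table: dict[str, tuple[str, int]] = {}
    for chrom in config.chromosomes:
        n_mark = int(chrom.length_cM / config.marker_spacing_cM) + 1
        pos = np.linspace(0.0, chrom.length_cM, n_mark)
        names = [f"M{chrom.name}_{i:04d}" for i in range(n_mark)]
        master_entries[chrom.name] = list(zip(names, pos))
        for name, bp in zip(names, cm_to_bp(pos, chrom, config)):
            marker_table[name] = (chrom.name, int(bp))
    master = LinkageMap("master", master_entries)

    types, probs = zip(*config.pop_mix)
    records: list[QTLRecord] = []
    study_maps: dict[str, LinkageMap] = {}
    for s in range(config.n_studies):
        study_id = f"S{s:02d}"
        pop_type = str(rng.choice(types, p=np.array(probs) / sum(probs)))
        lo, hi = config.pop_size_ranges[pop_type]
        pop_size = int(rng.integers(lo, hi + 1))
        scale = float(np.exp(rng.normal(0.0, config.scale_jitter_sd)))

        entries: dict[str, list[tuple[str, float]]] = {}
        for chrom in config.chromosomes:
            markers = master_entries[chrom.name]
            keep = rng.random(len(markers)) < config.map_subsample
            keep[0] = keep[-1] = True
            entries[chrom.name] = [
                (m, p * scale) for (m, p), k in zip(markers, keep) if k
            ]
        smap = LinkageMap(study_id, entries)
        study_maps[study_id] = smap

        qn = 0
        for chrom in config.chromosomes:
            span = [p for _, p in entries[chrom.name]]
            for true_pos in truth.loci[chrom.name]:
                if rng.random() >= config.p_det:
                    continue
                pve = float(rng.uniform(config.pve_min, config.pve_max))
                width = estimate_ci(pop_type, pop_size, pve / 100.0)
                # each study's peak error carries the sd its own CI implies
                # (width/3.92), so generated data follow the heteroscedastic
                # model; sigma_cM is the scale these sds average to under the
                # default population conditions and sets locus separation
                peak_sd = width / 3.92
                peak = float(
                    np.clip(
                        scale * rng.normal(true_pos, peak_sd),
                        span[0], span[-1],
                    )
                )
                lod = float(config.lod_base + rng.exponential(config.lod_scale))
                below = [m for m, p in entries[chrom.name] if p <= peak]
                above = [m for m, p in entries[chrom.name] if p >= peak]
                qn += 1
                records.append(
                    QTLRecord(
                        qtl_id=f"{study_id}_q{qn:03d}",
                        study_id=study_id,
                        population_type=pop_type,
                        population_size=pop_size,
                        chromosome=chrom.name,
                        flank_lo=below[-1],
                        flank_hi=above[0],
                        peak=peak,
                        ci_lo=max(0.0, peak - width / 2.0),
                        ci_hi=peak + width / 2.0,
                        lod=lod,
                        pve=pve,
                    )
                )
    return SyntheticStudySet(records, study_maps, master, marker_table)


@dataclass
class ValidationLayers:
    mtas: pd.DataFrame
    genes: pd.DataFrame
    expression: pd.DataFrame
    sample_tissues: dict[str, str]
    known_genes: pd.DataFrame


def generate_validation_layers(
    truth: Truth,
    seed: int | None = None,
    mtas_per_locus: int = 2,
    n_decoy_mtas: int = 0,
    gene_spacing_bp: int = 2_000_000,
    frac_expressed: float = 0.5,
) -> ValidationLayers:
    """MTAs, gene models, TPM matrix and known genes tied to the truth.

    MTAs are planted within ±1 Mb of each true locus (plus optional uniform
    decoys); genes are tiled along each chromosome with one gene planted at
    each true-locus bp; TPM is LogNormal with roughly ``frac_expressed`` of
    genes above 2 TPM in the relevant tissues; known genes sit exactly at
    the first true locus of each chromosome.
    """
    config = truth.config
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)

    mta_rows = []
    for chrom in config.chromosomes:
        for i, bp in enumerate(truth.locus_bp(chrom.name)):
            for j in range(mtas_per_locus):
                offset = int(rng.uniform(-1_000_000, 1_000_000))
                mta_rows.append(
                    {
                        "snp_id": f"snp_{chrom.name}_{i}_{j}",
                        "chr": chrom.name,
                        "bp": max(0, int(bp) + offset),
                        "study_id": f"GWAS{j}",
                        "trait": "GPC",
                    }
                )
        for j in range(n_decoy_mtas):
            mta_rows.append(
                {
                    "snp_id": f"decoy_{chrom.name}_{j}",
                    "chr": chrom.name,
                    "bp": int(rng.uniform(0, chrom.length_bp)),
                    "study_id": "GWASdecoy",
                    "trait": "GPC",
                }
            )
    mtas = pd.DataFrame(mta_rows, columns=["snp_id", "chr", "bp", "study_id", "trait"])

    gene_rows = []
    known_rows = []
    for chrom in config.chromosomes:
        starts = np.arange(500_000, chrom.length_bp, gene_spacing_bp, dtype=np.int64)
        for i, s in enumerate(starts):
            gene_rows.append(
                {
                    "gene_id": f"G{chrom.name}_{i:04d}",
                    "chr": chrom.name,
                    "start_bp": int(s),
                    "end_bp": int(s + 3_000),
                    "description": "tiled gene model",
                }
            )
        for i, bp in enumerate(truth.locus_bp(chrom.name)):
            gene_rows.append(
                {
                    "gene_id": f"Gtrue_{chrom.name}_{i}",
                    "chr": chrom.name,
                    "start_bp": int(bp),
                    "end_bp": int(bp) + 3_000,
                    "description": "planted causal gene",
                }
            )
        bp0 = truth.locus_bp(chrom.name)
        if len(bp0):
            known_rows.append(
                {
                    "gene_id": f"KNOWN_{chrom.name}",
                    "chr": chrom.name,
                    "start_bp": int(bp0[0]),
                    "end_bp": int(bp0[0]) + 3_000,
                    "description": "known trait gene",
                }
            )
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chr", "start_bp", "end_bp", "description"]
    )
    known = pd.DataFrame(
        known_rows, columns=["gene_id", "chr", "start_bp", "end_bp", "description"]
    )

    tissues = {"grain_1": "grain", "spike_1": "spike", "leaf_1": "leaf", "root_1": "root"}
    n_genes = len(genes)
    expr = {}
    for sample, tissue in tissues.items():
        relevant = tissue in ("grain", "spike")
        if frac_expressed <= 0:
            tpm = np.zeros(n_genes)
        else:
            # median chosen so P(TPM > 2) ~= frac_expressed in relevant tissues
            mu = np.log(2.0) - _norm_ppf(1.0 - frac_expressed)
            tpm = rng.lognormal(mu if relevant else mu - 2.0, 1.0, n_genes)
        expr[sample] = tpm
    expression = pd.DataFrame(expr, index=genes["gene_id"].tolist())
    # planted causal genes are always strongly expressed in relevant tissues
    if frac_expressed > 0:
        planted = genes["gene_id"].str.startswith("Gtrue_")
        expression.loc[planted.values, ["grain_1", "spike_1"]] = 50.0

    return ValidationLayers(mtas, genes, expression, tissues, known)


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))
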