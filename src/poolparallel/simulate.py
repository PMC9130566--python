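"""Synthetic multi-lineage pool-seq datasets with known truth.

The generator emulates the data structure the pipeline consumes: several
independent lineages, each with a few anadromous and freshwater pools
sequenced as DNA pools; scaffolded genomes; neutral SNPs whose per-pool
frequencies drift around a shared ancestral frequency; optional planted
"freshwater-selected" regions where every (or a chosen subset of) freshwater
pool's frequency is shifted so the expected |dAF| equals a target delta; and
a tunable fraction of SNP positions shared between lineages (standing
variation at the same sites).

Model
-----
ancestral frequency  per lineage and site, Beta(a, b);
pool frequency       sigmoid(logit(ancestral or shifted target) +
                     Normal(0, drift_sd)) — drift acts on the logit scale so
                     frequencies stay inside (0, 1) without boundary pileups;
read counts          coverage ~ Poisson(coverage_mean) per pool and site,
                     alternative-allele reads ~ Binomial(coverage, freq).

Defaults mirror the study design the pipeline targets: four lineages with
(2 anadromous, 3 freshwater), (2, 3), (2, 1), (2, 1) pools, ~32x coverage,
pools of 25 diploids.  Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    EFFECT_CLASSES,
    EffectRecord,
    GeneModel,
    PoolInfo,
    SiteCounts,
    write_effects,
    write_gff,
    write_manifest,
    write_sync,
)

__all__ = [
    "PlantedRegion",
    "SimConfig",
    "TruthSet",
    "LineageData",
    "SimulatedDataset",
    "simulate",
    "null_dataset",
    "evenly_planted_regions",
]

_LOGIT_EPS = 1e-4

DEFAULT_EFFECT_RATES = {
    "nonsynonymous": 0.03,
    "synonymous": 0.04,
    "UTR": 0.05,
    "upstream": 0.05,
    "downstream": 0.05,
    "intronic": 0.28,
    "intergenic": 0.50,
}


@dataclass(frozen=True)
class PlantedRegion:
    """A freshwater-selected genomic interval with target |dAF| shift."""

    scaffold: int | str  # index into the simulated scaffolds, or name
    start: int  # 1-based inclusive
    end: int
    delta: float  # target |dAF| in [0, 1]
    lineages: tuple[str, ...] | None = None  # None = all lineages
    fresh_pools: tuple[str, ...] | None = None  # None = all freshwater pools

    def __post_init__(self):
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must be in [0, 1], got {self.delta}")
        if self.start > self.end:
            raise ValueError("planted region start > end")


@dataclass(frozen=True)
class SimConfig:
    n_lineages: int = 4
    pools_per_lineage: tuple[tuple[int, int], ...] = ((2, 3), (2, 3), (2, 1), (2, 1))
    n_scaffolds: int = 10
    scaffold_length: int = 1_000_000
    n_snps: int = 20_000
    beta_a: float = 0.7
    beta_b: float = 0.7
    drift_sd: float = 0.5  # logit-scale per-pool drift noise
    planted_regions: tuple[PlantedRegion, ...] = ()
    coverage_mean: float = 32.0
    shared_fraction: float = 0.5  # fraction of SNP positions shared by all lineages
    pool_n_individuals: int = 25
    min_snps_per_region: int | None = None  # top-up planted regions to this many SNPs
    effect_rates: tuple[tuple[str, float], ...] = tuple(DEFAULT_EFFECT_RATES.items())
    force_nonsyn_in_regions: bool = False
    seed: int = 0

    def __post_init__(self):
        if len(self.pools_per_lineage) != self.n_lineages:
            raise ValueError(
                "pools_per_lineage must list one (n_anadromous, n_freshwater) "
                "tuple per lineage"
            )
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        rates = dict(self.effect_rates)
        if set(rates) - set(EFFECT_CLASSES):
            raise ValueError(f"unknown effect classes in rates: {rates}")
        if abs(sum(rates.values()) - 1.0) > 1e-9:
            raise ValueError("effect_rates must sum to 1")

    @property
    def lineage_names(self) -> list[str]:
        return [f"L{i + 1}" for i in range(self.n_lineages)]

    @property
    def scaffold_names(self) -> list[str]:
        width = len(str(self.n_scaffolds))
        return [f"scaffold_{i + 1:0{width}d}" for i in range(self.n_scaffolds)]

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {name: self.scaffold_length for name in self.scaffold_names}


@dataclass
class TruthSet:
    """Ground truth of one simulation: planted regions, frequencies, effects."""

    regions: dict[str, list[tuple[str, int, int, float]]]  # lineage -> (scaf, s, e, d)
    true_freqs: dict[str, np.ndarray]  # lineage -> (S, P) alt-allele frequency
    effects: list[EffectRecord]


@dataclass
class LineageData:
    lineage: str
    pools: list[PoolInfo]
    scaffold: np.ndarray  # (S,) names
    position: np.ndarray  # (S,) 1-based
    ref: np.ndarray  # (S,) reference base
    alt: np.ndarray  # (S,) alternative base
    true_freqs: np.ndarray  # (S, P) alt-allele frequency per pool
    counts: np.ndarray  # (S, P, 6) sync-order read counts

    def site_counts(self) -> list[SiteCounts]:
        return [
            SiteCounts(
                scaffold=str(self.scaffold[i]),
                position=int(self.position[i]),
                ref_base=str(self.ref[i]),
                counts=tuple(tuple(int(c) for c in pool) for pool in self.counts[i]),
            )
            for i in range(len(self.position))
        ]


@dataclass
class SimulatedDataset:
    config: SimConfig
    manifest: list[PoolInfo]
    lineages: dict[str, LineageData]
    truth: TruthSet
    genes: list[GeneModel]

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return self.config.scaffold_lengths

    def write(self, outdir: str | Path) -> None:
        """Write sync (one per lineage), manifest, truth BED, GFF, effects."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_manifest(self.manifest, outdir / "manifest.tsv")
        for name, lin in self.lineages.items():
            write_sync(lin.site_counts(), outdir / f"{name}.sync")
        with open(outdir / "scaffold_lengths.tsv", "w") as fh:
            fh.write("scaffold\tlength\n")
            for scaf, length in self.scaffold_lengths.items():
                fh.write(f"{scaf}\t{length}\n")
        with open(outdir / "truth_regions.bed", "w") as fh:
            for lineage, regs in sorted(self.truth.regions.items()):
                for scaf, start, end, delta in regs:
                    fh.write(
                        f"{scaf}\t{start - 1}\t{end}\t{lineage}\t{delta:g}\t.\n"
                    )
        write_gff(self.genes, outdir / "genes.gff3")
        write_effects(self.truth.effects, outdir / "effects.tsv")


def evenly_planted_regions(
    cfg: SimConfig,
    n_regions: int,
    delta: float,
    length: int = 20_000,
    lineages: Sequence[str] | None = None,
) -> tuple[PlantedRegion, ...]:
    """Deterministically spaced planted regions (round-robin over scaffolds).

    Regions are centered in equal slots so that, after 20 kb merging, distinct
    planted regions can never coalesce.
    """
    per_scaffold = -(-n_regions // cfg.n_scaffolds)  # ceil
    slot = cfg.scaffold_length // per_scaffold
    if slot < length + 100_000:
        raise ValueError("scaffolds too short to space the requested regions")
    regions = []
    for r in range(n_regions):
        scaf = r % cfg.n_scaffolds
        k = r // cfg.n_scaffolds
        mid = k * slot + slot // 2
        start = mid - length // 2
        regions.append(
            PlantedRegion(
                scaffold=scaf, start=start, end=start + length - 1, delta=delta,
                lineages=tuple(lineages) if lineages is not None else None,
            )
        )
    return tuple(regions)


def _draw_unique_positions(rng: np.random.Generator, total: int, k: int,
                           taken: set[int]) -> np.ndarray:
    """k distinct linear coordinates in [0, total) avoiding ``taken``."""
    if k == 0:
        return np.empty(0, dtype=np.int64)
    out: list[int] = []
    need = k
    while need > 0:
        draw = rng.integers(0, total, size=int(need * 1.3) + 16)
        for g in draw.tolist():
            if g not in taken:
                taken.add(g)
                out.append(g)
                if len(out) == k:
                    break
        need = k - len(out)
    return np.array(out, dtype=np.int64)


def _resolve_scaffold(cfg: SimConfig, scaffold: int | str) -> tuple[int, str]:
    names = cfg.scaffold_names
    if isinstance(scaffold, (int, np.integer)):
        return int(scaffold), names[int(scaffold)]
    return names.index(scaffold), str(scaffold)


def simulate(cfg: SimConfig) -> SimulatedDataset:
    """Generate one dataset; deterministic given ``cfg`` (including its seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    total = cfg.n_scaffolds * cfg.scaffold_length
    scaffold_names = np.array(cfg.scaffold_names, dtype=object)
    lineage_names = cfg.lineage_names

    # --- pool manifest -----------------------------------------------------
    manifest: list[PoolInfo] = []
    for lname, (n_an, n_fw) in zip(lineage_names, cfg.pools_per_lineage):
        if n_an < 1 or n_fw < 1:
            raise ValueError(
                f"{lname}: each lineage needs >= 1 anadromous and >= 1 "
                "freshwater pool"
            )
        for i in range(n_an):
            manifest.append(
                PoolInfo(f"{lname}_an{i + 1}", lname, "anadromous",
                         cfg.pool_n_individuals)
            )
        for i in range(n_fw):
            manifest.append(
                PoolInfo(f"{lname}_fw{i + 1}", lname, "freshwater",
                         cfg.pool_n_individuals)
            )

    # --- SNP positions: shared set + private per lineage -------------------
    taken: set[int] = set()
    n_shared = int(round(cfg.shared_fraction * cfg.n_snps))
    shared = _draw_unique_positions(rng, total, n_shared, taken)
    lineage_positions: dict[str, np.ndarray] = {}
    for lname in lineage_names:
        private = _draw_unique_positions(rng, total, cfg.n_snps - n_shared, taken)
        lineage_positions[lname] = np.concatenate([shared, private])

    # planted-region bookkeeping (resolved to scaffold names), plus optional
    # top-up so each region holds at least min_snps_per_region SNPs
    resolved: list[tuple[int, str, PlantedRegion]] = []
    for pr in cfg.planted_regions:
        si, sname = _resolve_scaffold(cfg, pr.scaffold)
        if pr.end > cfg.scaffold_length:
            raise ValueError(f"planted region extends past scaffold: {pr}")
        resolved.append((si, sname, pr))

    for lname in lineage_names:
        for si, sname, pr in resolved:
            if pr.lineages is not None and lname not in pr.lineages:
                continue
            if cfg.min_snps_per_region is None:
                continue
            g_lo = si * cfg.scaffold_length + (pr.start - 1)
            g_hi = si * cfg.scaffold_length + (pr.end - 1)
            pos = lineage_positions[lname]
            have = int(((pos >= g_lo) & (pos <= g_hi)).sum())
            deficit = cfg.min_snps_per_region - have
            if deficit > 0:
                lineage_taken = taken  # global uniqueness keeps shared sets clean
                extra = _draw_unique_positions(
                    rng, g_hi - g_lo + 1, deficit,
                    {g - g_lo for g in lineage_taken
                     if g_lo <= g <= g_hi},
                ) + g_lo
                taken.update(extra.tolist())
                lineage_positions[lname] = np.concatenate([pos, extra])

    for lname in lineage_names:
        lineage_positions[lname] = np.sort(lineage_positions[lname])

    # --- ref/alt alleles, consistent across lineages at shared positions ---
    all_positions = np.unique(np.concatenate(list(lineage_positions.values())))
    bases = np.array(["A", "T", "C", "G"], dtype=object)
    ref_choice = rng.integers(0, 4, size=len(all_positions))
    alt_shift = rng.integers(1, 4, size=len(all_positions))
    alt_choice = (ref_choice + alt_shift) % 4
    allele_index = {int(g): k for k, g in enumerate(all_positions)}

    # --- per-lineage frequencies and read counts ---------------------------
    lineages: dict[str, LineageData] = {}
    truth_regions: dict[str, list[tuple[str, int, int, float]]] = {}
    truth_freqs: dict[str, np.ndarray] = {}
    n_clipped = 0
    for lname in lineage_names:
        pools = [p for p in manifest if p.lineage == lname]
        gpos = lineage_positions[lname]
        S, P = len(gpos), len(pools)
        scaf_idx = gpos // cfg.scaffold_length
        position = (gpos % cfg.scaffold_length + 1).astype(np.int64)

        anc = rng.beta(cfg.beta_a, cfg.beta_b, size=S)
        anc = np.clip(anc, _LOGIT_EPS, 1.0 - _LOGIT_EPS)

        # per-pool target frequency before drift: ancestral everywhere, the
        # shifted value for freshwater pools inside planted regions
        target = np.tile(anc[:, None], (1, P))
        regs_here: list[tuple[str, int, int, float]] = []
        for si, sname, pr in resolved:
            if pr.lineages is not None and lname not in pr.lineages:
                continue
            in_region = (scaf_idx == si) & (position >= pr.start) & (
                position <= pr.end
            )
            if not in_region.any():
                regs_here.append((sname, pr.start, pr.end, pr.delta))
                continue
            a = anc[in_region]
            # shift in whichever direction keeps the target inside [0, 1];
            # when delta exceeds both headrooms, saturate at the far boundary
            up_ok = a + pr.delta <= 1.0
            down_ok = a - pr.delta >= 0.0
            shifted = np.where(
                up_ok, a + pr.delta,
                np.where(down_ok, a - pr.delta,
                         np.where(a <= 0.5, a + pr.delta, a - pr.delta)),
            )
            bad = (shifted < 0.0) | (shifted > 1.0)
            n_clipped += int(bad.sum())
            shifted = np.clip(shifted, 0.0, 1.0)
            for j, p in enumerate(pools):
                if p.life_history != "freshwater":
                    continue
                if pr.fresh_pools is not None and p.name not in pr.fresh_pools:
                    continue
                target[in_region, j] = shifted
            regs_here.append((sname, pr.start, pr.end, pr.delta))
        truth_regions[lname] = regs_here

        logit = np.log(np.clip(target, _LOGIT_EPS, 1 - _LOGIT_EPS)) - np.log1p(
            -np.clip(target, _LOGIT_EPS, 1 - _LOGIT_EPS)
        )
        noise = rng.normal(0.0, cfg.drift_sd, size=(S, P))
        freqs = 1.0 / (1.0 + np.exp(-(logit + noise)))

        coverage = rng.poisson(cfg.coverage_mean, size=(S, P))
        alt_reads = rng.binomial(coverage, freqs)
        ref_reads = coverage - alt_reads

        k = np.array([allele_index[int(g)] for g in gpos])
        ref_i = ref_choice[k]
        alt_i = alt_choice[k]
        counts = np.zeros((S, P, 6), dtype=np.int64)
        rows = np.arange(S)[:, None]
        cols = np.arange(P)[None, :]
        counts[rows, cols, ref_i[:, None]] = ref_reads
        counts[rows, cols, alt_i[:, None]] = alt_reads

        lineages[lname] = LineageData(
            lineage=lname,
            pools=pools,
            scaffold=scaffold_names[scaf_idx],
            position=position,
            ref=bases[ref_i],
            alt=bases[alt_i],
            true_freqs=freqs,
            counts=counts,
        )
        truth_freqs[lname] = freqs

    if n_clipped:
        warnings.warn(
            f"{n_clipped} planted-site frequencies fell outside [0, 1] and "
            "were clipped (delta too large for the ancestral frequency)",
            stacklevel=2,
        )

    # --- effect labels over the union of SNP positions ---------------------
    rates = dict(cfg.effect_rates)
    classes = list(rates)
    probs = np.array([rates[c] for c in classes])
    draw = rng.choice(len(classes), size=len(all_positions), p=probs)
    planted_global: list[tuple[int, int]] = [
        (si * cfg.scaffold_length + pr.start - 1,
         si * cfg.scaffold_length + pr.end - 1)
        for si, _, pr in resolved
    ]
    effects: list[EffectRecord] = []
    for k, g in enumerate(all_positions):
        cls = classes[draw[k]]
        if cfg.force_nonsyn_in_regions and any(
            lo <= g <= hi for lo, hi in planted_global
        ):
            cls = "nonsynonymous"
        effects.append(
            EffectRecord(
                scaffold=str(scaffold_names[g // cfg.scaffold_length]),
                position=int(g % cfg.scaffold_length + 1),
                effect=cls,
            )
        )

    # --- toy gene models: one inside each planted region + background ------
    genes: list[GeneModel] = []
    for r, (si, sname, pr) in enumerate(resolved, start=1):
        mid = (pr.start + pr.end) // 2
        half = min(2000, (pr.end - pr.start) // 2)
        genes.append(
            GeneModel(sname, max(1, mid - half), mid + half, "+",
                      f"planted_gene_{r}", "inside planted region")
        )
    for si, sname in enumerate(cfg.scaffold_names):
        start = cfg.scaffold_length // 4
        genes.append(
            GeneModel(sname, start, start + 3000, "-", f"bg_gene_{si + 1}_a", None)
        )
        start = 3 * cfg.scaffold_length // 4
        genes.append(
            GeneModel(sname, start, start + 3000, "+", f"bg_gene_{si + 1}_b", None)
        )

    return SimulatedDataset(
        config=cfg,
        manifest=manifest,
        lineages=lineages,
        truth=TruthSet(regions=truth_regions, true_freqs=truth_freqs,
                       effects=effects),
        genes=genes,
    )


def null_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Pure-drift dataset (no planted selection) for type-I-error calibration."""
    if cfg.planted_regions:
        raise ValueError("null_dataset requires a config with no planted regions")
    return simulate(cfg)
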