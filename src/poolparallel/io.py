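"""Readers and writers for the external formats the pipeline touches.

Formats handled here:

* Popoolation2 ``sync``: tab-separated ``scaffold  position  ref_base`` followed
  by one ``A:T:C:G:N:del`` count sextuple per pool.  Sync carries no pool
  metadata, so pools are described by a separate manifest table.
* Pool manifest: TSV with columns ``pool_name  lineage  life_history
  n_individuals`` (an optional ``haploid_pool_size`` column is validated if
  present; otherwise it is 2 x n_individuals, the diploid pool-size convention).
* GFF3 gene models (via gffutils; only ``gene`` features are retained).
* BED6 output for outlier regions.
* TSV variant-effect tables (``scaffold  position  effect``).

All coordinates are held 1-based inclusive internally (the sync/GFF
convention); conversion to BED's 0-based half-open happens only at write time.
"""

from __future__ import annotations

import os
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SYNC_ALLELE_ORDER",
    "LIFE_HISTORIES",
    "EFFECT_CLASSES",
    "SyncFormatError",
    "SiteCounts",
    "PoolInfo",
    "GeneModel",
    "EffectRecord",
    "read_manifest",
    "write_manifest",
    "read_sync",
    "write_sync",
    "read_gff",
    "read_effects",
    "write_effects",
    "write_regions_bed",
    "read_regions_bed",
    "read_scaffold_lengths",
]

#: Column order of the per-pool count sextuple in sync files.
SYNC_ALLELE_ORDER = ("A", "T", "C", "G", "N", "del")

LIFE_HISTORIES = ("anadromous", "freshwater")

#: The seven variant-effect classes consumed by the shared-nonsynonymous test.
EFFECT_CLASSES = (
    "nonsynonymous",
    "synonymous",
    "UTR",
    "upstream",
    "downstream",
    "intronic",
    "intergenic",
)


class SyncFormatError(ValueError):
    """A sync file violated the format contract (always names the line)."""


@dataclass(frozen=True)
class SiteCounts:
    """Raw per-pool nucleotide counts at one genomic site.

    ``counts`` is one 6-tuple per pool in manifest order, following the sync
    convention A:T:C:G:N:del.  N and del contribute to coverage but are never
    treated as alleles.
    """

    scaffold: str
    position: int  # 1-based
    ref_base: str
    counts: tuple[tuple[int, int, int, int, int, int], ...]

    def coverage(self, pool_index: int) -> int:
        return sum(self.counts[pool_index])

    @property
    def n_pools(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class PoolInfo:
    """One sequenced pool: a population sample of ``n_individuals`` diploids."""

    name: str
    lineage: str
    life_history: str  # "anadromous" | "freshwater"
    n_individuals: int

    def __post_init__(self) -> None:
        if self.life_history not in LIFE_HISTORIES:
            raise ValueError(
                f"pool {self.name!r}: life_history must be one of "
                f"{LIFE_HISTORIES}, got {self.life_history!r}"
            )
        if self.n_individuals < 1:
            raise ValueError(f"pool {self.name!r}: n_individuals must be >= 1")

    @property
    def haploid_pool_size(self) -> int:
        """Pool size = 2 x individuals, the convention for diploid organisms."""
        return 2 * self.n_individuals


@dataclass(frozen=True)
class GeneModel:
    scaffold: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    gene_id: str
    description: str | None = None


@dataclass(frozen=True)
class EffectRecord:
    scaffold: str
    position: int
    effect: str

    def __post_init__(self) -> None:
        if self.effect not in EFFECT_CLASSES:
            raise ValueError(
                f"effect {self.effect!r} at {self.scaffold}:{self.position} "
                f"is not one of {EFFECT_CLASSES}"
            )


# ---------------------------------------------------------------------------
# pool manifest
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ("pool_name", "lineage", "life_history", "n_individuals")


def read_manifest(path: str | Path) -> list[PoolInfo]:
    """Read a TSV pool manifest; order of rows defines sync column order."""
    pools: list[PoolInfo] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _MANIFEST_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: manifest missing columns {missing}")
        idx = {c: header.index(c) for c in header}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            pool = PoolInfo(
                name=parts[idx["pool_name"]],
                lineage=parts[idx["lineage"]],
                life_history=parts[idx["life_history"]],
                n_individuals=int(parts[idx["n_individuals"]]),
            )
            if "haploid_pool_size" in idx:
                stated = int(parts[idx["haploid_pool_size"]])
                if stated != pool.haploid_pool_size:
                    raise ValueError(
                        f"{path}:{lineno}: haploid_pool_size {stated} != "
                        f"2 x n_individuals ({pool.haploid_pool_size})"
                    )
            pools.append(pool)
    names = [p.name for p in pools]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate pool names in manifest")
    return pools


def write_manifest(pools: Sequence[PoolInfo], path: str | Path) -> None:
    with _atomic_open(path) as fh:
        fh.write("\t".join(_MANIFEST_COLUMNS + ("haploid_pool_size",)) + "\n")
        for p in pools:
            fh.write(
                f"{p.name}\t{p.lineage}\t{p.life_history}\t"
                f"{p.n_individuals}\t{p.haploid_pool_size}\n"
            )


def check_scan_manifest(pools: Sequence[PoolInfo]) -> None:
    """Validate that each lineage has both life histories (scan stages need both)."""
    by_lineage: dict[str, set[str]] = {}
    for p in pools:
        by_lineage.setdefault(p.lineage, set()).add(p.life_history)
    for lineage, kinds in by_lineage.items():
        if kinds != set(LIFE_HISTORIES):
            raise ValueError(
                f"lineage {lineage!r} needs at least one anadromous and one "
                f"freshwater pool for the scan; has only {sorted(kinds)}"
            )


# ---------------------------------------------------------------------------
# sync
# ---------------------------------------------------------------------------


def read_sync(path: str | Path, manifest: Sequence[PoolInfo]) -> list[SiteCounts]:
    """Parse a Popoolation2 sync file against a pool manifest.

    Records are returned in file order.  Any malformed line (wrong column
    count, non-integer count, malformed sextuple) raises :class:`SyncFormatError`
    naming the offending line number.
    """
    n_pools = len(manifest)
    expected_cols = 3 + n_pools
    sites: list[SiteCounts] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != expected_cols:
                raise SyncFormatError(
                    f"{path}:{lineno}: expected {expected_cols} columns "
                    f"(3 + {n_pools} pools), found {len(parts)}"
                )
            scaffold, pos_s, ref = parts[0], parts[1], parts[2]
            try:
                position = int(pos_s)
            except ValueError:
                raise SyncFormatError(
                    f"{path}:{lineno}: non-integer position {pos_s!r}"
                ) from None
            if position < 1:
                raise SyncFormatError(f"{path}:{lineno}: position must be >= 1")
            counts = []
            for col, tok in enumerate(parts[3:], start=4):
                pieces = tok.split(":")
                if len(pieces) != 6:
                    raise SyncFormatError(
                        f"{path}:{lineno}: column {col}: expected 6 "
                        f"colon-separated counts, got {tok!r}"
                    )
                try:
                    sextuple = tuple(int(x) for x in pieces)
                except ValueError:
                    raise SyncFormatError(
                        f"{path}:{lineno}: column {col}: non-integer count in {tok!r}"
                    ) from None
                if any(c < 0 for c in sextuple):
                    raise SyncFormatError(
                        f"{path}:{lineno}: column {col}: negative count in {tok!r}"
                    )
                counts.append(sextuple)
            sites.append(SiteCounts(scaffold, position, ref, tuple(counts)))
    if not sites:
        warnings.warn(f"{path}: sync file contained no records", stacklevel=2)
    return sites


def write_sync(sites: Iterable[SiteCounts], path: str | Path) -> None:
    with _atomic_open(path) as fh:
        for s in sites:
            cols = [s.scaffold, str(s.position), s.ref_base]
            cols += [":".join(str(c) for c in pool) for pool in s.counts]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GFF3 / effects
# ---------------------------------------------------------------------------


def read_gff(path: str | Path) -> list[GeneModel]:
    """Load ``gene`` features from a GFF3 file (other feature types ignored)."""
    import gffutils

    if os.path.getsize(path) == 0 or not _has_feature_lines(path):
        return []
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if feat.start > feat.end:
            warnings.warn(
                f"{path}: gene {feat.id} has start > end "
                f"({feat.start} > {feat.end}); record rejected",
                stacklevel=2,
            )
            continue
        desc = feat.attributes.get("description", [None])[0]
        genes.append(
            GeneModel(
                scaffold=feat.seqid,
                start=int(feat.start),
                end=int(feat.end),
                strand=feat.strand or ".",
                gene_id=feat.id,
                description=desc,
            )
        )
    return genes


def _has_feature_lines(path: str | Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return True
    return False


def write_gff(genes: Sequence[GeneModel], path: str | Path) -> None:
    with _atomic_open(path) as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.description:
                attrs += f";description={g.description}"
            fh.write(
                f"{g.scaffold}\tpoolparallel\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_effects(path: str | Path) -> list[EffectRecord]:
    records: list[EffectRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["scaffold", "position", "effect"]:
            raise ValueError(
                f"{path}: effect table must have columns scaffold/position/effect"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            scaffold, pos_s, effect = line.rstrip("\n").split("\t")[:3]
            try:
                records.append(EffectRecord(scaffold, int(pos_s), effect))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return records


def write_effects(records: Sequence[EffectRecord], path: str | Path) -> None:
    with _atomic_open(path) as fh:
        fh.write("scaffold\tposition\teffect\n")
        for r in records:
            fh.write(f"{r.scaffold}\t{r.position}\t{r.effect}\n")


def read_scaffold_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column ``scaffold\\tlength`` TSV (header optional)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            scaffold, value = line.rstrip("\n").split("\t")[:2]
            if scaffold == "scaffold" and not value.isdigit():
                continue  # header
            lengths[scaffold] = int(value)
    return lengths


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_regions_bed(regions: Sequence, path: str | Path) -> None:
    """Write outlier regions as BED6 (0-based half-open; score = peak stat).

    Internal spans are 1-based inclusive, so bed_start = start - 1 and
    bed_end = end.  Regions are written sorted by (scaffold, start).
    """
    rows = sorted(regions, key=lambda r: (r.scaffold, r.start, r.end))
    with _atomic_open(path) as fh:
        for i, r in enumerate(rows, start=1):
            score = getattr(r, "peak_stat", 0.0)
            name = getattr(r, "name", f"region_{i}")
            fh.write(
                f"{r.scaffold}\t{r.start - 1}\t{r.end}\t{name}\t{score:.6g}\t.\n"
            )


def read_regions_bed(path: str | Path) -> list[tuple[str, int, int, str, float]]:
    """Read a BED written by :func:`write_regions_bed` back to 1-based spans."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            scaffold, bed_start, bed_end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            score = float(parts[4]) if len(parts) > 4 else 0.0
            out.append((scaffold, bed_start + 1, bed_end, name, score))
    return out


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


class _atomic_open:
    """Write to a temp file and rename into place so outputs are all-or-nothing."""

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def __enter__(self):
        self.path.parent.mkdir(parents=True, exist_ok=True)
        fd, self._tmp = tempfile.mkstemp(
            dir=self.path.parent, prefix=self.path.name + ".", suffix=".tmp"
        )
        self._fh = os.fdopen(fd, "w")
        return self._fh

    def __exit__(self, exc_type, exc, tb):
        self._fh.close()
        if exc_type is None:
            os.replace(self._tmp, self.path)
        else:
            os.unlink(self._tmp)
        return False
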