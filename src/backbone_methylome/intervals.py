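"""Genomic interval algebra for compartment partitioning.

All coordinates are 0-based, half-open (BED convention). The central object
is :class:`RegionSet`, a named collection of intervals that is normalized
(sorted, merged, non-overlapping) on construction. The compartment taxonomy
— CpG islands, shores, promoters, 5'-bodies, exons, DNase hypersensitive
sites, TF-binding sites, enhancers, repeats — is built from these sets, and
the "backbone" is the genome complement of their union: a proxy for
non-functional intergenic sequence where most human CpGs reside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

Genome = Mapping[str, int]  # chrom -> length


class MalformedIntervalError(ValueError):
    """Raised for an interval with end <= start or negative start."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise MalformedIntervalError(
                f"malformed interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene/transcript record: transcript interval, strand, exons."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: Tuple[Tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.end <= self.start:
            raise MalformedIntervalError(f"gene {self.gene_id}: end <= start")
        for s, e in self.exons:
            if s < self.start or e > self.end or e <= s:
                raise MalformedIntervalError(
                    f"gene {self.gene_id}: exon {s}-{e} outside transcript"
                )

    @property
    def length(self) -> int:
        return self.end - self.start


def _merge_sorted(arr: np.ndarray) -> np.ndarray:
    """Merge a (n, 2) start/end array sorted by start; abutting intervals merge."""
    if len(arr) == 0:
        return arr.reshape(0, 2)
    out = [arr[0].copy()]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.array(out, dtype=np.int64)


class RegionSet:
    """Named, normalized set of genomic intervals.

    Internally a dict chrom -> (n, 2) int64 array, sorted and merged so no
    two intervals overlap or abut. Construction normalizes its input, so the
    per-base coverage is preserved exactly while the representation is
    canonical; ``normalize`` is therefore idempotent and order-independent.
    """

    def __init__(self, name: str, intervals: Iterable[Tuple[str, int, int]] = ()):
        self.name = name
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start < 0 or end <= start:
                raise MalformedIntervalError(
                    f"malformed interval {chrom}:{start}-{end} in set {name!r}"
                )
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self._by_chrom: Dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            arr = np.array(sorted(ivs), dtype=np.int64).reshape(-1, 2)
            self._by_chrom[chrom] = _merge_sorted(arr)

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_arrays(cls, name: str, by_chrom: Mapping[str, np.ndarray]) -> "RegionSet":
        rs = cls(name)
        for chrom, arr in by_chrom.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if len(arr):
                if (arr[:, 1] <= arr[:, 0]).any() or (arr[:, 0] < 0).any():
                    raise MalformedIntervalError(f"malformed interval in set {name!r}")
                order = np.argsort(arr[:, 0], kind="stable")
                rs._by_chrom[chrom] = _merge_sorted(arr[order])
        return rs

    # -- accessors ------------------------------------------------------------
    @property
    def chroms(self) -> List[str]:
        return sorted(self._by_chrom)

    def arrays(self, chrom: str) -> np.ndarray:
        return self._by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))

    def intervals(self) -> List[GenomicInterval]:
        out = []
        for chrom in self.chroms:
            for s, e in self._by_chrom[chrom]:
                out.append(GenomicInterval(chrom, int(s), int(e)))
        return out

    def total_length(self) -> int:
        return int(
            sum((arr[:, 1] - arr[:, 0]).sum() for arr in self._by_chrom.values())
        )

    def __len__(self) -> int:
        return sum(len(arr) for arr in self._by_chrom.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        if set(self._by_chrom) != set(other._by_chrom):
            a = {c for c, v in self._by_chrom.items() if len(v)}
            b = {c for c, v in other._by_chrom.items() if len(v)}
            if a != b:
                return False
        return all(
            np.array_equal(self.arrays(c), other.arrays(c))
            for c in set(self.chroms) | set(other.chroms)
        )

    def __repr__(self) -> str:
        return (
            f"RegionSet({self.name!r}, n={len(self)}, bp={self.total_length()})"
        )

    # -- membership -----------------------------------------------------------
    def contains(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized half-open membership test for positions on one chromosome."""
        arr = self.arrays(chrom)
        positions = np.asarray(positions)
        if len(arr) == 0:
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(arr[:, 0], positions, side="right") - 1
        ok = idx >= 0
        res = np.zeros(positions.shape, dtype=bool)
        res[ok] = positions[ok] < arr[idx[ok], 1]
        return res

    # -- algebra --------------------------------------------------------------
    def union(self, other: "RegionSet", name: str | None = None) -> "RegionSet":
        merged: Dict[str, np.ndarray] = {}
        for chrom in set(self._by_chrom) | set(other._by_chrom):
            both = np.vstack([self.arrays(chrom), other.arrays(chrom)])
            order = np.argsort(both[:, 0], kind="stable")
            merged[chrom] = _merge_sorted(both[order])
        return RegionSet.from_arrays(name or f"{self.name}|{other.name}", merged)

    def subtract(self, other: "RegionSet", name: str | None = None) -> "RegionSet":
        """Bases in self but not in other."""
        out: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, mine in self._by_chrom.items():
            theirs = other.arrays(chrom)
            res: List[Tuple[int, int]] = []
            j = 0
            for s, e in mine:
                cur = s
                while j < len(theirs) and theirs[j][1] <= cur:
                    j += 1
                k = j
                while k < len(theirs) and theirs[k][0] < e:
                    ts, te = theirs[k]
                    if ts > cur:
                        res.append((cur, int(ts)))
                    cur = max(cur, int(te))
                    if cur >= e:
                        break
                    k += 1
                if cur < e:
                    res.append((int(cur), int(e)))
            if res:
                out[chrom] = np.array(res, dtype=np.int64)
        return RegionSet.from_arrays(name or f"{self.name}-{other.name}", out)

    def intersect(self, other: "RegionSet", name: str | None = None) -> "RegionSet":
        return self.subtract(self.subtract(other), name or f"{self.name}&{other.name}")


def union_all(sets: Sequence[RegionSet], name: str = "union") -> RegionSet:
    out = RegionSet(name)
    for rs in sets:
        out = out.union(rs, name)
    return out


def normalize(regions: RegionSet) -> RegionSet:
    """Return a sorted, merged, non-overlapping copy covering the same bases.

    RegionSet already normalizes on construction, so this is the identity for
    an existing set; it exists as the named operation of the partition algebra.
    """
    return RegionSet.from_arrays(regions.name, regions._by_chrom)


def genome_regions(genome: Genome, name: str = "genome") -> RegionSet:
    return RegionSet(name, [(c, 0, int(l)) for c, l in genome.items() if l > 0])


def shore_of(cgis: RegionSet, genome: Genome, flank: int = 2000) -> RegionSet:
    """CGI shores: the ±`flank` bp regions around each CGI boundary.

    CGI bases themselves are excluded (shores and islands are distinct
    compartment classes); flanks are clipped to chromosome bounds, and bases
    between nearby islands are counted once.
    """
    flanks: List[Tuple[str, int, int]] = []
    for chrom in cgis.chroms:
        L = genome.get(chrom)
        if L is None:
            continue
        for s, e in cgis.arrays(chrom):
            ls, le = max(0, int(s) - flank), int(s)
            if le > ls:
                flanks.append((chrom, ls, le))
            rs, re = int(e), min(L, int(e) + flank)
            if re > rs:
                flanks.append((chrom, rs, re))
    return RegionSet("shore", flanks).subtract(cgis, "shore")


def promoter_of(gene: GeneModel, genome: Genome, length: int = 1500) -> GenomicInterval:
    """The 0–`length` bp region immediately upstream of the TSS.

    Strand-aware: upstream of `start` for + genes, of `end` for − genes.
    Clipped to chromosome bounds. Undefined for strandless records.
    """
    L = genome[gene.chrom]
    if gene.strand == "+":
        s, e = max(0, gene.start - length), gene.start
    else:
        s, e = gene.end, min(L, gene.end + length)
    if e <= s:
        raise MalformedIntervalError(
            f"gene {gene.gene_id}: promoter degenerate at chromosome edge"
        )
    return GenomicInterval(gene.chrom, s, e, gene.strand)


def five_prime_body_of(gene: GeneModel, fraction: float = 0.1) -> GenomicInterval:
    """First `fraction` of the gene body measured from the 5' end.

    Fractional length is floor(fraction * length) with a 1 bp minimum.
    """
    flen = max(1, int(np.floor(fraction * gene.length)))
    if gene.strand == "+":
        return GenomicInterval(gene.chrom, gene.start, gene.start + flen, "+")
    return GenomicInterval(gene.chrom, gene.end - flen, gene.end, "-")


def build_backbone(
    genome: Genome, functional: Sequence[RegionSet], repeats: RegionSet
) -> RegionSet:
    """The genome complement of the functional compartments plus repeats.

    backbone = genome − (CGI ∪ shore ∪ promoter ∪ 5'-body ∪ exon ∪ DNase ∪
    TF sites ∪ enhancer ∪ repeats). Repeats are removed for the same reason
    array studies mask them: cross-hybridization and copy-number artifacts.
    """
    everything = union_all(list(functional) + [repeats], "functional|repeats")
    return genome_regions(genome).subtract(everything, "backbone")


def build_gene_region_sets(
    genes: Sequence[GeneModel],
    genome: Genome,
    promoter_length: int = 1500,
    body_fraction: float = 0.1,
) -> Dict[str, RegionSet]:
    """Promoter, 5'-body and exon sets from gene/transcript records.

    One promoter/5'-body per supplied record; overlaps between transcripts
    of one gene are deduplicated by normalization.
    """
    proms, bodies, exons = [], [], []
    for g in genes:
        p = promoter_of(g, genome, promoter_length)
        proms.append((p.chrom, p.start, p.end))
        b = five_prime_body_of(g, body_fraction)
        bodies.append((b.chrom, b.start, b.end))
        for s, e in g.exons:
            exons.append((g.chrom, s, e))
    return {
        "promoter": RegionSet("promoter", proms),
        "five_prime_body": RegionSet("five_prime_body", bodies),
        "exon": RegionSet("exon", exons),
    }
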