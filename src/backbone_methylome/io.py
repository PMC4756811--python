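"""Readers and writers for the plain-text formats the pipeline exchanges.

BED3/BED6 (tab-separated, 0-based half-open), a two-column genome file
(chrom<TAB>length), probe manifests, and probes × samples TSV matrices for
beta values and detection p-values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, Genome, RegionSet

MANIFEST_COLUMNS = ["probe_id", "chrom", "pos", "snp_dist", "repeat_within_15bp", "type"]


def read_genome(path: str) -> Genome:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": np.int64}, comment="#")
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_genome(genome: Genome, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bed(path: str, name: Optional[str] = None) -> RegionSet:
    """Read BED3+ into a RegionSet (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={0: str, 1: np.int64, 2: np.int64})
    label = name or os.path.splitext(os.path.basename(path))[0]
    return RegionSet(label, df.itertuples(index=False, name=None))


def read_named_bed(path: str) -> Dict[str, RegionSet]:
    """Read BED with a name column (col 4) into one RegionSet per name.

    Used for TF-binding-site tracks where column 4 carries the factor.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "name"],
                     dtype={0: str, 1: np.int64, 2: np.int64, 3: str})
    out: Dict[str, RegionSet] = {}
    for factor, grp in df.groupby("name", sort=True):
        out[factor] = RegionSet(
            str(factor),
            grp[["chrom", "start", "end"]].itertuples(index=False, name=None),
        )
    return out


def write_bed(regions: RegionSet, path: str, name_col: bool = False) -> None:
    with open(path, "w") as fh:
        for iv in regions.intervals():
            if name_col:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{regions.name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_named_bed(sets: Dict[str, RegionSet], path: str) -> None:
    with open(path, "w") as fh:
        for factor in sorted(sets):
            for iv in sets[factor].intervals():
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{factor}\n")


def read_genes_bed(path: str) -> List[GeneModel]:
    """Gene/transcript records from BED6 (+ optional exon columns 7/8).

    Columns: chrom, start, end, gene_id, score, strand[, exon_starts, exon_ends]
    with exon starts/ends as comma-separated absolute coordinates.
    """
    genes: List[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end, gid, _score, strand = parts[:6]
            exons: tuple = ()
            if len(parts) >= 8 and parts[6] and parts[7]:
                starts = [int(x) for x in parts[6].rstrip(",").split(",")]
                ends = [int(x) for x in parts[7].rstrip(",").split(",")]
                exons = tuple(zip(starts, ends))
            genes.append(GeneModel(gid, chrom, int(start), int(end), strand, exons))
    return genes


def write_genes_bed(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons)
            ends = ",".join(str(e) for _, e in g.exons)
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}"
                     f"\t{starts}\t{ends}\n")


def read_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    missing = set(MANIFEST_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def write_manifest(manifest: pd.DataFrame, path: str) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_matrix(path: str) -> pd.DataFrame:
    """Probes × samples TSV matrix (first column = probe_id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index_label="probe_id", float_format=float_format)


@dataclass
class BetaMatrix:
    """Beta values (probes × samples) with a parallel boolean mask.

    mask is True where a cell is unusable (failed detection, filtered probe);
    unmasked values lie in [0, 1].
    """

    values: pd.DataFrame
    mask: pd.DataFrame

    def __post_init__(self):
        if self.mask is None:
            self.mask = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not self.values.index.is_unique or not self.values.columns.is_unique:
            raise ValueError("probe ids and sample ids must be unique")
        usable = self.values.values[~self.mask.values]
        usable = usable[~np.isnan(usable)]
        if len(usable) and (usable.min() < 0 or usable.max() > 1):
            raise ValueError("unmasked beta values outside [0, 1]")

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        keep = self.values.index.intersection(pd.Index(probe_ids))
        return BetaMatrix(self.values.loc[keep], self.mask.loc[keep])

    def masked_values(self) -> pd.DataFrame:
        """Values with masked cells as NaN."""
        return self.values.mask(self.mask)

    @classmethod
    def from_files(cls, beta_path: str, mask_path: Optional[str] = None) -> "BetaMatrix":
        values = read_matrix(beta_path)
        mask = read_matrix(mask_path).astype(bool) if mask_path else None
        return cls(values, mask)

    def to_files(self, beta_path: str, mask_path: Optional[str] = None) -> None:
        write_matrix(self.values, beta_path)
        if mask_path:
            write_matrix(self.mask.astype(int), mask_path, float_format="%d")


def write_bedgraph(track: pd.DataFrame, path: str) -> None:
    """Write a chrom/start/end/value DataFrame as bedGraph (missing dropped)."""
    out = track.dropna(subset=["value"])
    out[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )
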