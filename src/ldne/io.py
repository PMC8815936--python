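"""File formats: minimal VCF, genetic-map sidecar, BED-like tracks.

Conventions: VCF positions are 1-based (standard); everything internal
is 0-based half-open bp, converted only here.  The genetic map dialect
is three whitespace-separated, headered columns (chrom, position_bp,
cumulative cM), matching common published human-map distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .maps import GenomeMap, RecombinationMap
from .simulate import HaplotypeSample

__all__ = ["GenotypeData", "write_vcf", "read_vcf", "write_genetic_map",
           "read_genetic_map", "write_track", "read_track"]

logger = logging.getLogger(__name__)


@dataclass
class GenotypeData:
    """Genotypes for one chromosome as loaded from VCF.

    `haplotypes` is the phased 2n x S matrix when every genotype was
    phased, else None; `dosages` (n x S) is always available and feeds
    the composite-LD (unphased) estimators.
    """

    chrom: str
    positions_bp: np.ndarray           # 0-based
    dosages: np.ndarray                # (n, S) int8
    haplotypes: np.ndarray | None      # (2n, S) uint8 or None
    n_skipped: int = 0

    @property
    def phased(self) -> bool:
        return self.haplotypes is not None

    def to_sample(self, rmap: RecombinationMap, length_bp: int | None = None) -> HaplotypeSample:
        """Phased haplotype sample with map positions attached."""
        if self.haplotypes is None:
            raise ValueError(
                "unphased genotypes cannot feed the phased estimator; "
                "use composite (unphased) LD mode")
        return HaplotypeSample(self.haplotypes, self.positions_bp,
                               np.asarray(rmap.morgans_at(self.positions_bp), dtype=float),
                               length_bp or rmap.length_bp, self.chrom)


def write_vcf(samples: dict[str, HaplotypeSample], path, sample_prefix: str = "ind") -> None:
    """Minimal VCF 4.2 with phased GT fields, one contig per chromosome."""
    samples = dict(samples)
    n_h = {s.n_haplotypes for s in samples.values()}
    if len(n_h) != 1:
        raise ValueError("all chromosomes must have the same sample size")
    n = n_h.pop() // 2
    names = [f"{sample_prefix}{i + 1}" for i in range(n)]
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ldne\n")
        for chrom, s in samples.items():
            fh.write(f"##contig=<ID={chrom},length={s.sequence_length_bp}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for chrom, s in samples.items():
            mat = s.matrix
            for j in range(s.n_sites):
                col = mat[:, j]
                gts = "\t".join(f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n))
                fh.write(f"{chrom}\t{s.positions_bp[j] + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path, strict: bool = False) -> dict[str, GenotypeData]:
    """Load biallelic SNP genotypes per chromosome.

    Multi-allelic or missing-GT records are skipped with a logged count
    (`strict=True` raises instead).  If any genotype is unphased the
    chromosome is returned in dosage-only form.
    """
    vcf = VCF(str(path), gts012=True)
    per_chrom: dict[str, dict] = {}
    for var in vcf:
        store = per_chrom.setdefault(var.CHROM, {
            "pos": [], "gt": [], "phased": True, "skipped": 0})
        genotypes = var.genotypes
        if (len(var.ALT) != 1 or var.num_unknown > 0
                or any(g[0] < 0 or g[1] < 0 for g in genotypes)):
            if strict:
                raise ValueError(
                    f"record {var.CHROM}:{var.POS} is not a fully-called biallelic SNP")
            store["skipped"] += 1
            continue
        store["pos"].append(var.POS - 1)
        store["gt"].append([(g[0], g[1]) for g in genotypes])
        if not all(g[2] for g in genotypes):
            store["phased"] = False
    out: dict[str, GenotypeData] = {}
    for chrom, store in per_chrom.items():
        if store["skipped"]:
            logger.info("chromosome %s: skipped %d non-biallelic/missing records",
                        chrom, store["skipped"])
        pos = np.asarray(store["pos"], dtype=np.int64)
        gt = np.asarray(store["gt"], dtype=np.int8)       # (S, n, 2)
        if gt.size == 0:
            out[chrom] = GenotypeData(chrom, pos, np.empty((0, 0), np.int8), None,
                                      store["skipped"])
            continue
        dosages = gt.sum(axis=2).T.astype(np.int8)        # (n, S)
        haps = None
        if store["phased"]:
            s_count, n, _ = gt.shape
            haps = gt.transpose(1, 2, 0).reshape(2 * n, s_count).astype(np.uint8)
        out[chrom] = GenotypeData(chrom, pos, dosages, haps, store["skipped"])
    return out


def write_genetic_map(genome_map: GenomeMap, path, anchors_per_segment: int = 1) -> None:
    """Headered sidecar: chrom, position_bp, cumulative cM."""
    rows = []
    for chrom, rmap in genome_map.items():
        bps = np.append(rmap.segment_starts_bp, rmap.length_bp)
        for bp in bps:
            rows.append((chrom, int(bp), float(rmap.morgans_at(bp)) * 100.0))
    frame = pd.DataFrame(rows, columns=["chrom", "position_bp", "cM"])
    frame.to_csv(path, sep="\t", index=False)


def read_genetic_map(path, chrom_lengths: dict[str, int] | None = None) -> GenomeMap:
    """Piecewise-linear cumulative map from (chrom, bp, cM) anchors."""
    frame = pd.read_csv(path, sep=r"\s+")
    frame.columns = [c.lower() for c in frame.columns]
    cols = list(frame.columns[:3])
    gmap = GenomeMap()
    for chrom, sub in frame.groupby(cols[0], sort=False):
        pos = sub[cols[1]].to_numpy(np.int64)
        cm = sub[cols[2]].to_numpy(float)
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"cumulative cM decreases on chromosome {chrom}")
        length = chrom_lengths.get(str(chrom)) if chrom_lengths else None
        gmap[str(chrom)] = RecombinationMap.from_anchors(pos, cm, length)
    return gmap


def write_track(frame: pd.DataFrame, path) -> None:
    """BED-like TSV: chrom, start, end, value (0-based half-open)."""
    frame[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", index=False, header=False)


def read_track(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "value"],
                       dtype={"chrom": str})
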