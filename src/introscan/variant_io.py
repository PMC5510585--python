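"""Readers, writers and genetic-map utilities.

The pipeline works on three in-memory containers:

* :class:`GenotypeMatrix` — diploid alternate-allele dosages (0/1/2, with a
  missing sentinel) for all samples, each tagged with a group
  (``ref_a`` / ``ref_b`` / ``admixed``);
* :class:`HaplotypePanel` — a phased binary haplotype matrix (2n x m) used by
  the haplotype-homozygosity statistics;
* :class:`GeneticMap` — per-site genetic positions (cM), either read from a
  PLINK-like table or built with the uniform-rate construction
  (genetic position proportional to physical position).

Internal coordinates are 1-based inclusive (the VCF convention); BED output is
converted to 0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger("introscan")

#: Sentinel for a missing diploid genotype in a dosage matrix.
MISSING: int = -1

#: Recognised sample group labels.
GROUPS = ("ref_a", "ref_b", "admixed")

SITE_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


def _as_site_table(sites: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise ValueError(f"site table lacks columns {missing}")
    pos = sites["pos"].to_numpy()
    if np.any(np.diff(pos) <= 0):
        raise ValueError("site positions must be strictly increasing")
    return sites.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix (n samples x m sites) with group labels."""

    samples: list[str]
    groups: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray  # (n, m) int8; MISSING for no-calls

    def __post_init__(self) -> None:
        self.sites = _as_site_table(self.sites)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        if n != len(self.samples) or n != len(self.groups):
            raise ValueError("sample/group/dosage dimensions disagree")
        if m != len(self.sites):
            raise ValueError("site/dosage dimensions disagree")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be 0/1/2 or MISSING")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def group_index(self, group: str) -> np.ndarray:
        """Row indices of the samples belonging to ``group``."""
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
        return np.flatnonzero(np.asarray(self.groups) == group)

    def subset_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            groups=list(self.groups),
            sites=self.sites.iloc[idx],
            dosage=self.dosage[:, idx],
        )


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes (2n x m); rows 2i, 2i+1 belong to sample i."""

    samples: list[str]
    groups: list[str]
    sites: pd.DataFrame
    haplotypes: np.ndarray  # (2n, m) uint8 in {0, 1}

    def __post_init__(self) -> None:
        self.sites = _as_site_table(self.sites)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape[0] != 2 * len(self.samples):
            raise ValueError("haplotype rows must be 2 x n_samples")
        if self.haplotypes.shape[1] != len(self.sites):
            raise ValueError("site/haplotype dimensions disagree")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def sample_of_origin(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.samples)), 2)

    def group_panel(self, group: str) -> "HaplotypePanel":
        """Sub-panel holding only the samples of one group."""
        keep = np.flatnonzero(np.asarray(self.groups) == group)
        rows = np.sort(np.concatenate([2 * keep, 2 * keep + 1]))
        return HaplotypePanel(
            samples=[self.samples[i] for i in keep],
            groups=[self.groups[i] for i in keep],
            sites=self.sites,
            haplotypes=self.haplotypes[rows],
        )

    def subset_sites(self, idx: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return HaplotypePanel(
            samples=list(self.samples),
            groups=list(self.groups),
            sites=self.sites.iloc[idx],
            haplotypes=self.haplotypes[:, idx],
        )

    def to_genotypes(self, missing: np.ndarray | None = None) -> GenotypeMatrix:
        """Collapse haplotype pairs to dosages, optionally masking genotypes."""
        dos = (self.haplotypes[0::2].astype(np.int8) + self.haplotypes[1::2])
        if missing is not None:
            dos = dos.copy()
            dos[np.asarray(missing, dtype=bool)] = MISSING
        return GenotypeMatrix(
            samples=list(self.samples),
            groups=list(self.groups),
            sites=self.sites,
            dosage=dos,
        )


@dataclass
class GeneticMap:
    """Non-decreasing genetic positions (cM) at known physical positions."""

    pos: np.ndarray  # bp, strictly increasing
    cm: np.ndarray   # cM, non-decreasing

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if self.pos.shape != self.cm.shape:
            raise ValueError("pos/cm must have equal length")
        if np.any(np.diff(self.pos) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("genetic positions must be non-decreasing")

    @property
    def total_cm(self) -> float:
        return float(self.cm[-1])

    def interpolate(self, bp) -> np.ndarray:
        """Genetic position (cM) at physical position(s) by linear interpolation."""
        bp = np.asarray(bp, dtype=float)
        if np.any(bp < self.pos[0]) or np.any(bp > self.pos[-1]):
            raise ValueError("query position outside the mapped span")
        return np.interp(bp, self.pos, self.cm)


@dataclass
class VcfContents:
    """What :func:`read_vcf` recovered from a file."""

    genotypes: GenotypeMatrix
    haplotypes: HaplotypePanel | None
    n_skipped: int = 0


def read_vcf(path, group_assignments: dict[str, str]) -> VcfContents:
    """Read a biallelic-SNP VCF into a dosage matrix (and panel if fully phased).

    Multiallelic and non-SNP records are skipped and counted; ``./.`` (and
    half-missing) genotypes become :data:`MISSING`.  A
    :class:`HaplotypePanel` is returned only when every genotype is phased and
    called, since binary haplotypes cannot represent missing alleles.

    Parameters
    ----------
    path
        VCF 4.x file (plain or bgzipped).
    group_assignments
        Mapping sample name -> ``ref_a`` / ``ref_b`` / ``admixed``.  Every
        sample in the file must be assigned.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in group_assignments:
            raise KeyError(f"sample {s!r} has no group assignment")
    groups = [group_assignments[s] for s in samples]
    for s, g in zip(samples, groups):
        if g not in GROUPS:
            raise ValueError(f"sample {s!r} assigned unknown group {g!r}")

    rows_dos: list[np.ndarray] = []
    rows_hap: list[np.ndarray] = []
    site_rows = []
    n_skipped = 0
    all_phased = True
    for rec_no, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        n_s = len(samples)
        a0 = np.full(n_s, -1, dtype=np.int64)
        a1 = np.full(n_s, -1, dtype=np.int64)
        phased = np.zeros(n_s, dtype=bool)
        for i, g in enumerate(rec.genotypes):
            if len(g) >= 3:
                a0[i], a1[i], phased[i] = g[0], g[1], bool(g[2])
            elif len(g) == 2:  # haploid call: treat as missing diploid
                phased[i] = False
            else:
                raise ValueError(f"malformed GT at record {rec_no}")
        if np.any(a0 > 1) or np.any(a1 > 1):
            raise ValueError(f"malformed GT allele index at record {rec_no}")
        called = (a0 >= 0) & (a1 >= 0)
        dos = np.where(called, a0 + a1, MISSING).astype(np.int8)
        if not (phased.all() and called.all()):
            all_phased = False
        rows_dos.append(dos)
        rows_hap.append(np.stack([a0, a1], axis=1).ravel())
        site_rows.append(
            (rec.CHROM, rec.POS, rec.ID or f"{rec.CHROM}:{rec.POS}", rec.REF, rec.ALT[0])
        )
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    sites = pd.DataFrame(site_rows, columns=SITE_COLUMNS)
    dosage = np.array(rows_dos, dtype=np.int8).T.reshape(len(samples), -1)
    gm = GenotypeMatrix(samples=samples, groups=groups, sites=sites, dosage=dosage)
    panel = None
    if all_phased and len(site_rows):
        hap = np.array(rows_hap, dtype=np.uint8).T.reshape(2 * len(samples), -1)
        panel = HaplotypePanel(
            samples=samples, groups=groups, sites=sites, haplotypes=hap
        )
    return VcfContents(genotypes=gm, haplotypes=panel, n_skipped=n_skipped)


def write_vcf(path, panel: HaplotypePanel, missing: np.ndarray | None = None) -> None:
    """Write a phased single-contig VCF 4.2 (``a|b`` genotypes).

    ``missing`` is an optional (n_samples x m) boolean mask of genotypes to
    emit as ``.|.``, matching what :func:`read_vcf` maps back to
    :data:`MISSING`.
    """
    sites = panel.sites
    hap = panel.haplotypes
    if missing is None:
        missing = np.zeros((len(panel.samples), panel.n_sites), dtype=bool)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={sites['chrom'].iloc[0]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        for j in range(panel.n_sites):
            row = sites.iloc[j]
            gts = [
                ".|." if missing[i, j] else f"{hap[2 * i, j]}|{hap[2 * i + 1, j]}"
                for i in range(len(panel.samples))
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def filter_missingness(gm: GenotypeMatrix, max_missing_fraction: float) -> GenotypeMatrix:
    """Drop sites whose missing-call fraction exceeds the threshold.

    Sites that are monomorphic among the remaining called genotypes are also
    removed: they carry no information for differentiation or ancestry.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    miss = gm.dosage == MISSING
    frac = miss.mean(axis=0)
    keep = frac <= max_missing_fraction
    # monomorphic among called genotypes (or entirely missing)
    called = ~miss
    alt = np.where(called, gm.dosage, 0).sum(axis=0)
    n_alleles = 2 * called.sum(axis=0)
    poly = (alt > 0) & (alt < n_alleles)
    keep &= poly
    if not keep.any():
        warnings.warn("filter_missingness removed every site", stacklevel=2)
    return gm.subset_sites(np.flatnonzero(keep))


def build_uniform_map(sites, total_cm: float | None = None,
                      rate_cm_per_mb: float = 1.0) -> GeneticMap:
    """Uniform-rate genetic map: cM position proportional to physical position.

    Site ``i`` is placed at ``pos_i / pos_last * total_cm``, i.e. the genetic
    position is the ratio of the physical position to the last site's
    position, scaled to the chromosome's genetic length.  When ``total_cm`` is
    not given it defaults to ``pos_last * rate_cm_per_mb / 1e6`` (1 cM/Mb).
    """
    if isinstance(sites, pd.DataFrame):
        pos = sites["pos"].to_numpy(dtype=np.int64)
    else:
        pos = np.asarray(sites, dtype=np.int64)
    if pos.size < 2:
        raise ValueError("a genetic map needs at least two sites")
    if total_cm is None:
        total_cm = float(pos[-1]) * rate_cm_per_mb / 1e6
    cm = pos / float(pos[-1]) * total_cm
    return GeneticMap(pos=pos, cm=cm)


def genetic_length(gmap: GeneticMap, bp_start: int, bp_end: int) -> float:
    """Genetic length (cM) of ``[bp_start, bp_end]`` by linear interpolation."""
    if bp_end < bp_start:
        raise ValueError("bp_end must be >= bp_start")
    lo, hi = gmap.interpolate([bp_start, bp_end])
    return float(hi - lo)


def read_map(path) -> GeneticMap:
    """Read a genetic map TSV with columns (chrom, pos, cM)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "pos", "cm"])
    return GeneticMap(pos=df["pos"].to_numpy(), cm=df["cm"].to_numpy())


def write_map(path, chrom: str, gmap: GeneticMap) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tcm\n")
        for p, c in zip(gmap.pos, gmap.cm):
            fh.write(f"{chrom}\t{p}\t{c:.8f}\n")


def write_bed(path, regions) -> None:
    """Write 1-based inclusive intervals ``(chrom, start, end)`` as BED3.

    BED is 0-based half-open, so an internal interval ``[start, end]`` becomes
    the line ``chrom <start-1> <end>``.
    """
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{int(start) - 1}\t{int(end)}\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read BED3 back into 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append((chrom, int(start) + 1, int(end)))
    return out


def write_table(path, df: pd.DataFrame) -> None:
    """TSV with a single '#'-commented header line."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_groups(path) -> dict[str, str]:
    """Read a two-column (sample, group) TSV into an assignment mapping."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["sample", "group"])
    return dict(zip(df["sample"], df["group"]))


def write_groups(path, samples, groups) -> None:
    with open(path, "w") as fh:
        fh.write("#sample\tgroup\n")
        for s, g in zip(samples, groups):
            fh.write(f"{s}\t{g}\n")
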