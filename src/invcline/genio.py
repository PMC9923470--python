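"""Genotype matrix container, VCF/TSV input-output, site filters and LD pruning.

The central container is :class:`GenotypeMatrix`: a site-major matrix of
alternate-allele dosages (0, 1, 2; ``-1`` for a missing call) together with a
site table (contig, bp position, optional linkage-group/cM columns joined from
a genetic map) and the sample identifiers.  All downstream statistics operate
on this container.

Filtering follows the conventional WGS pipeline for transect data: minor
allele frequency, per-site call rate, observed heterozygosity (paralog
screen), mean sequencing depth (paralog/duplication screen), then greedy
physical-distance LD pruning at one SNP per window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1

SAMPLE_COLUMNS = ["id", "transect", "path_pos_m", "size_mm", "sex"]
MAP_COLUMNS = ["contig", "lg", "cM"]


@dataclass
class GenotypeMatrix:
    """Biallelic dosage matrix (sites x individuals) with site metadata.

    ``dosages`` holds counts of the alternate allele; ``MISSING`` (-1) marks
    uncalled genotypes.  ``sites`` is indexed positionally and carries at
    least ``contig``, ``pos``, ``ref``, ``alt`` and ``mean_depth`` columns;
    after :func:`attach_map` it also carries ``lg`` and ``cM``.
    """

    dosages: np.ndarray
    sites: pd.DataFrame
    samples: list[str]
    depths: np.ndarray | None = None  # per-genotype DP, same shape as dosages

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (sites x individuals)")
        if len(self.sites) != self.dosages.shape[0]:
            raise ValueError("site table length does not match dosage rows")
        if len(self.samples) != self.dosages.shape[1]:
            raise ValueError("sample list length does not match dosage columns")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages outside {0,1,2,missing}")

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def called(self) -> np.ndarray:
        """Boolean mask of called genotypes."""
        return self.dosages != MISSING

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per site over called genotypes."""
        called = self.called()
        n = called.sum(axis=1)
        alt = np.where(called, self.dosages, 0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return self.called().mean(axis=1)

    def hobs_per_site(self) -> np.ndarray:
        """Observed heterozygosity per site over called genotypes."""
        called = self.called()
        n = called.sum(axis=1)
        het = (self.dosages == 1).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, het / n, np.nan)

    def mean_depth(self) -> np.ndarray:
        if self.depths is not None:
            d = np.asarray(self.depths, dtype=float)
            return d.mean(axis=1)
        if "mean_depth" in self.sites:
            return self.sites["mean_depth"].to_numpy(float)
        return np.full(self.n_sites, np.nan)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[index],
            self.sites.iloc[index].reset_index(drop=True),
            list(self.samples),
            None if self.depths is None else self.depths[index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.sites.copy(),
            [self.samples[i] for i in index],
            None if self.depths is None else self.depths[:, index],
        )


@dataclass
class FilterConfig:
    """Site-filter thresholds.

    Defaults mirror the usual transect pipeline: alleles above 1% frequency,
    sites called in at least 90% of individuals, observed heterozygosity at
    most 0.6 and mean depth at most 10x (both to screen collapsed paralogs),
    and one SNP per kilobase after pruning.
    """

    min_maf: float = 0.01
    min_call_rate: float = 0.90
    max_hobs: float = 0.6
    max_mean_depth: float = 10.0
    prune_window_bp: int = 1000

    def __post_init__(self) -> None:
        if not (0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must be in [0, 0.5]")
        if not (0 <= self.min_call_rate <= 1):
            raise ValueError("min_call_rate must be in [0, 1]")
        if not (0 <= self.max_hobs <= 1):
            raise ValueError("max_hobs must be in [0, 1]")
        if self.max_mean_depth <= 0:
            raise ValueError("max_mean_depth must be positive")
        if self.prune_window_bp <= 0:
            raise ValueError("prune_window_bp must be positive")


# ---------------------------------------------------------------------------
# VCF IO
# ---------------------------------------------------------------------------

_GT_TYPE_TO_DOSAGE = {0: 0, 1: 1, 2: MISSING, 3: 2}  # cyvcf2 gt_types coding


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNPs are retained; multi-allelic or non-SNP records are
    skipped with a logged count.  ``./.`` genotypes become missing dosages.
    Per-genotype DP is kept when present.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, meta, depth_rows = [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        # gts012=True: 0/1/2 = dosage, 3 = unknown
        dos = np.asarray(var.gt_types, dtype=np.int16)
        dos[dos == 3] = MISSING
        rows.append(dos.astype(np.int8))
        try:
            dp = var.format("DP")
        except KeyError:  # DP absent from the header entirely
            dp = None
        if dp is not None:
            dp = np.asarray(dp, dtype=float).reshape(-1)
            dp[dp < 0] = 0
            depth_rows.append(dp)
            mean_dp = float(np.mean(dp))
        else:
            depth_rows.append(None)
            mean_dp = np.nan
        meta.append((var.CHROM, var.POS, var.REF, var.ALT[0], mean_dp))
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)
    if not rows:
        raise ValueError(f"no biallelic SNPs found in {path}")
    sites = pd.DataFrame(meta, columns=["contig", "pos", "ref", "alt", "mean_depth"])
    depths = None
    if all(d is not None for d in depth_rows):
        depths = np.asarray(depth_rows, dtype=np.int32)
    return GenotypeMatrix(np.asarray(rows), sites, samples, depths)


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF v4.2 (GT:DP) that round-trips through read_vcf."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for contig in pd.unique(g.sites["contig"]):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        has_dp = g.depths is not None
        fmt = "GT:DP" if has_dp else "GT"
        contigs = g.sites["contig"].to_numpy()
        positions = g.sites["pos"].to_numpy()
        refs = g.sites["ref"].to_numpy()
        alts = g.sites["alt"].to_numpy()
        for j in range(g.n_sites):
            cells = []
            for i in range(g.n_samples):
                gt = _DOSAGE_TO_GT[int(g.dosages[j, i])]
                if has_dp:
                    cells.append(f"{gt}:{int(g.depths[j, i])}")
                else:
                    cells.append(gt)
            fh.write(
                f"{contigs[j]}\t{positions[j]}\t.\t{refs[j]}\t{alts[j]}\t.\tPASS\t.\t"
                + fmt
                + "\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Sample / map tables
# ---------------------------------------------------------------------------


def read_tables(
    sample_path: str, map_path: str
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Read the sample TSV and genetic-map TSV.

    Returns ``(samples, genmap, warnings)``.  Duplicate sample ids and
    contigs mapped to more than one position are reported as warnings;
    samples without a path position are rejected.
    """
    samples = pd.read_csv(sample_path, sep="\t")
    genmap = pd.read_csv(map_path, sep="\t")
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing_cols:
        raise ValueError(f"sample table missing columns: {missing_cols}")
    missing_cols = [c for c in MAP_COLUMNS if c not in genmap.columns]
    if missing_cols:
        raise ValueError(f"map table missing columns: {missing_cols}")
    warnings: list[str] = []
    dup = samples["id"][samples["id"].duplicated()].tolist()
    if dup:
        warnings.append(f"duplicate sample ids: {dup}")
    dupc = genmap["contig"][genmap["contig"].duplicated()].tolist()
    if dupc:
        warnings.append(f"contigs with multiple map positions: {dupc}")
        genmap = genmap.drop_duplicates("contig", keep="first")
    no_pos = samples["path_pos_m"].isna()
    if no_pos.any():
        warnings.append(
            f"rejected {int(no_pos.sum())} samples without a path position"
        )
        samples = samples[~no_pos].reset_index(drop=True)
    for w in warnings:
        logger.warning("read_tables: %s", w)
    return samples, genmap, warnings


def attach_map(g: GenotypeMatrix, genmap: pd.DataFrame) -> GenotypeMatrix:
    """Join linkage-group and cM positions onto the site table.

    Sites on contigs absent from the map keep NaN cM and are flagged
    ``unplaced``.
    """
    sites = g.sites.drop(columns=[c for c in ("lg", "cM") if c in g.sites])
    merged = sites.merge(
        genmap.drop_duplicates("contig")[MAP_COLUMNS], on="contig", how="left"
    )
    merged["unplaced"] = merged["cM"].isna()
    n_unplaced = int(merged["unplaced"].sum())
    if n_unplaced:
        logger.warning("attach_map: %d sites on unmapped contigs", n_unplaced)
    return GenotypeMatrix(g.dosages, merged, list(g.samples), g.depths)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def apply_site_filters(
    g: GenotypeMatrix, f: FilterConfig | None = None
) -> tuple[GenotypeMatrix, dict]:
    """Apply the site filters in fixed order MAF -> call rate -> H_obs -> depth.

    The report counts removals per rule *in application order*, so a site
    failing several rules is charged to the first one.
    """
    if f is None:
        f = FilterConfig()
    report: dict = {"input_sites": g.n_sites}
    keep = np.ones(g.n_sites, dtype=bool)

    maf = g.maf()
    fail = keep & ~(maf >= f.min_maf)  # NaN MAF (all-missing) fails here
    report["removed_maf"] = int(fail.sum())
    keep &= ~fail

    cr = g.call_rate()
    fail = keep & (cr < f.min_call_rate)
    report["removed_call_rate"] = int(fail.sum())
    keep &= ~fail

    hobs = g.hobs_per_site()
    fail = keep & (hobs > f.max_hobs)
    report["removed_hobs"] = int(fail.sum())
    keep &= ~fail

    depth = g.mean_depth()
    fail = keep & (depth > f.max_mean_depth)  # NaN depth passes
    report["removed_depth"] = int(fail.sum())
    keep &= ~fail

    report["output_sites"] = int(keep.sum())
    return g.take_sites(keep), report


def ld_prune(g: GenotypeMatrix, window_bp: int = 1000) -> GenotypeMatrix:
    """Greedy keep-first physical pruning: one SNP per ``window_bp`` per contig.

    Sites must be sorted by (contig, pos); a retained site opens a half-open
    window ``[pos, pos + window_bp)`` and the next site at ``pos + window_bp``
    or beyond is kept.
    """
    contigs = g.sites["contig"].to_numpy()
    pos = g.sites["pos"].to_numpy()
    order = pd.DataFrame({"contig": contigs, "pos": pos})
    if not order.equals(order.sort_values(["contig", "pos"]).reset_index(drop=True)):
        raise ValueError("sites must be sorted by (contig, pos) before pruning")
    keep = np.zeros(g.n_sites, dtype=bool)
    last_contig, last_pos = None, None
    for j in range(g.n_sites):
        if contigs[j] != last_contig or pos[j] - last_pos >= window_bp:
            keep[j] = True
            last_contig, last_pos = contigs[j], pos[j]
    return g.take_sites(keep)
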