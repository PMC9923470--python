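"""Synthetic shore-transect datasets with a segregating chromosomal inversion.

The generator emulates the sampling design the downstream analyses assume:
two independent ~175 m transects across a wave-exposure gradient, each snail
placed uniformly along the shore, its inversion karyotype (L/L, L/D, D/D)
drawn from Hardy-Weinberg proportions with the D-arrangement frequency
following a sigmoid cline.  SNPs live on contigs mapped to a single linkage
group; between-arrangement divergence inside the inversion follows a
suspension-bridge profile along the map (peaks near the breakpoints, sag in
the middle), a configurable fraction of inside SNPs carry fixed differences,
and outside SNPs are drawn from near-identical allele pools.  A nested
three-allele allozyme-like locus (alleles 80/100/120) sits on a designated
contig inside the inversion: the 120 allele rides exclusively on D
haplotypes, 80 and 100 on L haplotypes, encoded so the three alleles are
recoverable as haplotype classes from two diagnostic biallelic SNPs.  Snail
size is dimorphic (large ecotype ~1.5x the dwarf) with the heterokaryotype
intermediate.

Divergence targets are calibrated on the Weir-Cockerham theta scale: for two
demes the large-sample W&C estimate of pools p_bar +/- d is
``2 d^2 / (p_bar q_bar + d^2)``, so hitting a theta target t requires
``d^2 = t p_bar q_bar / (2 - t)``.  The Nei G_ST rule
(``d = sqrt(t p_bar q_bar)``) is also exposed; the two coincide only at
t in {0, 1}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bridgefit import BridgeParams, bridge_expectation
from .clinefit import ClineParams, cline_frequency
from .genio import MISSING, GenotypeMatrix, write_vcf

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimBundle",
    "pool_freqs_for_target_fst",
    "pool_freqs_for_target_theta",
    "simulate_dataset",
    "simulate_contig_fst_observations",
    "write_bundle",
]

KARYOTYPES = ("L/L", "L/D", "D/D")
AK_ALLELES = ("80", "100", "120")


@dataclass
class SimConfig:
    """Study conditions for the synthetic transects.

    Defaults follow the field setting the analyses target: 128 + 167 snails
    on two 175 m transects; a sigmoid arrangement cline of width 65 m with
    near-fixation at the ends; a 69 cM linkage group with the inversion
    spanning cM 11-58; W&C F_ST between arrangements averaging ~0.32 inside
    the inversion (bridge-shaped, peak 0.55 / sag 0.20) and ~0.02 outside,
    with 1% of inside SNPs fixed between arrangements; a three-allele
    allozyme-like locus at ~12 cM from the nearer breakpoint; and a size
    dimorphism of 9 mm vs 6 mm (ratio 1.5) with SD 0.8 mm.
    """

    n_individuals: tuple[int, int] = (128, 167)
    transect_names: tuple[str, str] = ("south", "north")
    transect_length: float = 175.0
    cline_center: float = 85.0  # c_true, m
    cline_width: float = 65.0  # w_true, m
    qmin: float = 0.03  # D-arrangement frequency at x = 0 (exposed end)
    qmax: float = 0.97  # at x = transect_length (sheltered end)
    lg_length: float = 69.0  # cM
    lg_name: str = "LG3"
    inv_start: float = 11.0  # b_true, cM
    inv_span: float = 47.0  # k_true, cM
    m_t: float = 0.02  # background theta target outside the inversion
    peak_t: float = 0.55  # theta target at the breakpoints
    sag_t: float = 0.20  # theta target mid-inversion
    fst_scatter: float = 0.5  # beta concentration of per-SNP theta targets;
    # values < 1 give the U-shaped (bimodal) per-SNP distribution seen in
    # real inversion data: most SNPs weakly differentiated plus a tail of
    # near-fixed differences, averaging to the bridge curve
    n_snps: int = 2000
    n_contigs: int = 250
    contig_length_bp: int = 70_000
    fraction_fixed: float = 0.01
    ak_cm: float = 23.0  # allozyme contig position (12 cM inside b_true)
    n_ak_snps: int = 70
    ak_allele_freqs: tuple[float, float] = (0.19, 0.81)  # (Ak80, Ak100) in L pool
    size_means: tuple[float, float, float] = (9.0, 7.5, 6.0)  # L/L, L/D, D/D mm
    size_sd: float = 0.8
    mean_depth: float = 5.0
    seed: int = 20180401

    def __post_init__(self) -> None:
        if not (0.0 <= self.qmin < self.qmax <= 1.0) and not (
            self.qmin == self.qmax
        ):
            raise ValueError("need 0 <= qmin <= qmax <= 1")
        if not (0.0 < self.inv_start < self.inv_start + self.inv_span
                < self.lg_length):
            raise ValueError("inversion interval must lie inside the LG")
        if not (0.0 <= self.fraction_fixed <= 1.0):
            raise ValueError("fraction_fixed must be in [0, 1]")
        if abs(sum(self.ak_allele_freqs) - 1.0) > 1e-9:
            raise ValueError("ak_allele_freqs must sum to 1")

    def true_cline(self) -> ClineParams:
        return ClineParams(shape="sigmoid", center=self.cline_center,
                           width=self.cline_width, pmin=self.qmin,
                           pmax=self.qmax)

    def true_bridge(self) -> BridgeParams:
        """Bridge profile hitting the configured theta levels (s = 0)."""
        peak_e = self.peak_t - self.m_t
        sag_e = self.sag_t - self.m_t
        k = self.inv_span
        return BridgeParams(
            m=self.m_t, a0=peak_e, a1=4.0 * (sag_e - peak_e) / k,
            a2=4.0 * (peak_e - sag_e) / k**2, b=self.inv_start, k=k,
            l=1.0, r=1.0, s=0.0)


# ---------------------------------------------------------------------------
# pool-frequency rules
# ---------------------------------------------------------------------------


def pool_freqs_for_target_fst(target_fst: float, mean_freq: float
                              ) -> tuple[float, float]:
    """Pool frequencies hitting a Nei G_ST target exactly.

    With d = sqrt(t p q) the two pools p_bar +/- d satisfy
    G_ST = 1 - (p q - d^2)/(p q) = t.
    """
    if not (0.0 <= target_fst <= 1.0):
        raise ValueError("target_fst must be in [0, 1]")
    pq = mean_freq * (1.0 - mean_freq)
    d = np.sqrt(target_fst * pq)
    lo, hi = mean_freq - d, mean_freq + d
    if lo < -1e-12 or hi > 1.0 + 1e-12:
        raise ValueError("infeasible: pool frequencies leave [0, 1]; "
                         "resample mean_freq")
    return float(np.clip(hi, 0, 1)), float(np.clip(lo, 0, 1))


def pool_freqs_for_target_theta(target_theta: float, mean_freq: float
                                ) -> tuple[float, float]:
    """Pool frequencies whose large-sample two-deme W&C theta equals the
    target: d^2 = t p q / (2 - t), theta = 2 d^2 / (p q + d^2)."""
    if not (0.0 <= target_theta <= 1.0):
        raise ValueError("target_theta must be in [0, 1]")
    pq = mean_freq * (1.0 - mean_freq)
    d = np.sqrt(target_theta * pq / (2.0 - target_theta))
    lo, hi = mean_freq - d, mean_freq + d
    if lo < -1e-12 or hi > 1.0 + 1e-12:
        raise ValueError("infeasible: pool frequencies leave [0, 1]; "
                         "resample mean_freq")
    return float(np.clip(hi, 0, 1)), float(np.clip(lo, 0, 1))


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------


@dataclass
class SimTruth:
    karyotypes: list[str]  # aligned with the sample table
    ak_genotypes: list[str]  # e.g. "100/120", alleles sorted
    alpha_l: np.ndarray  # per-SNP alt frequency on L haplotypes
    alpha_d: np.ndarray  # per-SNP alt frequency on D haplotypes
    snp_target_fst: np.ndarray
    snp_is_fixed: np.ndarray
    snp_inside: np.ndarray
    cline: ClineParams
    bridge: BridgeParams
    seed: int

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "karyotypes": self.karyotypes,
            "ak_genotypes": self.ak_genotypes,
            "alpha_l": self.alpha_l.tolist(),
            "alpha_d": self.alpha_d.tolist(),
            "snp_target_fst": self.snp_target_fst.tolist(),
            "snp_is_fixed": self.snp_is_fixed.astype(int).tolist(),
            "snp_inside": self.snp_inside.astype(int).tolist(),
            "cline": asdict(self.cline),
            "bridge": asdict(self.bridge),
        }
        return json.dumps(payload, indent=1)


@dataclass
class SimBundle:
    genotypes: GenotypeMatrix
    samples: pd.DataFrame
    genmap: pd.DataFrame
    truth: SimTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _site_layout(cfg: SimConfig, rng: np.random.Generator):
    """Contigs on the map and SNP rows (contig, bp, cM, is_ak)."""
    cm = np.sort(rng.uniform(0.0, cfg.lg_length, cfg.n_contigs))
    names = [f"contig_{i:04d}" for i in range(cfg.n_contigs)]
    per = np.full(cfg.n_contigs, cfg.n_snps // cfg.n_contigs)
    per[: cfg.n_snps % cfg.n_contigs] += 1
    rows = []
    for name, c, n in zip(names, cm, per):
        bp = np.sort(rng.choice(np.arange(1, cfg.contig_length_bp + 1), size=n,
                                replace=False))
        for p in bp:
            rows.append((name, int(p), float(c), False))
    bp = np.sort(rng.choice(np.arange(1, cfg.contig_length_bp + 1),
                            size=cfg.n_ak_snps, replace=False))
    for p in bp:
        rows.append(("contig_ak", int(p), float(cfg.ak_cm), True))
    sites = pd.DataFrame(rows, columns=["contig", "pos", "cM", "is_ak"])
    sites = sites.sort_values(["contig", "pos"], ignore_index=True)
    genmap = pd.DataFrame({
        "contig": names + ["contig_ak"],
        "lg": cfg.lg_name,
        "cM": np.concatenate([cm, [cfg.ak_cm]]),
    }).sort_values("contig", ignore_index=True)
    return sites, genmap


def _draw_pools(cfg: SimConfig, sites: pd.DataFrame, bridge: BridgeParams,
                rng: np.random.Generator):
    """Per-SNP target theta and L/D pool frequencies (background SNPs)."""
    n = len(sites)
    cm = sites["cM"].to_numpy()
    inside = (cm >= cfg.inv_start) & (cm <= cfg.inv_start + cfg.inv_span)
    curve = np.where(inside, bridge_expectation(cm, bridge), cfg.m_t)
    conc = cfg.fst_scatter
    # stratified beta draws: one shuffled stratum of (0,1) per SNP, pushed
    # through each SNP's beta quantile function, keeps the realized mean of
    # the targets pinned at the curve mean (the configured region levels)
    # while preserving the per-SNP marginal distribution
    from scipy.stats import beta as beta_dist
    a = np.maximum(curve * conc, 1e-3)
    bpar = np.maximum((1.0 - curve) * conc, 1e-3)
    target = np.empty(n)
    for mask in (inside, ~inside):
        m = int(mask.sum())
        if m == 0:
            continue
        u = (np.arange(m) + rng.random(m)) / m
        u = u[rng.permutation(m)]
        target[mask] = beta_dist.ppf(u, a[mask], bpar[mask])
    target = np.clip(target, 1e-4, 0.95)
    fixed = inside & (rng.random(n) < cfg.fraction_fixed)
    target[fixed] = 1.0
    alpha_l = np.empty(n)
    alpha_d = np.empty(n)
    flip = rng.random(n) < 0.5
    for j in range(n):
        if fixed[j]:
            hi, lo = 1.0, 0.0
        else:
            # U-shaped mean-frequency spectrum: Beta(0.12, 0.12) rescaled to
            # [0.02, 0.98] puts background heterozygosity near 0.1, the level
            # typical of filtered WGS SNP sets; infeasible draws (pools
            # outside [0,1]) are resampled
            while True:
                pbar = 0.02 + 0.96 * rng.beta(0.12, 0.12)
                try:
                    hi, lo = pool_freqs_for_target_theta(target[j], pbar)
                    break
                except ValueError:
                    continue
        alpha_l[j], alpha_d[j] = (hi, lo) if flip[j] else (lo, hi)
    return target, fixed, inside, alpha_l, alpha_d


def _ak_class_freqs(cfg: SimConfig, n_ak: int) -> np.ndarray:
    """Alt-allele frequency per haplotype class (80, 100, 120) x Ak SNP.

    SNP 0 and 1 are the diagnostic pair (fixed for the 120 and the 80 class
    respectively); the rest cycle through the three one-vs-rest bipartitions
    with 0.977/0.023 frequencies, giving three divergent haplotype classes.
    The 0.023 within-class minor frequency is calibrated so homozygote-class
    observed heterozygosity sits near 0.045 (2q(1-q)), the level seen for
    allozyme-homozygote clusters at such a contig.
    """
    hi, lo = 0.977, 0.023
    F = np.full((3, n_ak), lo)
    if n_ak >= 1:
        F[:, 0] = [0.0, 0.0, 1.0]  # fixed in the 120 class
    if n_ak >= 2:
        F[:, 1] = [1.0, 0.0, 0.0]  # fixed in the 80 class
    for j in range(2, n_ak):
        F[j % 3, j] = hi
    return F


def simulate_dataset(config: SimConfig | None = None) -> SimBundle:
    """Generate the full bundle: genotypes + samples + map + truth.

    Same seed, same output — every draw flows from one root generator in a
    fixed order, so the written VCF is byte-identical across runs.
    """
    cfg = config if config is not None else SimConfig()
    rng = np.random.default_rng(cfg.seed)
    sites, genmap = _site_layout(cfg, rng)
    bridge = cfg.true_bridge()
    cline = cfg.true_cline()
    bg = ~sites["is_ak"].to_numpy()
    bg_sites = sites[bg].reset_index(drop=True)
    target, fixed, inside_bg, alpha_l, alpha_d = _draw_pools(
        cfg, bg_sites, bridge, rng)
    ak_freqs = _ak_class_freqs(cfg, cfg.n_ak_snps)

    sample_rows = []
    karyotypes: list[str] = []
    ak_genotypes: list[str] = []
    dos_blocks = []
    for name, n_ind in zip(cfg.transect_names, cfg.n_individuals):
        x = np.sort(rng.uniform(0.0, cfg.transect_length, n_ind))
        q = cline_frequency(x, cline)
        n_d = rng.binomial(2, q)  # D-arrangement copies, Hardy-Weinberg
        n_l = 2 - n_d
        # allozyme-like haplotype classes per individual: counts of 80/100/120
        n80 = rng.binomial(n_l, cfg.ak_allele_freqs[0])
        n100 = n_l - n80
        class_counts = np.stack([n80, n100, n_d], axis=1)
        # background dosages: sum of draws from each pool
        dos_bg = (rng.binomial(n_l[:, None], alpha_l[None, :])
                  + rng.binomial(n_d[:, None], alpha_d[None, :]))
        dos_ak = np.zeros((n_ind, cfg.n_ak_snps), dtype=np.int64)
        for c in range(3):
            dos_ak += rng.binomial(class_counts[:, c][:, None],
                                   ak_freqs[c][None, :])
        for i in range(n_ind):
            karyotypes.append(KARYOTYPES[n_d[i]])
            alleles = (["80"] * n80[i] + ["100"] * n100[i] + ["120"] * n_d[i])
            alleles.sort(key=lambda a: int(a))
            ak_genotypes.append("/".join(alleles))
        size_mu = np.array(cfg.size_means)[n_d]
        size = rng.normal(size_mu, cfg.size_sd)
        sex = np.where(rng.random(n_ind) < 0.5, "F", "M")
        for i in range(n_ind):
            sample_rows.append((f"{name}_{i:03d}", name, float(x[i]),
                                float(size[i]), sex[i]))
        # assemble in site order: background + ak interleaved per site table
        dos_full = np.empty((n_ind, len(sites)), dtype=np.int64)
        dos_full[:, np.flatnonzero(bg)] = dos_bg
        dos_full[:, np.flatnonzero(~bg)] = dos_ak
        dos_blocks.append(dos_full)

    dosages = np.concatenate(dos_blocks, axis=0).T  # site-major
    depths = rng.poisson(cfg.mean_depth, dosages.shape).astype(np.int32)
    dosages = np.where(depths == 0, MISSING, dosages).astype(np.int8)

    samples = pd.DataFrame(sample_rows,
                           columns=["id", "transect", "path_pos_m",
                                    "size_mm", "sex"])
    refalt = pd.DataFrame({"ref": "A", "alt": "T"}, index=sites.index)
    site_table = pd.concat(
        [sites[["contig", "pos"]], refalt], axis=1)
    site_table["mean_depth"] = depths.mean(axis=1)
    site_table["lg"] = cfg.lg_name
    site_table["cM"] = sites["cM"].to_numpy()
    site_table["is_ak"] = sites["is_ak"].to_numpy()
    g = GenotypeMatrix(dosages, site_table, samples["id"].tolist(), depths)

    # per-SNP truth arrays in site-table order
    n_total = len(sites)
    t_full = np.full(n_total, np.nan)
    fx_full = np.zeros(n_total, dtype=bool)
    in_full = np.zeros(n_total, dtype=bool)
    al_full = np.full(n_total, np.nan)
    ad_full = np.full(n_total, np.nan)
    bg_idx = np.flatnonzero(bg)
    t_full[bg_idx] = target
    fx_full[bg_idx] = fixed
    in_full[bg_idx] = inside_bg
    in_full[np.flatnonzero(~bg)] = True
    al_full[bg_idx] = alpha_l
    ad_full[bg_idx] = alpha_d

    truth = SimTruth(
        karyotypes=karyotypes, ak_genotypes=ak_genotypes,
        alpha_l=al_full, alpha_d=ad_full, snp_target_fst=t_full,
        snp_is_fixed=fx_full, snp_inside=in_full, cline=cline, bridge=bridge,
        seed=cfg.seed)
    return SimBundle(g, samples, genmap, truth, cfg)


def simulate_contig_fst_observations(params: BridgeParams, contig_positions,
                                     seed: int = 0) -> np.ndarray:
    """Contig-level logit-F_ST observations from a bridge landscape:
    logit(F(p_j)) plus Normal(0, s) residual noise."""
    pos = np.asarray(contig_positions, dtype=float)
    mu = bridge_expectation(pos, params)
    if np.any(mu <= 0.0) or np.any(mu >= 1.0):
        raise ValueError("model expectation outside (0, 1) at some position")
    rng = np.random.default_rng(seed)
    return np.log(mu / (1.0 - mu)) + params.s * rng.standard_normal(len(pos))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Write VCF + sample TSV + map TSV + truth JSON to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "samples": out / "samples.tsv",
        "map": out / "genetic_map.tsv",
        "truth": out / "truth.json",
    }
    write_vcf(bundle.genotypes, paths["vcf"])
    bundle.samples.to_csv(paths["samples"], sep="\t", index=False)
    bundle.genmap.to_csv(paths["map"], sep="\t", index=False)
    paths["truth"].write_text(bundle.truth.to_json())
    return paths
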