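"""Synthetic twin and genotype cohorts with a known genetic architecture.

This module generates the two kinds of data the analysis needs and that the
original cohort cannot supply:

* MZ/DZ twin-pair phenotypes drawn from a bivariate ACE truth
  (:class:`GeneratorTruth`), so the variance-component model can be tested
  against known parameters; and
* a discovery + target genotype cohort with LD-block structure and a
  pleiotropic causal architecture (:class:`PleiotropyDesign`), from which
  marginal GWAS summary statistics are computed, so the polygenic-score
  pipeline can be tested against known shared signal.

Every generator takes an explicit integer seed and is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneratorTruth",
    "GenotypePanel",
    "PleiotropyDesign",
    "CalibrationError",
    "calibrate_generator",
    "simulate_twin_dataset",
    "simulate_genotype_panel",
    "simulate_pleiotropic_traits",
    "simulate_gwas_summary",
    "simulate_refraction_records",
]

TWIN_COLUMNS = [
    "pair_id",
    "zygosity",
    "trait1_t1",
    "trait2_t1",
    "trait1_t2",
    "trait2_t2",
]


class CalibrationError(ValueError):
    """The requested phenotypic correlation is unreachable for the given
    variance components (would require a factor correlation outside [-1, 1])."""


@dataclasses.dataclass(frozen=True)
class GeneratorTruth:
    """Standardized bivariate ACE truth.

    ``A1, C1, E1`` and ``A2, C2, E2`` are the additive-genetic, shared- and
    unique-environment variance proportions of traits 1 and 2 (each triple
    sums to 1); ``r_a, r_c, r_e`` are the cross-trait correlations of the
    corresponding latent factors.
    """

    A1: float
    C1: float
    E1: float
    A2: float
    C2: float
    E2: float
    r_a: float
    r_c: float
    r_e: float

    def __post_init__(self) -> None:
        for name in ("A1", "C1", "E1", "A2", "C2", "E2"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"variance proportion {name} must be >= 0")
        for tot, lab in ((self.A1 + self.C1 + self.E1, "trait 1"),
                         (self.A2 + self.C2 + self.E2, "trait 2")):
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"{lab} proportions sum to {tot}, not 1")
        for name in ("r_a", "r_c", "r_e"):
            if abs(getattr(self, name)) > 1 + 1e-12:
                raise ValueError(f"{name} outside [-1, 1]")

    def _block(self, v1: float, v2: float, r: float) -> np.ndarray:
        return np.array([[v1, r * math.sqrt(v1 * v2)],
                         [r * math.sqrt(v1 * v2), v2]])

    @property
    def sigma_a(self) -> np.ndarray:
        """2x2 additive-genetic covariance block."""
        return self._block(self.A1, self.A2, self.r_a)

    @property
    def sigma_c(self) -> np.ndarray:
        return self._block(self.C1, self.C2, self.r_c)

    @property
    def sigma_e(self) -> np.ndarray:
        return self._block(self.E1, self.E2, self.r_e)

    @property
    def implied_rp(self) -> float:
        """Model-implied within-person cross-trait (phenotypic) correlation:
        sqrt(A1 A2) rA + sqrt(C1 C2) rC + sqrt(E1 E2) rE."""
        return (math.sqrt(self.A1 * self.A2) * self.r_a
                + math.sqrt(self.C1 * self.C2) * self.r_c
                + math.sqrt(self.E1 * self.E2) * self.r_e)


def calibrate_generator(
    A1: float, C1: float, E1: float,
    A2: float, C2: float, E2: float,
    r_a: float,
    target_rp: float,
) -> GeneratorTruth:
    """Build a :class:`GeneratorTruth` whose implied phenotypic correlation
    equals ``target_rp`` exactly.

    The reported twin-model fit gives per-trait proportions and the genetic
    correlation rA, but not the environmental factor correlations.  By
    convention rC is fixed at 0 (the shared-environment component of trait 1
    is nearly nil, so its cross term is numerically negligible) and rE is
    solved from the one-unknown linear identity

        rP = sqrt(A1 A2) rA + sqrt(C1 C2) rC + sqrt(E1 E2) rE.

    Proportions are renormalized to sum to exactly 1 per trait (the published
    point estimates are rounded and need not).

    Raises
    ------
    CalibrationError
        if the solved |rE| exceeds 1, i.e. the target correlation is not
        reachable with the given components.
    """
    s1 = A1 + C1 + E1
    s2 = A2 + C2 + E2
    if s1 <= 0 or s2 <= 0:
        raise ValueError("variance proportions must have a positive sum")
    A1, C1, E1 = A1 / s1, C1 / s1, E1 / s1
    A2, C2, E2 = A2 / s2, C2 / s2, E2 / s2

    genetic_share = math.sqrt(A1 * A2) * r_a
    resid = target_rp - genetic_share
    ee = math.sqrt(E1 * E2)
    if ee < 1e-12:
        if abs(resid) > 1e-9:
            raise CalibrationError(
                "no unique-environment variance to absorb the residual "
                f"correlation {resid:.4g}")
        r_e = 0.0
    else:
        r_e = resid / ee
    if abs(r_e) > 1:
        raise CalibrationError(
            f"target rP={target_rp} requires rE={r_e:.3f} outside [-1, 1]")
    return GeneratorTruth(A1, C1, E1, A2, C2, E2, r_a=r_a, r_c=0.0, r_e=r_e)


def _psd_factor(m: np.ndarray) -> np.ndarray:
    """Factor F with F F' = m for a (possibly singular) PSD matrix."""
    w, v = np.linalg.eigh(np.asarray(m, dtype=float))
    if w.min() < -1e-10:
        raise ValueError("covariance block is not positive semi-definite")
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_twin_dataset(
    truth: GeneratorTruth, n_mz: int, n_dz: int, seed: int
) -> pd.DataFrame:
    """Draw twin pairs under the bivariate ACE truth.

    MZ co-twins share identical additive-genetic (A) and shared-environment
    (C) bivariate deviates.  DZ co-twins share C fully, and their A deviates
    are built as a common part plus a twin-specific part, each with half the
    A covariance, so the cross-twin genetic covariance is 0.5*Sigma_A with
    exact second moments.  Unique-environment deviates (E) are independent
    per twin.  Each trait is the sum of its three deviates, so per-trait
    variance is 1 and within-person cross-trait correlation is
    ``truth.implied_rp``.

    Returns a DataFrame with columns ``pair_id, zygosity, trait1_t1,
    trait2_t1, trait1_t2, trait2_t2`` (one row per pair).
    """
    if n_mz < 0 or n_dz < 0:
        raise ValueError("pair counts must be non-negative")
    rng = np.random.default_rng(seed)
    fa = _psd_factor(truth.sigma_a)
    fc = _psd_factor(truth.sigma_c)
    fe = _psd_factor(truth.sigma_e)
    fa_half = fa / math.sqrt(2.0)  # (fa/sqrt2)(fa/sqrt2)' = 0.5 Sigma_A

    def draw(factor: np.ndarray, n: int) -> np.ndarray:
        return rng.standard_normal((n, 2)) @ factor.T

    rows = []
    a = draw(fa, n_mz)
    c = draw(fc, n_mz)
    t1 = a + c + draw(fe, n_mz)
    t2 = a + c + draw(fe, n_mz)
    rows.append(("MZ", t1, t2))

    a_common = draw(fa_half, n_dz)
    c = draw(fc, n_dz)
    t1 = a_common + draw(fa_half, n_dz) + c + draw(fe, n_dz)
    t2 = a_common + draw(fa_half, n_dz) + c + draw(fe, n_dz)
    rows.append(("DZ", t1, t2))

    frames = []
    offset = 0
    for zyg, tw1, tw2 in rows:
        n = tw1.shape[0]
        frames.append(pd.DataFrame({
            "pair_id": [f"{zyg.lower()}{i + 1:05d}" for i in range(n)],
            "zygosity": zyg,
            "trait1_t1": tw1[:, 0],
            "trait2_t1": tw1[:, 1],
            "trait1_t2": tw2[:, 0],
            "trait2_t2": tw2[:, 1],
        }))
        offset += n
    return pd.concat(frames, ignore_index=True)


@dataclasses.dataclass
class GenotypePanel:
    """Individuals x SNPs dosage matrix plus per-SNP metadata.

    ``dosages`` holds allele counts in [0, 2] (individuals in rows);
    ``snps`` is a DataFrame with columns ``id, chrom, pos, a1, a2, maf``
    where ``a1`` is the counted (effect) allele and ``pos`` is 1-based.
    """

    dosages: np.ndarray
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if self.dosages.shape[1] != len(self.snps):
            raise ValueError("dosage columns must match SNP metadata rows")
        if self.dosages.size and (
                self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        for _, grp in self.snps.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("positions must be strictly increasing per chromosome")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def subset_individuals(self, idx: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(self.dosages[idx], self.snps.copy())


_BLOCK_GAP_BP = 1_000_000
_SNP_SPACING_BP = 2_000


def simulate_genotype_panel(
    n: int,
    m: int,
    block_size: int,
    within_block_r: float,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> GenotypePanel:
    """Simulate a diploid dosage panel with LD organised in blocks.

    Each haplotype is a latent Gaussian AR(1) series per block (lag-one
    correlation ``within_block_r``, independent across blocks and across
    haplotypes) thresholded at each SNP's allele-frequency quantile; the
    dosage is the sum of the two haplotypes.  Blocks are separated by a 1 Mb
    gap so SNPs in different blocks are both statistically independent and
    outside any clumping window; SNPs within a block are 2 kb apart.
    """
    if m % block_size:
        raise ValueError("m must be divisible by block_size")
    if not 0 <= within_block_r < 1:
        raise ValueError("within_block_r must be in [0, 1)")
    lo, hi = maf_range
    if lo >= 0.5 or lo <= 0 or hi > 0.5 or lo > hi:
        raise ValueError("maf_range must be inside (0, 0.5]")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=m)
    thresh = stats.norm.ppf(maf)

    n_blocks = m // block_size
    dosage = np.zeros((n, m), dtype=float)
    for hap in range(2):
        z = rng.standard_normal((n, n_blocks, block_size))
        for j in range(1, block_size):
            z[:, :, j] = (within_block_r * z[:, :, j - 1]
                          + math.sqrt(1 - within_block_r ** 2) * z[:, :, j])
        dosage += (z.reshape(n, m) < thresh)

    pos = np.empty(m, dtype=int)
    for b in range(n_blocks):
        start = 1 + b * _BLOCK_GAP_BP
        pos[b * block_size:(b + 1) * block_size] = (
            start + _SNP_SPACING_BP * np.arange(block_size))
    alleles = np.array(["A", "C", "G", "T"])
    snps = pd.DataFrame({
        "id": [f"snp{j + 1:06d}" for j in range(m)],
        "chrom": "1",
        "pos": pos,
        "a1": rng.choice(alleles, size=m),
        "maf": maf,
    })
    # other allele drawn from a non-complementary base so simulated panels
    # are free of strand-ambiguous (palindromic) SNPs by construction
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    other = []
    for a in snps["a1"]:
        choices = [b for b in alleles if b != a and b != comp[a]]
        other.append(choices[rng.integers(len(choices))])
    snps["a2"] = other
    snps = snps[["id", "chrom", "pos", "a1", "a2", "maf"]]
    return GenotypePanel(dosage, snps)


@dataclasses.dataclass(frozen=True)
class PleiotropyDesign:
    """Causal architecture for a pair of polygenic traits.

    ``prop_shared`` of the causal SNPs (fraction of the smaller causal set)
    influence both traits, with per-SNP effect sizes correlated at
    ``shared_effect_corr`` across traits; ``h2_1, h2_2`` are the SNP
    heritabilities of the two traits.
    """

    n_causal_1: int
    n_causal_2: int
    prop_shared: float
    h2_1: float
    h2_2: float
    effect_sd: float = 1.0
    shared_effect_corr: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.prop_shared <= 1:
            raise ValueError("prop_shared must be in [0, 1]")
        if not (0 <= self.h2_1 <= 1 and 0 <= self.h2_2 <= 1):
            raise ValueError("heritabilities must be in [0, 1]")
        if min(self.n_causal_1, self.n_causal_2) < 0:
            raise ValueError("causal counts must be non-negative")


def simulate_pleiotropic_traits(
    panel: GenotypePanel, design: PleiotropyDesign
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Simulate two phenotypes over ``panel`` with partially shared causal SNPs.

    Each trait is a genetic value (centered dosages times true per-allele
    effects, rescaled so its variance is the target SNP heritability) plus
    independent Gaussian noise of variance 1 - h2.  Returns the two phenotype
    vectors and a table of true effects (columns ``id, beta1, beta2,
    shared``) for oracle checks.
    """
    if max(design.n_causal_1, design.n_causal_2) > panel.m:
        raise ValueError("causal counts exceed panel SNPs")
    rng = np.random.default_rng(design.seed)
    m = panel.m
    n_shared = round(design.prop_shared * min(design.n_causal_1, design.n_causal_2))

    # trait-exclusive causal SNPs are placed in disjoint loci (runs of SNPs
    # separated by <500 kb) so that with prop_shared = 0 the two genetic
    # values are genuinely independent, not correlated through linkage
    order = np.lexsort((panel.snps["pos"].to_numpy(),
                        panel.snps["chrom"].to_numpy()))
    locus = np.empty(m, dtype=int)
    lid = -1
    prev_chrom, prev_pos = None, None
    for j in order:
        chrom, pos = panel.snps["chrom"].iat[j], panel.snps["pos"].iat[j]
        if chrom != prev_chrom or pos - prev_pos >= 500_000:
            lid += 1
        locus[j] = lid
        prev_chrom, prev_pos = chrom, pos

    shared = rng.choice(m, size=n_shared, replace=False)
    loci = rng.permutation(lid + 1)
    pool1 = np.flatnonzero(np.isin(locus, loci[0::2]) & ~np.isin(np.arange(m), shared))
    pool2 = np.flatnonzero(np.isin(locus, loci[1::2]) & ~np.isin(np.arange(m), shared))
    need1 = design.n_causal_1 - n_shared
    need2 = design.n_causal_2 - n_shared
    if need1 > len(pool1) or need2 > len(pool2):
        raise ValueError("panel has too few unlinked loci for the requested "
                         "trait-exclusive causal counts")
    only1 = rng.choice(pool1, size=need1, replace=False)
    only2 = rng.choice(pool2, size=need2, replace=False)

    beta1 = np.zeros(m)
    beta2 = np.zeros(m)
    rho = design.shared_effect_corr
    z = rng.standard_normal((n_shared, 2))
    beta1[shared] = design.effect_sd * z[:, 0]
    beta2[shared] = design.effect_sd * (
        rho * z[:, 0] + math.sqrt(max(0.0, 1 - rho ** 2)) * z[:, 1])
    beta1[only1] = design.effect_sd * rng.standard_normal(len(only1))
    beta2[only2] = design.effect_sd * rng.standard_normal(len(only2))

    x = panel.dosages - panel.dosages.mean(axis=0)

    def assemble(beta: np.ndarray, h2: float) -> tuple[np.ndarray, np.ndarray]:
        g = x @ beta
        vg = g.var()
        if h2 == 0 or vg < 1e-30:
            scale = 0.0
        else:
            scale = math.sqrt(h2 / vg)
        g = g * scale
        noise = rng.standard_normal(panel.n) * math.sqrt(max(0.0, 1 - h2))
        return g + noise, beta * scale

    y1, b1s = assemble(beta1, design.h2_1)
    y2, b2s = assemble(beta2, design.h2_2)
    truth = pd.DataFrame({
        "id": panel.snps["id"].to_numpy(),
        "beta1": b1s,
        "beta2": b2s,
        "shared": np.isin(np.arange(m), shared),
    })
    return y1, y2, truth


def simulate_gwas_summary(panel: GenotypePanel, phenotype: np.ndarray) -> pd.DataFrame:
    """Marginal single-SNP GWAS of ``phenotype`` against each panel SNP.

    Runs the simple linear regression y ~ dosage per SNP (vectorised) and
    returns a PLINK-association-style table with columns
    ``SNP, CHR, BP, A1, A2, BETA, SE, P`` plus ``MAF`` and a
    ``zero_variance`` flag; monomorphic SNPs get NaN estimates and must be
    excluded downstream.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.shape != (panel.n,):
        raise ValueError("phenotype length must equal panel individuals")
    n = panel.n
    x = panel.dosages
    xm = x.mean(axis=0)
    xc = x - xm
    yc = y - y.mean()
    sxx = (xc ** 2).sum(axis=0)
    sxy = xc.T @ yc
    zero = sxx < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(zero, np.nan, sxy / sxx)
        syy = (yc ** 2).sum()
        rss = syy - np.where(zero, 0.0, beta ** 2 * sxx)
        rss = np.clip(rss, 0.0, None)
        dof = n - 2
        se = np.sqrt(rss / dof / sxx)
        tstat = beta / se
    p = 2 * stats.t.sf(np.abs(tstat), dof)
    # exact linear relation: rss == 0 gives se 0 and t inf -> p exactly 0
    p = np.where(zero, np.nan, p)
    out = panel.snps.rename(columns={
        "id": "SNP", "chrom": "CHR", "pos": "BP", "a1": "A1", "a2": "A2",
        "maf": "MAF"})
    out = out.assign(BETA=beta, SE=se, P=p, zero_variance=zero)
    return out[["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "MAF",
                "zero_variance"]]


def simulate_refraction_records(
    n: int,
    seed: int,
    iq_effect: float = -0.35,
    myopia_prevalence_shift: float = 0.0,
) -> pd.DataFrame:
    """Synthetic refraction + cognition records for exercising phenotype prep.

    Emits one row per individual with per-eye sphere/cylinder (minus-cylinder
    convention), age at refraction (14-18 years), sex, an IQ-like cognitive
    score, and a pair id (two individuals per pair).  Spherical equivalent
    depends linearly on age, sex and the cognitive score (slope ``iq_effect``
    dioptres per SD) plus noise, giving a realistic myopia fraction of
    roughly a quarter.  This is plumbing for the association models, not a
    cohort emulation.
    """
    rng = np.random.default_rng(seed)
    age = rng.uniform(14, 18, size=n)
    sex = rng.choice(["M", "F"], size=n)
    iq = rng.standard_normal(n)
    mean_se = (0.9 - 0.12 * (age - 16) - 0.1 * (sex == "M")
               + iq_effect * iq + rng.normal(0, 1.4, size=n)
               + myopia_prevalence_shift)
    astig = -np.abs(rng.normal(0, 0.4, size=n))
    eye_diff = rng.normal(0, 0.15, size=n)
    se_r = mean_se + eye_diff
    se_l = mean_se - eye_diff
    return pd.DataFrame({
        "pair_id": [f"fam{i // 2 + 1:05d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "iq": iq,
        "sphere_right": se_r - astig / 2,
        "cylinder_right": astig,
        "sphere_left": se_l - astig / 2,
        "cylinder_left": astig,
    })
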