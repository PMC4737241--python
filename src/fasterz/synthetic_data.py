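"""Synthetic inputs with the statistical structure the pipeline assumes.

Generators emit per-contig divergence and polymorphism count tables,
RPKM expression matrices with known sex-bias ground truth, and
phylogenetically correlated trait data, all seed-deterministic.  Default
dimensions mirror a six-species transcriptome study design: 160
Z-linked, 1690 autosome-1-10 and 741 microchromosomal orthogroups, with
20 autosomal and 15 Z-linked sampled allele copies per species (5 males
+ 5 females; females carry one Z).

Counts follow the models the estimators assume: substitution counts are
Poisson in sites x branch divergence x omega, polymorphic-site counts
Poisson in sites x theta x H(n-1) (the Watterson expectation), with the
Z category's omega multiplied by a true Faster-Z effect and its
diversity scaled by a true N_EZ/N_EA ratio and the Z/autosome mutation
rate quotient.

The SNP detection-power simulation — drawing allele copies without
replacement from a finite diploid population and scoring samples in
which the polymorphism is invisible — is included here together with
its closed-form hypergeometric oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from fasterz.popsize_ne import (
    N_ALLELES_AUTO,
    N_ALLELES_Z,
    U_A_DEFAULT,
    U_Z_DEFAULT,
    harmonic_number,
)
from fasterz.tables_io import DivergenceRecord, PolymorphismRecord

# microchromosome labels cycle over autosomes 11..38
_MICRO_CHROMS = [str(c) for c in range(11, 39)]
_MACRO_CHROMS = [str(c) for c in range(1, 11)]


@dataclass
class SimConfig:
    """Ground-truth parameters for all generators.

    Defaults reproduce the study's table dimensions and realistic avian
    transcriptome rates: autosomal dN/dS ~ 0.12, per-contig synonymous
    branch divergence ~ 0.15, synonymous scaled diversity ~ 0.005 per
    site, and a modest true Faster-Z effect of 1.2.
    """

    seed: int = 0
    n_contigs_z: int = 160
    n_contigs_auto: int = 1690
    n_contigs_micro: int = 741
    omega_auto: float = 0.12
    faster_z_true: float = 1.2
    ds_branch: float = 0.15
    mean_sites: float = 900.0       # median total (N + S) sites per contig
    sites_sigma: float = 0.6        # log-scale spread of contig length
    n_to_s: float = 3.0             # nonsynonymous : synonymous site ratio
    theta_auto: float = 0.005
    ne_ratio_true: float = 0.75
    selection_factor: float = 0.3   # pN/pS under purifying selection
    u_z: float = U_Z_DEFAULT
    u_a: float = U_A_DEFAULT
    n_alleles_auto: int = N_ALLELES_AUTO
    n_alleles_z: int = N_ALLELES_Z
    fourfold_fraction: float = 0.6  # share of synonymous sites that are 4D
    # expression
    n_genes: int = 500
    n_per_sex: int = 5
    sex_bias_fraction: float = 0.2
    sex_limited_fraction: float = 0.02
    bias_log2fc: float = 2.0
    expr_mean_log2: float = 3.0
    expr_gene_sigma: float = 1.5
    expr_sample_sigma: float = 0.35
    # traits
    trait_slope: float = 0.3
    trait_sigma2: float = 0.05

    def __post_init__(self) -> None:
        if min(self.n_contigs_z, self.n_contigs_auto, self.n_contigs_micro) < 0:
            raise ValueError("contig counts must be >= 0")
        for name in ("omega_auto", "faster_z_true", "ds_branch", "theta_auto",
                     "ne_ratio_true", "selection_factor", "mean_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.sex_bias_fraction <= 1) or not (0 <= self.sex_limited_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


def _contig_layout(config: SimConfig) -> tuple[list[str], list[str]]:
    """Chromosome labels and contig ids in a fixed, reproducible order."""
    chroms: list[str] = []
    chroms += ["Z"] * config.n_contigs_z
    chroms += [_MACRO_CHROMS[i % len(_MACRO_CHROMS)] for i in range(config.n_contigs_auto)]
    chroms += [_MICRO_CHROMS[i % len(_MICRO_CHROMS)] for i in range(config.n_contigs_micro)]
    ids = [f"contig{i:05d}" for i in range(len(chroms))]
    return chroms, ids


def _sites(config: SimConfig, rng: np.random.Generator, n: int
           ) -> tuple[np.ndarray, np.ndarray]:
    total = rng.lognormal(math.log(config.mean_sites), config.sites_sigma, n)
    total = np.maximum(total, 30.0)
    frac_n = config.n_to_s / (1.0 + config.n_to_s)
    return total * frac_n, total * (1.0 - frac_n)


def gen_divergence_counts(config: SimConfig) -> list[DivergenceRecord]:
    """Per-contig substitution counts under Poisson divergence.

    D_S ~ Poisson(S x ds_branch) and D_N ~ Poisson(N x ds_branch x
    omega_cat) with omega multiplied by the true Faster-Z effect on the Z;
    tree_dS is the realized per-contig synonymous divergence D_S/S.
    """
    rng = config.rng(stream=10)
    chroms, ids = _contig_layout(config)
    n = len(chroms)
    N, S = _sites(config, rng, n)
    is_z = np.array([c == "Z" for c in chroms])
    omega = np.where(is_z, config.omega_auto * config.faster_z_true, config.omega_auto)
    D_S = rng.poisson(S * config.ds_branch).astype(float)
    D_N = rng.poisson(N * config.ds_branch * omega).astype(float)
    tree_ds = D_S / S
    return [
        DivergenceRecord(contig_id=i, chrom=c, D_N=dn, D_S=ds, N=nn, S=ss, tree_dS=td)
        for i, c, dn, ds, nn, ss, td in zip(ids, chroms, D_N, D_S, N, S, tree_ds)
    ]


def gen_polymorphism_counts(config: SimConfig) -> list[PolymorphismRecord]:
    """Per-contig polymorphic-site counts under the Watterson expectation.

    The expected polymorphic fraction of a site class is theta x H(n-1)
    for its category's sampled allele-copy count; the Z's theta is
    theta_auto x ne_ratio_true x (U_Z/U_A).  P_N applies a purifying
    selection factor; fourfold-degenerate counts are a binomial subset of
    the synonymous sites so that P_4D <= L_4D always.
    """
    rng = config.rng(stream=20)
    chroms, ids = _contig_layout(config)
    n = len(chroms)
    N, S = _sites(config, rng, n)
    is_z = np.array([c == "Z" for c in chroms])
    theta = np.where(
        is_z,
        config.theta_auto * config.ne_ratio_true * (config.u_z / config.u_a),
        config.theta_auto,
    )
    hn = np.where(is_z, harmonic_number(config.n_alleles_z - 1),
                  harmonic_number(config.n_alleles_auto - 1))
    poly_frac = theta * hn
    P_S = rng.poisson(S * poly_frac)
    P_N = rng.poisson(N * poly_frac * config.selection_factor)
    L_4D = np.maximum(np.round(S * config.fourfold_fraction).astype(int), 1)
    P_4D = rng.binomial(L_4D, np.minimum(poly_frac, 1.0))
    return [
        PolymorphismRecord(contig_id=i, chrom=c, P_N=int(pn), P_S=int(ps),
                           N=nn, S=ss, P_4D=int(p4), L_4D=int(l4))
        for i, c, pn, ps, nn, ss, p4, l4 in zip(ids, chroms, P_N, P_S, N, S, P_4D, L_4D)
    ]


def gen_expression(config: SimConfig, species: str = "sp1", tissue: str = "gonad"):
    """RPKM expression records plus the ground-truth class of every gene.

    Per-gene baseline log2 expression is normal across genes; biased
    genes shift one sex's mean by ``bias_log2fc`` (split symmetrically);
    sex-limited genes zero out the other sex entirely.  Returns
    ``(records, truth)`` with truth values in {male_biased, female_biased,
    male_limited, female_limited, unbiased}.
    """
    from fasterz.expression_bias import (
        FEMALE_BIASED, FEMALE_LIMITED, MALE_BIASED, MALE_LIMITED, UNBIASED,
        ExpressionRecord,
    )

    rng = config.rng(stream=30)
    n_genes, k = config.n_genes, config.n_per_sex
    sexes = ("M",) * k + ("F",) * k
    n_biased = int(round(config.sex_bias_fraction * n_genes))
    n_limited = int(round(config.sex_limited_fraction * n_genes))
    labels = ([MALE_BIASED] * (n_biased // 2)
              + [FEMALE_BIASED] * (n_biased - n_biased // 2)
              + [MALE_LIMITED] * (n_limited // 2)
              + [FEMALE_LIMITED] * (n_limited - n_limited // 2))
    labels += [UNBIASED] * (n_genes - len(labels))
    rng.shuffle(labels)

    records, truth = [], {}
    base = rng.normal(config.expr_mean_log2, config.expr_gene_sigma, n_genes)
    for g in range(n_genes):
        gene = f"gene{g:05d}"
        klass = labels[g]
        shift_m = shift_f = 0.0
        if klass == MALE_BIASED:
            shift_m, shift_f = config.bias_log2fc / 2, -config.bias_log2fc / 2
        elif klass == FEMALE_BIASED:
            shift_m, shift_f = -config.bias_log2fc / 2, config.bias_log2fc / 2
        male = 2.0 ** (base[g] + shift_m + rng.normal(0, config.expr_sample_sigma, k))
        female = 2.0 ** (base[g] + shift_f + rng.normal(0, config.expr_sample_sigma, k))
        if klass == MALE_LIMITED:
            female = np.zeros(k)
        elif klass == FEMALE_LIMITED:
            male = np.zeros(k)
        values = tuple(np.concatenate([male, female]))
        records.append(ExpressionRecord(gene, species, tissue, values, sexes))
        truth[gene] = klass
    return records, truth


def gen_traits(tree, b: float, sigma2: float, seed: int = 0,
               intercept: float = 1.0, x_sigma2: float = 1.0):
    """Species trait rows simulated by Brownian motion on the tree.

    The predictor x evolves as Brownian motion with variance ``x_sigma2``
    per unit branch length; the response is intercept + b x plus Brownian
    noise of variance ``sigma2``.  Returns TraitRow objects with the
    response stored as ``faster_z`` and predictor as ``log_sperm_number``.
    """
    from fasterz.comparative_pgls import TraitRow, brownian_cov

    tips = sorted(t.label for t in tree.taxon_namespace)
    C = brownian_cov(tree, tips)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 40)))
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(tips)))
    x = L @ rng.standard_normal(len(tips)) * math.sqrt(x_sigma2)
    noise = L @ rng.standard_normal(len(tips)) * math.sqrt(sigma2) if sigma2 > 0 else 0.0
    y = intercept + b * x + noise
    return [
        TraitRow(species=s, faster_z=float(yi), log_sperm_number=float(xi))
        for s, yi, xi in zip(tips, y, x)
    ]


def simulate_fn_rate(
    n_sampled: int,
    maf: float,
    pop_alleles: int = 100,
    reps: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo false-negative rate of SNP detection at a given MAF.

    A population of ``pop_alleles`` allele copies holds
    round(maf x pop_alleles) minor-allele copies.  Each replicate draws
    ``n_sampled`` copies without replacement; a false negative is a draw
    containing a single distinct allele (the site looks monomorphic).
    Returns the fraction of false-negative replicates.
    """
    if not (0 < maf <= 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    if n_sampled > pop_alleles:
        raise ValueError("cannot sample more copies than the population holds")
    if n_sampled < 1 or reps < 1:
        raise ValueError("n_sampled and reps must be >= 1")
    K = int(round(maf * pop_alleles))
    rng = np.random.default_rng(np.random.SeedSequence((seed, 50)))
    minor_drawn = rng.hypergeometric(K, pop_alleles - K, n_sampled, reps)
    false_neg = (minor_drawn == 0) | (minor_drawn == n_sampled)
    return float(false_neg.mean())


def hypergeom_fn_rate(n_sampled: int, minor_copies: int, pop_alleles: int) -> float:
    """Closed-form false-negative probability for sampling without
    replacement: [C(M-K, n) + C(K, n)] / C(M, n), the chance the sample is
    all-major or all-minor (C(a, b) = 0 when b > a)."""
    if not (0 <= minor_copies <= pop_alleles):
        raise ValueError("minor_copies must lie in [0, pop_alleles]")
    if not (0 < n_sampled <= pop_alleles):
        raise ValueError("n_sampled must lie in [1, pop_alleles]")
    M, K, n = pop_alleles, minor_copies, n_sampled
    denom = math.comb(M, n)
    all_major = math.comb(M - K, n) if M - K >= n else 0
    all_minor = math.comb(K, n) if K >= n else 0
    return (all_major + all_minor) / denom
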