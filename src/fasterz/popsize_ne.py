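"""Nucleotide diversity, Watterson's theta and effective population size.

In a male-heterogametic (ZW) system there are three Z chromosomes for
every four autosome copies, so under equal sex-specific reproductive
variance N_EZ/N_EA = 3/4.  Stronger variance in male reproductive
success (e.g. under intense sperm competition) pushes the ratio below
3/4 toward 1/2, because the Z spends two-thirds of its time in males.
The ratio is estimated from neutral diversity after correcting for
male-biased mutation: N_E = diversity / (4 U g) with a Z-specific and an
autosomal mutation rate U (per site per year) and generation time g.

Diversity here is the proportion of fourfold-degenerate (or all
synonymous) sites that are polymorphic — a segregating-site density —
and Watterson's theta divides the same quantity by the harmonic number
H(n-1) of the sampled allele-copy count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from fasterz.divergence_rates import RatioResult
from fasterz.resampling import ResamplingPlan, bootstrap_ci_two_group
from fasterz.tables_io import Category

# Galliform mutation rates per site per year, from published Z-linked and
# autosomal divergence estimates; the Z rate is higher because the Z
# spends more time in the mutagenic male germline.
U_Z_DEFAULT = 1.45e-9
U_A_DEFAULT = 1.33e-9

# sampled allele copies with 5 males + 5 females per species:
# 20 autosomal copies, 15 Z copies (females carry a single Z)
N_ALLELES_AUTO = 20
N_ALLELES_Z = 15


@dataclass
class NEEstimate:
    category: Category
    diversity_pi: float
    diversity_theta: float
    n_alleles: int
    U: float
    gen_time: float
    NE_pi: float
    NE_theta: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")


def harmonic_number(k: int) -> float:
    """H(k) = sum_{i=1..k} 1/i."""
    return float(np.sum(1.0 / np.arange(1, k + 1))) if k >= 1 else 0.0


def pi_per_site(records: Sequence, site_class: str = "fourfold") -> float:
    """Per-site diversity: Σ polymorphic sites / Σ sites for a site class.

    ``fourfold`` uses P_4D/L_4D; ``synonymous`` uses P_S/S.  Concatenated
    across contigs like every other rate in the pipeline.
    """
    if site_class == "fourfold":
        poly = sum(r.P_4D for r in records)
        sites = sum(r.L_4D for r in records)
    elif site_class == "synonymous":
        poly = sum(r.P_S for r in records)
        sites = sum(r.S for r in records)
    else:
        raise ValueError(f"unknown site class {site_class!r}")
    if sites <= 0:
        raise ValueError(f"pi_per_site({site_class}): zero site total")
    return poly / sites


def watterson_theta(segregating: float, n_alleles: int, sites: float) -> float:
    """Watterson's estimator per site: S / (H(n-1) * sites)."""
    if n_alleles < 2:
        raise ValueError("watterson_theta requires n_alleles >= 2")
    if sites <= 0:
        raise ValueError("watterson_theta: sites must be positive")
    if segregating < 0:
        raise ValueError("watterson_theta: segregating count must be >= 0")
    return segregating / (harmonic_number(n_alleles - 1) * sites)


def mutation_rate(K: float, T: float) -> float:
    """U = K / 2T: substitutions per site between homologs over twice the
    divergence time give the per-lineage per-year rate."""
    if T <= 0:
        raise ValueError("divergence time must be positive")
    if K < 0:
        raise ValueError("substitutions per site must be >= 0")
    return K / (2.0 * T)


def ne_estimate(diversity: float, U: float, gen_time: float) -> float:
    """N_E = diversity / (4 U g) for an autosomal-inheritance diversity
    measure with mutation rate U per site per year and generation time g
    in years."""
    if U <= 0 or gen_time <= 0:
        raise ValueError("U and gen_time must be positive")
    if diversity < 0:
        raise ValueError("diversity must be >= 0")
    return diversity / (4.0 * U * gen_time)


def category_ne(
    records: Sequence,
    category: Category,
    U: float,
    gen_time: float,
    n_alleles: int,
    site_class: str = "fourfold",
) -> NEEstimate:
    """Per-category N_E from both pi and Watterson's theta."""
    pi = pi_per_site(records, site_class)
    if site_class == "fourfold":
        seg = sum(r.P_4D for r in records)
        sites = sum(r.L_4D for r in records)
    else:
        seg = sum(r.P_S for r in records)
        sites = sum(r.S for r in records)
    theta = watterson_theta(seg, n_alleles, sites)
    return NEEstimate(
        category=category, diversity_pi=pi, diversity_theta=theta,
        n_alleles=n_alleles, U=U, gen_time=gen_time,
        NE_pi=ne_estimate(pi, U, gen_time),
        NE_theta=ne_estimate(theta, U, gen_time),
    )


EXPECT_MONOGAMY = 0.75  # N_EZ/N_EA under equal sex-specific reproductive variance


def ne_ratio(
    records_z: Sequence,
    records_a: Sequence,
    plan: ResamplingPlan | None = None,
    U_z: float = U_Z_DEFAULT,
    U_a: float = U_A_DEFAULT,
    gen_time: float = 1.0,
    n_alleles_z: int = N_ALLELES_Z,
    n_alleles_a: int = N_ALLELES_AUTO,
    site_class: str = "fourfold",
    measure: str = "pi",
) -> RatioResult:
    """N_EZ / N_EA with a contig-level bootstrap CI.

    Generation time cancels in the ratio; the mutation rates do not
    (their quotient U_a/U_z rescales the diversity ratio).  When the
    bootstrap CI excludes 3/4 the ratio departs from the strict-monogamy
    expectation.
    """
    est_z = category_ne(records_z, Category.Z, U_z, gen_time, n_alleles_z, site_class)
    est_a = category_ne(records_a, Category.ALL_AUTO, U_a, gen_time, n_alleles_a, site_class)
    ne_z = est_z.NE_pi if measure == "pi" else est_z.NE_theta
    ne_a = est_a.NE_pi if measure == "pi" else est_a.NE_theta
    if ne_a <= 0:
        raise ValueError("autosomal N_E is zero; ratio undefined")
    ratio = ne_z / ne_a

    ci_low = ci_high = float("nan")
    n_boot = seed = 0
    if plan is not None:
        if site_class == "fourfold":
            X_z = np.array([[r.P_4D, r.L_4D] for r in records_z], dtype=float)
            X_a = np.array([[r.P_4D, r.L_4D] for r in records_a], dtype=float)
        else:
            X_z = np.array([[r.P_S, r.S] for r in records_z], dtype=float)
            X_a = np.array([[r.P_S, r.S] for r in records_a], dtype=float)
        # H(n-1) factors cancel within each category's pi; for theta they are
        # constants, so the bootstrap distribution of the ratio only needs the
        # diversity ratio rescaled by the constant (U_a/U_z) (x H-ratio for theta)
        if measure == "pi":
            scale = U_a / U_z
        else:
            scale = (U_a / U_z) * (harmonic_number(n_alleles_a - 1)
                                   / harmonic_number(n_alleles_z - 1))
        ci_low, ci_high = bootstrap_ci_two_group(
            X_z, X_a,
            lambda sa, sb: scale * (sa[:, 0] / sa[:, 1]) / (sb[:, 0] / sb[:, 1]),
            plan,
        )
        n_boot, seed = plan.n_boot, plan.seed
    return RatioResult(float(ne_z), float(ne_a), float(ratio),
                       ci_low, ci_high, float("nan"), n_boot, 0, seed)
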