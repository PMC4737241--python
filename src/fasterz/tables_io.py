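"""Domain types, table readers and genomic-category assignment.

Input tables begin downstream of sequence analysis: per-contig substitution
and polymorphic-site counts (as produced by codon-model fitting and SNP
calling), per-SNP sample-level evidence, and species trees.  All tables are
tab-separated with a header row; ``.`` marks a missing value.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd

logger = logging.getLogger("fasterz")


class Category(enum.Enum):
    """Genomic category used to stratify every Z-versus-autosome contrast.

    Microchromosomes differ from macrochromosomes in recombination rate,
    gene density and GC content, so the fairest Faster-Z contrast is the Z
    chromosome against the similarly sized autosomes 1-10; the
    all-autosome and microchromosome categories are kept for completeness.
    """

    Z = "Z"
    AUTO_1_10 = "AUTO_1_10"
    MICRO = "MICRO"
    ALL_AUTO = "ALL_AUTO"


@dataclass(frozen=True)
class DivergenceRecord:
    """Per-contig substitution counts and site counts.

    ``D_N``/``D_S`` are estimated nonsynonymous/synonymous substitution
    counts, ``N``/``S`` the corresponding site counts (real-valued to allow
    fractional codon-site accounting), and ``tree_dS`` the synonymous
    divergence summed over all branches of the tree, used by the
    saturation filter.
    """

    contig_id: str
    chrom: str
    D_N: float
    D_S: float
    N: float
    S: float
    tree_dS: float = 0.0
    species: str | None = None

    def __post_init__(self) -> None:
        if self.D_N < 0 or self.D_S < 0:
            raise ValueError(
                f"contig {self.contig_id!r}: substitution counts must be >= 0"
            )
        if self.N <= 0 or self.S <= 0:
            raise ValueError(
                f"contig {self.contig_id!r}: site counts must be > 0 (N={self.N}, S={self.S})"
            )
        if self.tree_dS < 0:
            raise ValueError(f"contig {self.contig_id!r}: tree_dS must be >= 0")


@dataclass(frozen=True)
class PolymorphismRecord:
    """Per-contig polymorphic-site counts.

    ``P_N``/``P_S`` count nonsynonymous/synonymous polymorphic sites,
    ``P_4D``/``L_4D`` polymorphic and total fourfold-degenerate sites.
    """

    contig_id: str
    chrom: str
    P_N: int
    P_S: int
    N: float
    S: float
    P_4D: int = 0
    L_4D: int = 0

    def __post_init__(self) -> None:
        if self.P_N < 0 or self.P_S < 0 or self.P_4D < 0 or self.L_4D < 0:
            raise ValueError(f"contig {self.contig_id!r}: negative count")
        if self.P_4D > self.L_4D:
            raise ValueError(
                f"contig {self.contig_id!r}: P_4D={self.P_4D} exceeds L_4D={self.L_4D}"
            )
        if self.N <= 0 or self.S <= 0:
            raise ValueError(f"contig {self.contig_id!r}: site counts must be > 0")


@dataclass(frozen=True)
class SnpCall:
    """A single biallelic SNP with per-sample read evidence."""

    contig_id: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float
    per_sample_depth: tuple[int, ...]
    per_sample_qual: tuple[float, ...]
    effect: str  # "synonymous" | "nonsynonymous"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.contig_id}:{self.pos}: position must be >= 1")
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.contig_id}:{self.pos}: maf={self.maf} outside [0, 0.5]")
        if len(self.per_sample_depth) != len(self.per_sample_qual):
            raise ValueError(
                f"{self.contig_id}:{self.pos}: depth and quality vectors differ in length"
            )
        if self.effect not in ("synonymous", "nonsynonymous"):
            raise ValueError(f"{self.contig_id}:{self.pos}: unknown effect {self.effect!r}")


@dataclass
class RunConfig:
    """Analysis-wide thresholds and resampling sizes.

    All randomness flows from ``seed``; every output records the seed and
    the thresholds in force.
    """

    seed: int = 0
    n_boot: int = 1000
    n_perm: int = 1000
    maf_min: float = 0.15
    ds_max: float = 2.0
    fdr: float = 0.05
    qvalue_lambda: float = 0.0

    def __post_init__(self) -> None:
        if self.n_boot < 1 or self.n_perm < 1:
            raise ValueError("n_boot and n_perm must be >= 1")
        for name in ("maf_min", "ds_max", "fdr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.qvalue_lambda < 1):
            raise ValueError("qvalue_lambda must lie in [0, 1)")

    def metadata(self) -> dict:
        """Dict recorded in every result file."""
        return {
            "seed": self.seed,
            "n_boot": self.n_boot,
            "n_perm": self.n_perm,
            "maf_min": self.maf_min,
            "ds_max": self.ds_max,
            "fdr": self.fdr,
            "qvalue_lambda": self.qvalue_lambda,
        }


# chromosome labels excluded from every analysis: the W (female-limited,
# no Z/autosome contrast), mitochondrion, linkage groups without a
# chromosome assignment, and unplaced scaffolds
_EXCLUDED_RE = re.compile(
    r"^(W|MT|M|LG.*|UN.*|JH\d+.*|SCAFFOLD.*|RANDOM.*)$", re.IGNORECASE
)
_MAX_AUTOSOME = 38  # chicken karyotype: autosomes 1..38


def assign_category(chrom: str) -> set[Category]:
    """Map a chromosome label to the genomic categories it belongs to.

    Autosomes numbered 1-10 are macrochromosomes (``AUTO_1_10``); autosomes
    numbered above 10 are microchromosomes (``MICRO``); both belong to
    ``ALL_AUTO``.  The W chromosome, mitochondrion, linkage groups and
    unplaced scaffolds return the empty set and take no part in any
    analysis.  Unrecognizable labels raise ``ValueError``.
    """
    label = str(chrom).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    if not label:
        raise ValueError("empty chromosome label")
    if label.upper() == "Z":
        return {Category.Z}
    if _EXCLUDED_RE.match(label):
        return set()
    if label.isdigit():
        num = int(label)
        if 1 <= num <= _MAX_AUTOSOME:
            if num <= 10:
                return {Category.AUTO_1_10, Category.ALL_AUTO}
            return {Category.MICRO, Category.ALL_AUTO}
    raise ValueError(f"unrecognized chromosome label: {chrom!r}")


def split_by_category(records: Sequence) -> dict[Category, list]:
    """Partition records (anything with a ``chrom`` attribute) by category.

    Records whose chromosome maps to no category are dropped; a record may
    appear in two categories (its macro/micro class and ``ALL_AUTO``).
    """
    out: dict[Category, list] = {cat: [] for cat in Category}
    dropped = 0
    for rec in records:
        cats = assign_category(rec.chrom)
        if not cats:
            dropped += 1
            continue
        for cat in cats:
            out[cat].append(rec)
    logger.info(
        "category split: %d records in, %d excluded (W/MT/unplaced); "
        "Z=%d auto1-10=%d micro=%d all-auto=%d",
        len(records), dropped, len(out[Category.Z]), len(out[Category.AUTO_1_10]),
        len(out[Category.MICRO]), len(out[Category.ALL_AUTO]),
    )
    return out


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "chrom": str},
                     na_values=["."], keep_default_na=False,
                     float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df["contig_id"].duplicated().any():
        dup = df.loc[df["contig_id"].duplicated(), "contig_id"].iloc[0]
        raise ValueError(f"{path}: duplicate contig_id {dup!r}")
    return df


def _record_rows(df: pd.DataFrame, cls, numeric: Sequence[str], path, int_fields=()):
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        kwargs = row._asdict()
        for col in numeric:
            try:
                kwargs[col] = int(kwargs[col]) if col in int_fields else float(kwargs[col])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: line {i}, column {col!r}: non-numeric value {kwargs[col]!r}"
                ) from exc
        try:
            records.append(cls(**kwargs))
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    return records


def read_divergence_table(path: str | Path) -> list[DivergenceRecord]:
    """Read a per-contig divergence table (TSV).

    Required columns: contig_id, chrom, D_N, D_S, N, S, tree_dS; an
    optional ``species`` column tags rows for species-specific analyses.
    """
    cols = ["contig_id", "chrom", "D_N", "D_S", "N", "S", "tree_dS"]
    df = _read_tsv(path, cols)
    keep = cols + (["species"] if "species" in df.columns else [])
    recs = _record_rows(df[keep], DivergenceRecord,
                        ["D_N", "D_S", "N", "S", "tree_dS"], path)
    logger.info("read %d divergence records from %s", len(recs), path)
    return recs


def write_divergence_table(records: Iterable[DivergenceRecord], path: str | Path) -> None:
    rows = [vars(r) for r in records]
    df = pd.DataFrame(rows)
    if "species" in df.columns and df["species"].isna().all():
        df = df.drop(columns="species")
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_polymorphism_table(path: str | Path) -> list[PolymorphismRecord]:
    """Read a per-contig polymorphism table (TSV).

    Required columns: contig_id, chrom, P_N, P_S, N, S, P_4D, L_4D.
    """
    cols = ["contig_id", "chrom", "P_N", "P_S", "N", "S", "P_4D", "L_4D"]
    df = _read_tsv(path, cols)
    recs = _record_rows(df[cols], PolymorphismRecord,
                        ["P_N", "P_S", "N", "S", "P_4D", "L_4D"], path,
                        int_fields=("P_N", "P_S", "P_4D", "L_4D"))
    logger.info("read %d polymorphism records from %s", len(recs), path)
    return recs


def write_polymorphism_table(records: Iterable[PolymorphismRecord], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, sep="\t", index=False)


_SNP_COLS = ["contig_id", "pos", "ref_allele", "alt_allele", "maf",
             "per_sample_depth", "per_sample_qual", "effect"]


def read_snp_table(path: str | Path, dialect: str = "tsv") -> list[SnpCall]:
    """Read per-SNP calls from TSV or a VCF restricted to biallelic SNPs.

    The TSV dialect stores the per-sample depth and quality vectors as
    comma-separated lists.  For VCF, the minor allele frequency is computed
    from called genotypes (missing calls ignored), depth/quality come from
    the per-sample DP and GQ FORMAT fields, and the synonymous versus
    nonsynonymous annotation from an ``EFF`` INFO key.  Multi-allelic
    records and indels are skipped with a logged count.
    """
    if dialect == "tsv":
        return _read_snp_tsv(path)
    if dialect == "vcf":
        return _read_snp_vcf(path)
    raise ValueError(f"unknown SNP dialect {dialect!r}")


def _read_snp_tsv(path: str | Path) -> list[SnpCall]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SNP_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    calls = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            calls.append(SnpCall(
                contig_id=row.contig_id,
                pos=int(row.pos),
                ref_allele=row.ref_allele,
                alt_allele=row.alt_allele,
                maf=float(row.maf),
                per_sample_depth=tuple(int(x) for x in str(row.per_sample_depth).split(",")),
                per_sample_qual=tuple(float(x) for x in str(row.per_sample_qual).split(",")),
                effect=row.effect,
            ))
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    logger.info("read %d SNP calls from %s", len(calls), path)
    return calls


def write_snp_table(calls: Iterable[SnpCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        d = vars(c).copy()
        d["per_sample_depth"] = ",".join(str(x) for x in c.per_sample_depth)
        d["per_sample_qual"] = ",".join(f"{x:g}" for x in c.per_sample_qual)
        rows.append(d)
    pd.DataFrame(rows, columns=_SNP_COLS).to_csv(path, sep="\t", index=False)


def _read_snp_vcf(path: str | Path) -> list[SnpCall]:
    from cyvcf2 import VCF

    calls = []
    skipped_multiallelic = 0
    skipped_indel = 0
    vcf = VCF(str(path))
    for var in vcf:
        if len(var.ALT) != 1:
            skipped_multiallelic += 1
            continue
        if not var.is_snp:
            skipped_indel += 1
            continue
        # allele frequency over called genotypes only
        n_alt = 0
        n_called = 0
        for gt in var.genotypes:  # [allele0, allele1, phased]
            for allele in gt[:-1]:
                if allele >= 0:
                    n_called += 1
                    n_alt += allele
        if n_called == 0:
            continue
        af = n_alt / n_called
        maf = min(af, 1.0 - af)
        depths = var.format("DP")
        quals = var.format("GQ")
        n_samp = len(vcf.samples)
        depth = tuple(int(max(d, 0)) for d in (depths[:, 0] if depths is not None else [0] * n_samp))
        qual = tuple(float(max(q, 0)) for q in (quals[:, 0] if quals is not None else [0.0] * n_samp))
        effect = dict(var.INFO).get("EFF", "synonymous")
        calls.append(SnpCall(
            contig_id=var.CHROM, pos=var.POS,
            ref_allele=var.REF, alt_allele=var.ALT[0],
            maf=maf, per_sample_depth=depth, per_sample_qual=qual,
            effect=str(effect),
        ))
    if skipped_multiallelic or skipped_indel:
        logger.info("VCF %s: skipped %d multi-allelic and %d indel records",
                    path, skipped_multiallelic, skipped_indel)
    logger.info("read %d SNP calls from VCF %s", len(calls), path)
    return calls


def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    Accepts a path or a literal Newick string.  Every edge below the root
    must carry a branch length, because all downstream uses (the Brownian
    covariance of PGLS) need the full path lengths.
    """
    s = str(path_or_string)
    if s.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=s, schema="newick")
    else:
        tree = dendropy.Tree.get(path=s, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:  # the root's own edge may be lengthless
            continue
        if edge.length is None:
            head = edge.head_node
            label = head.taxon.label if head.taxon else "<internal node>"
            raise ValueError(f"edge leading to {label} has no branch length")
    return tree
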