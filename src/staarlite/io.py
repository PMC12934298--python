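"""Readers and writers for the analysis file formats.

Genotypes come from VCF (bi-allelic SNVs, diploid GT) via cyvcf2 or from a
plain sample-by-variant dosage-matrix TSV; annotations from a FAVOR-style
CSV/TSV (gene symbol, functional categories, PHRED-scaled channel scores);
phenotypes from TSV; kinship from coordinate-format triplets. Results are
written as TSV with the cumulative minor-allele count attached to every
aggregate and a report filter on low-cMAC rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ANNOTATION_CHANNELS, NONCODING_CATEGORIES

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeBlock",
    "SparseKinship",
    "read_genotypes",
    "write_dosage_matrix",
    "read_annotations",
    "read_phenotypes",
    "read_kinship",
    "write_results",
]

_CODING_VALUES = {"pLoF", "DS", "missense", "synonymous", "none"}


def variant_key(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass
class GenotypeBlock:
    """Sample-by-variant minor/alt-allele dosage matrix with variant metadata.

    `dosage` holds alt-allele dosages in {0, 1, 2} with NaN for missing
    genotypes; variants are ordered by (chrom, pos, ref, alt). MAC/MAF and
    minor-allele orientation are computed downstream (masks module) so that
    allele counting always reflects observed genotypes only.
    """

    samples: np.ndarray
    dosage: np.ndarray  # (n_samples, n_variants), float with NaN = missing
    variants: pd.DataFrame  # columns chrom, pos, ref, alt
    n_skipped_multiallelic: int = 0

    def __post_init__(self):
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage shape does not match samples x variants")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def keys(self) -> np.ndarray:
        v = self.variants
        return np.array(
            [variant_key(c, p, r, a) for c, p, r, a in zip(v.chrom, v.pos, v.ref, v.alt)]
        )


def _sort_variants(variants: pd.DataFrame, dosage: np.ndarray):
    order = variants.sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort").index
    return variants.loc[order].reset_index(drop=True), dosage[:, np.asarray(order)]


def _read_vcf(path: Path, sample_subset=None) -> GenotypeBlock:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample_subset is not None:
        missing = set(sample_subset) - set(vcf.samples)
        if missing:
            raise ValueError(f"samples not in VCF header: {sorted(missing)}")
        vcf.set_samples(list(sample_subset))
    samples = np.array(vcf.samples)
    rows, dosages, skipped = [], [], 0
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    code = np.array([0.0, 1.0, np.nan, 2.0])
    for v in vcf:
        if len(v.ALT) != 1:
            skipped += 1
            continue
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        dosages.append(code[v.gt_types])
    vcf.close()
    if skipped:
        logger.info("skipped %d multi-allelic records in %s", skipped, path)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosage = (
        np.array(dosages).T if dosages else np.empty((len(samples), 0))
    )
    variants, dosage = _sort_variants(variants, dosage)
    return GenotypeBlock(samples, dosage, variants, n_skipped_multiallelic=skipped)


def _read_dosage_tsv(path: Path, sample_subset=None) -> GenotypeBlock:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    meta_cols = ["chrom", "pos", "ref", "alt"]
    if df.columns[:4].tolist() != meta_cols:
        raise ValueError(f"dosage matrix must start with columns {meta_cols}")
    samples = np.array(df.columns[4:])
    dosage = df.iloc[:, 4:].to_numpy(dtype=float).T
    variants = df[meta_cols].copy()
    if sample_subset is not None:
        idx = {s: i for i, s in enumerate(samples)}
        missing = [s for s in sample_subset if s not in idx]
        if missing:
            raise ValueError(f"samples not in dosage matrix: {missing}")
        sel = np.array([idx[s] for s in sample_subset])
        samples, dosage = samples[sel], dosage[sel]
    ok = np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0))
    if not ok.all():
        raise ValueError("dosages must be 0, 1, 2 or missing")
    variants, dosage = _sort_variants(variants, dosage)
    return GenotypeBlock(samples, dosage, variants)


def read_genotypes(path, sample_subset=None) -> GenotypeBlock:
    """Read a VCF (.vcf/.vcf.gz) or a dosage-matrix TSV into a GenotypeBlock.

    Multi-allelic VCF records are skipped with a logged count; variants are
    returned in deterministic (chrom, pos, ref, alt) order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if ".vcf" in path.suffixes or path.suffix == ".vcf":
        return _read_vcf(path, sample_subset)
    return _read_dosage_tsv(path, sample_subset)


def write_dosage_matrix(block: GenotypeBlock, path) -> None:
    """Write the block as a TSV round-trippable by read_genotypes."""
    df = block.variants[["chrom", "pos", "ref", "alt"]].copy()
    dm = pd.DataFrame(block.dosage.T, columns=block.samples)
    pd.concat([df, dm], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%g")


def write_vcf(block: GenotypeBlock, path) -> None:
    """Write the block as a minimal VCFv4.2 with GT-only genotypes.

    Dosages are alt-allele dosages, so 0 -> 0/0, 1 -> 0/1, 2 -> 1/1 and
    missing -> ./.; reading the file back reproduces the block.
    """
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(block.variants.chrom):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(block.samples)
            + "\n"
        )
        for j, row in enumerate(block.variants.itertuples(index=False)):
            gts = [
                gt_code.get(d, "./.") if not np.isnan(d) else "./."
                for d in block.dosage[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_annotations(path) -> pd.DataFrame:
    """Read a FAVOR-style annotation table (CSV or TSV).

    Required columns: chrom, pos, ref, alt (or a single `variant` key column
    chrom:pos:ref:alt), gene, coding_category; optional: noncoding_categories
    (semicolon-separated flags), is_ncRNA, and the 13 PHRED channel columns
    (missing scores stay NaN, distinguishable from an explicit 0). Returns a
    DataFrame indexed by the variant key string. A disruptive-missense (DS)
    variant is by definition also missense; mask construction relies on it.
    """
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"chrom": str, "ref": str, "alt": str})
    if "variant" in df.columns and "chrom" not in df.columns:
        parts = df["variant"].str.split(":", expand=True)
        df[["chrom", "pos", "ref", "alt"]] = parts
        df["pos"] = df["pos"].astype(int)
    mandatory = ["chrom", "pos", "ref", "alt", "gene", "coding_category"]
    for col in mandatory:
        if col not in df.columns:
            raise ValueError(f"annotation table missing mandatory column {col!r}")
    known = set(
        mandatory + ["variant", "noncoding_categories", "is_ncRNA"] + ANNOTATION_CHANNELS
    )
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("ignoring unknown annotation columns: %s", unknown)
        df = df.drop(columns=unknown)
    bad = set(df["coding_category"].fillna("none")) - _CODING_VALUES
    if bad:
        raise ValueError(f"unknown coding categories: {sorted(bad)}")
    df["coding_category"] = df["coding_category"].fillna("none")
    if "noncoding_categories" not in df.columns:
        df["noncoding_categories"] = ""
    df["noncoding_categories"] = df["noncoding_categories"].fillna("")
    flagged = set()
    for s in df["noncoding_categories"]:
        flagged.update(c for c in str(s).split(";") if c)
    bad = flagged - set(NONCODING_CATEGORIES)
    if bad:
        raise ValueError(f"unknown non-coding categories: {sorted(bad)}")
    if "is_ncRNA" not in df.columns:
        df["is_ncRNA"] = 0
    df["is_ncRNA"] = df["is_ncRNA"].fillna(0).astype(int)
    for ch in ANNOTATION_CHANNELS:
        if ch not in df.columns:
            df[ch] = np.nan
        if (df[ch].dropna() < 0).any():
            raise ValueError(f"negative PHRED scores in channel {ch}")
    keys = [
        variant_key(c, p, r, a) for c, p, r, a in zip(df.chrom, df.pos, df.ref, df.alt)
    ]
    if len(set(keys)) != len(keys):
        dup = pd.Series(keys).value_counts()
        raise ValueError(f"duplicate variant keys in annotations: {dup[dup > 1].index.tolist()[:5]}")
    df.index = pd.Index(keys, name="key")
    return df


def read_phenotypes(path, outcome="outcome") -> pd.DataFrame:
    """Read the phenotype/covariate TSV; sample_id must be unique and the
    outcome non-missing."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("phenotype table needs a sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in phenotype table")
    if outcome not in df.columns:
        raise ValueError(f"phenotype table missing outcome column {outcome!r}")
    if df[outcome].isna().any():
        raise ValueError("missing outcome values; drop those samples first")
    return df


@dataclass
class SparseKinship:
    """Pairwise relatedness coefficients stored as (i, j, value) triplets.

    Entries below the sparsity cutoff are simply absent; the matrix is
    symmetric and the diagonal defaults to 1 for samples never mentioned.
    """

    triplets: pd.DataFrame  # columns sample_i, sample_j, coefficient

    def to_dense(self, sample_ids) -> np.ndarray:
        ids = list(sample_ids)
        idx = {s: i for i, s in enumerate(ids)}
        K = np.eye(len(ids))
        for si, sj, v in self.triplets.itertuples(index=False):
            if si in idx and sj in idx:
                i, j = idx[si], idx[sj]
                K[i, j] = v
                K[j, i] = v
        return K


def read_kinship(path) -> SparseKinship:
    df = pd.read_csv(path, sep="\t", dtype={"sample_i": str, "sample_j": str})
    need = ["sample_i", "sample_j", "coefficient"]
    if list(df.columns[:3]) != need:
        raise ValueError(f"kinship triplets must have columns {need}")
    return SparseKinship(df[need])


RESULT_COLUMNS = [
    "gene",
    "chrom",
    "category",
    "n_snv",
    "cmac",
    "cmac_ultra_rare",
    "p_burden_min",
    "p_skat_min",
    "p_acatv_min",
    "staar_o",
    "mode",
    "applied_modifications",
]


def write_results(results, path, cmac_report_min: int = 10) -> pd.DataFrame:
    """Write the per-aggregate results TSV, dropping rows with cMAC below the
    report threshold (the dropped rows are logged, never silently lost).
    Returns the emitted DataFrame."""
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        df = pd.DataFrame([r.as_row() for r in results], columns=RESULT_COLUMNS)
    if len(df) == 0:
        df = pd.DataFrame(columns=RESULT_COLUMNS)
    kept = df[df["cmac"] >= cmac_report_min] if len(df) else df
    dropped = len(df) - len(kept)
    if dropped:
        excl = df[df["cmac"] < cmac_report_min]
        for row in excl.itertuples(index=False):
            logger.info(
                "excluded %s %s: cMAC %d < %d", row.gene, row.category, row.cmac, cmac_report_min
            )
    kept.to_csv(path, sep="\t", index=False)
    logger.info("wrote %d result rows to %s (%d excluded by cMAC filter)", len(kept), path, dropped)
    return kept
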