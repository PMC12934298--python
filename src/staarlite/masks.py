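"""Gene-by-functional-category variant sets ("masks").

Builds the aggregates tested per gene: the coding masks pLoF, DS, pLoF+DS,
missense (which by definition contains the DS variants) and synonymous; one
mask per non-coding category; and an ncRNA mask. Applies the in-sample
rarity filter (MAF below the threshold, MAC >= 1) and computes each set's
cumulative minor-allele count (cMAC) and ultra-rare (MAC < threshold)
substructure, which drives the omnibus safeguards downstream.

MAC is always counted over observed genotypes only — imputing missing
dosages would fabricate alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import NONCODING_CATEGORIES, AnalysisConfig
from .io import GenotypeBlock

logger = logging.getLogger(__name__)

__all__ = [
    "VariantSet",
    "compute_mac_maf",
    "build_variant_sets",
    "cmac_summary",
    "imputed_minor_dosage",
    "sets_to_bed",
]


@dataclass
class VariantSet:
    """One gene x category aggregate with its ultra-rare substructure."""

    gene: str
    category: str
    chrom: str
    variant_indices: np.ndarray  # indices into the genotype block
    maf: np.ndarray
    mac: np.ndarray
    mac_threshold: int = 10

    @property
    def n_snv(self) -> int:
        return len(self.variant_indices)

    @property
    def cmac_total(self) -> int:
        return int(self.mac.sum())

    @property
    def ultra_rare_mask(self) -> np.ndarray:
        return self.mac < self.mac_threshold

    @property
    def ultra_rare_indices(self) -> np.ndarray:
        return self.variant_indices[self.ultra_rare_mask]

    @property
    def cmac_ultra_rare(self) -> int:
        return int(self.mac[self.ultra_rare_mask].sum())

    def drop_variant(self, local_idx: int) -> "VariantSet":
        """Return the set with one variant removed (for leave-one-out)."""
        keep = np.ones(self.n_snv, dtype=bool)
        keep[local_idx] = False
        return VariantSet(
            self.gene, self.category, self.chrom,
            self.variant_indices[keep], self.maf[keep], self.mac[keep],
            self.mac_threshold,
        )


def compute_mac_maf(block: GenotypeBlock):
    """Per-variant minor-allele count/frequency and minor-allele orientation.

    alt count a = sum of observed dosages; total observed alleles
    t = 2 * n_observed; mac = min(a, t - a); maf = mac / t. `flipped` marks
    variants where the alt allele is the major one (dosages must be
    reflected to count the minor allele).
    """
    D = block.dosage
    observed = ~np.isnan(D)
    n_obs = observed.sum(axis=0)
    if np.any(n_obs == 0):
        bad = np.flatnonzero(n_obs == 0)
        raise ValueError(f"variants with zero observed genotypes at indices {bad.tolist()}")
    a = np.nansum(D, axis=0)
    t = 2.0 * n_obs
    mac = np.minimum(a, t - a)
    maf = mac / t
    flipped = a > t - a
    return mac.astype(int), maf, flipped


def imputed_minor_dosage(block: GenotypeBlock) -> np.ndarray:
    """Minor-allele dosage matrix with missing entries mean-imputed.

    Missing dosages are imputed at 2 x (alt-allele frequency among observed
    genotypes); the minor-allele flip is applied afterwards, so imputed
    values land at 2 x (minor-allele frequency). Used only inside test
    statistics, never for MAC counting.
    """
    D = block.dosage.copy()
    observed = ~np.isnan(D)
    alt_mean = np.nansum(D, axis=0) / observed.sum(axis=0)  # = 2 * alt AF
    idx = np.where(~observed)
    D[idx] = alt_mean[idx[1]]
    _, _, flipped = compute_mac_maf(block)
    D[:, flipped] = 2.0 - D[:, flipped]
    return D


def cmac_summary(vset: VariantSet, mac_threshold: int | None = None):
    """(cmac_total, cmac_ultra_rare, all_ultra_rare) for a set.

    all_ultra_rare is True exactly when every variant has MAC below the
    threshold, i.e. the set's cMAC equals the cMAC of its ultra-rare subset
    — the configuration under which ACAT-V degenerates to the burden test.
    """
    if mac_threshold is not None and mac_threshold != vset.mac_threshold:
        vset = VariantSet(
            vset.gene, vset.category, vset.chrom,
            vset.variant_indices, vset.maf, vset.mac, mac_threshold,
        )
    total = vset.cmac_total
    ultra = vset.cmac_ultra_rare
    return total, ultra, ultra == total


def build_variant_sets(
    annotations: pd.DataFrame,
    block: GenotypeBlock,
    config: AnalysisConfig | None = None,
) -> list:
    """Join annotations to genotypes and build all gene x category sets.

    Variants are filtered to in-sample MAF < rare_maf_threshold and MAC >= 1
    (monomorphic variants carry no information). Unmatched annotation rows
    are dropped with a logged count; empty sets are omitted.
    """
    config = config or AnalysisConfig()
    mac, maf, _ = compute_mac_maf(block)
    keys = block.keys
    key_to_idx = {k: i for i, k in enumerate(keys)}
    matched = annotations.index.isin(key_to_idx)
    if (~matched).sum():
        logger.info("dropping %d annotation rows with no matching genotype", int((~matched).sum()))
    ann = annotations[matched]

    keep = lambda i: mac[i] >= 1 and maf[i] < config.rare_maf_threshold  # noqa: E731

    sets: list[VariantSet] = []
    for gene, sub in ann.groupby("gene", sort=True):
        gidx = {k: key_to_idx[k] for k in sub.index}
        chrom = block.variants.chrom.iloc[next(iter(gidx.values()))]
        coding = sub["coding_category"]

        def _mk(category: str, sel) -> None:
            idx = sorted(gidx[k] for k in sub.index[sel] if keep(gidx[k]))
            if idx:
                idx = np.array(idx)
                sets.append(
                    VariantSet(
                        gene, category, chrom, idx, maf[idx], mac[idx],
                        config.mac_threshold,
                    )
                )

        _mk("pLoF", coding == "pLoF")
        _mk("DS", coding == "DS")
        _mk("pLoF_and_DS", coding.isin(["pLoF", "DS"]))
        _mk("missense", coding.isin(["DS", "missense"]))  # DS is a missense subset
        _mk("synonymous", coding == "synonymous")
        nc_flags = sub["noncoding_categories"].astype(str)
        for cat in NONCODING_CATEGORIES:
            _mk(cat, nc_flags.str.split(";").map(lambda xs: cat in xs))
        _mk("ncRNA", sub["is_ncRNA"] == 1)
    return sets


def sets_to_bed(sets: list, block: GenotypeBlock) -> pd.DataFrame:
    """BED-like table of set definitions for inspection (one row per
    variant-in-set; 0-based start, 1-based end as in BED)."""
    rows = []
    for s in sets:
        v = block.variants.iloc[s.variant_indices]
        for (_, row), mac, maf in zip(v.iterrows(), s.mac, s.maf):
            rows.append(
                (row.chrom, row.pos - 1, row.pos, s.gene, s.category, int(mac), float(maf))
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene", "category", "mac", "maf"]
    )
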