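"""Annotation-weighted omnibus p-value (STAAR-O style) per gene x category.

For every aggregate the three component tests (burden, SKAT, ACAT-V) are run
under two Beta(MAF) weight settings and across annotation channels — the
MAF-only channel plus one channel per PHRED-scaled functional score, whose
percentile multiplies the Beta weight. All resulting p-values are pooled by
an equal-weight Cauchy combination into the omnibus p.

Two modes are provided. "legacy" reproduces the upstream pipeline's
behaviour, including its pathologies for ultra-rare aggregates. "modified"
applies five robustness refinements: (1) the cumulative minor-allele count
is attached to every output row; (2) LINSIGHT channels are excluded from
coding aggregates; (3) ACAT-V entries are excluded when the ultra-rare
subset is non-empty with cMAC below the MAC threshold; (4) ACAT-V entries
are excluded when the aggregate consists entirely of ultra-rare variants
(where ACAT-V degenerates to the burden test and would double-count it in
the Cauchy pool); (5) the missense omnibus no longer pools in the same
gene's disruptive-missense (DS) channel p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CODING_CATEGORIES, MAF_ONLY, AnalysisConfig
from .masks import VariantSet
from .null_model import ScoreStats
from .set_tests import acatv_test, beta_maf_weight, burden_test, cauchy_combine, skat_test

logger = logging.getLogger(__name__)

__all__ = [
    "annotation_percentile",
    "build_channel_grid",
    "staar_o",
    "run_gene",
    "StaarResult",
    "GRID_COLUMNS",
]

TESTS = ("burden", "SKAT", "ACAT_V")
GRID_COLUMNS = ["test", "a1", "a2", "channel", "source_category", "p", "kept", "reason"]

KEPT = "kept"
R_LINSIGHT = "linsight_coding"
R_ACATV_CMAC = "acatv_ultrarare_cmac"
R_ACATV_ALL = "acatv_all_ultrarare"
R_DS = "ds_decoupled"


def annotation_percentile(phred):
    """Convert a PHRED-scaled score to its percentile: 1 - 10^(-phred/10).

    Missing scores map to 0, which zeroes the variant's weight in that
    channel (the variant effectively drops out of the channel).
    """
    phred = np.asarray(phred, dtype=float)
    out = 1.0 - np.power(10.0, -phred / 10.0)
    return np.where(np.isnan(phred) | (phred < 0), 0.0, out)


def _set_percentiles(vset: VariantSet, annotations: pd.DataFrame, keys, channels):
    """(n_snv, n_channels) annotation percentile matrix for a set."""
    set_keys = keys[vset.variant_indices]
    sub = annotations.reindex(set_keys)
    return {ch: annotation_percentile(sub[ch].to_numpy()) for ch in channels}


def build_channel_grid(
    vset: VariantSet,
    stats: ScoreStats,
    annotations: pd.DataFrame,
    block_keys: np.ndarray,
    config: AnalysisConfig | None = None,
    mode: str = "modified",
) -> pd.DataFrame:
    """Compute the (test x weight setting x channel) p-value grid for a set.

    Every entry is computed; in modified mode entries hit by a safeguard are
    flagged excluded with exactly one reason (the all-ultra-rare reason wins
    over the low-cMAC one, being the more specific diagnosis). `stats` is
    the full-block score statistics; the set's rows are subset here.
    """
    config = config or AnalysisConfig()
    if mode not in ("legacy", "modified"):
        raise ValueError(f"unknown mode {mode!r}")
    sub = stats.subset(vset.variant_indices)
    perc = _set_percentiles(vset, annotations, block_keys, config.channels)
    is_coding = vset.category in CODING_CATEGORIES

    cmac_total = vset.cmac_total
    cmac_ur = vset.cmac_ultra_rare
    has_ur = bool(vset.ultra_rare_mask.any())
    acatv_reason = None
    if mode == "modified":
        if has_ur and cmac_ur == cmac_total:
            acatv_reason = R_ACATV_ALL
        elif has_ur and cmac_ur < config.mac_threshold:
            acatv_reason = R_ACATV_CMAC

    rows = []
    for setting in config.settings:
        bw = beta_maf_weight(vset.maf, setting)
        for channel in [MAF_ONLY] + list(config.channels):
            a = np.ones(vset.n_snv) if channel == MAF_ONLY else perc[channel]
            u = bw * a
            degenerate = not np.any(u != 0)
            for test in TESTS:
                if degenerate:
                    p = 1.0
                elif test == "burden":
                    p = burden_test(sub.S, sub.Sigma, u)
                elif test == "SKAT":
                    p = skat_test(sub.S, sub.Sigma, u)
                else:
                    p = acatv_test(
                        sub.S, sub.Sigma, vset.maf, vset.mac, setting,
                        annotation=None if channel == MAF_ONLY else a,
                        mac_threshold=config.mac_threshold,
                    )
                reason = KEPT
                if test == "ACAT_V" and acatv_reason is not None:
                    reason = acatv_reason
                elif channel == "LINSIGHT" and is_coding and mode == "modified":
                    reason = R_LINSIGHT
                rows.append(
                    (test, setting.a1, setting.a2, channel, vset.category,
                     float(p), reason == KEPT, reason)
                )
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def staar_o(grid: pd.DataFrame) -> float:
    """Equal-weight Cauchy combination of all kept grid entries.

    If every entry is excluded, falls back to the burden+SKAT pool (the
    safeguards only ever target ACAT-V and single channels, so this pool is
    non-empty for any non-empty grid); an empty grid is an error.
    """
    pool = grid.loc[grid["kept"], "p"].to_numpy()
    if pool.size == 0:
        pool = grid.loc[grid["test"].isin(["burden", "SKAT"]), "p"].to_numpy()
    if pool.size == 0:
        raise ValueError("empty omnibus pool")
    return cauchy_combine(pool)


@dataclass
class StaarResult:
    """One output row: an aggregate's component and omnibus p-values."""

    gene: str
    category: str
    chrom: str
    n_snv: int
    cmac: int
    cmac_ultra_rare: int
    staar_o: float
    p_burden_min: float
    p_skat_min: float
    p_acatv_min: float
    mode: str
    applied_modifications: tuple = ()
    grid: pd.DataFrame | None = field(default=None, repr=False)

    def as_row(self) -> tuple:
        return (
            self.gene, self.chrom, self.category, self.n_snv, self.cmac,
            self.cmac_ultra_rare, self.p_burden_min, self.p_skat_min,
            self.p_acatv_min, self.staar_o, self.mode,
            ";".join(self.applied_modifications),
        )


def _component_min(grid: pd.DataFrame, test: str) -> float:
    kept = grid[(grid["test"] == test) & grid["kept"]]["p"]
    return float(kept.min()) if len(kept) else float("nan")


def run_gene(
    gene: str,
    sets: list,
    stats: ScoreStats,
    annotations: pd.DataFrame,
    block_keys: np.ndarray,
    config: AnalysisConfig | None = None,
    mode: str = "modified",
    keep_grids: bool = True,
) -> list:
    """Run the omnibus for every aggregate of one gene.

    In legacy mode the missense aggregate's pool additionally contains the
    same gene's DS channel p-values (the coupling the decoupling refinement
    removes); in modified mode those entries are present in the audit grid
    but excluded with reason ds_decoupled.
    """
    config = config or AnalysisConfig()
    sets = [s for s in sets if s.gene == gene]
    grids = {
        s.category: build_channel_grid(s, stats, annotations, block_keys, config, mode)
        for s in sets
    }
    results = []
    for s in sets:
        grid = grids[s.category]
        if s.category == "missense" and "DS" in grids:
            ds_rows = grids["DS"].copy()
            ds_rows["source_category"] = "DS"
            if mode == "modified":
                ds_rows["kept"] = False
                ds_rows["reason"] = R_DS
            grid = pd.concat([grid, ds_rows], ignore_index=True)
        mods = tuple(sorted(set(grid.loc[~grid["kept"], "reason"])))
        results.append(
            StaarResult(
                gene=gene,
                category=s.category,
                chrom=s.chrom,
                n_snv=s.n_snv,
                cmac=s.cmac_total,
                cmac_ultra_rare=s.cmac_ultra_rare,
                staar_o=staar_o(grid),
                p_burden_min=_component_min(grid, "burden"),
                p_skat_min=_component_min(grid, "SKAT"),
                p_acatv_min=_component_min(grid, "ACAT_V"),
                mode=mode,
                applied_modifications=mods,
                grid=grid if keep_grids else None,
            )
        )
    return results
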