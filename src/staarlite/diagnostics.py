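"""Influence diagnostics for gene aggregates.

`lovo` is the leave-one-variant-out analysis: the omnibus p-value is
recomputed with each variant removed in turn, which localises the variants
an aggregate's significance depends on. Removing a variant changes the
set's cumulative minor-allele count and its ultra-rare substructure, so the
omnibus safeguards are re-evaluated per reduced set rather than frozen at
their full-set state.

`channel_decomposition` exports the per-(test, weight setting, channel)
p-value grid in long format, the data behind annotation-set p-value plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .masks import VariantSet
from .null_model import ScoreStats
from .omnibus import R_DS, build_channel_grid, staar_o

__all__ = ["LovoResult", "lovo", "channel_decomposition"]


@dataclass
class LovoResult:
    """Full-set omnibus p plus one recomputed p per removed variant."""

    gene: str
    category: str
    full_set_p: float
    table: pd.DataFrame  # columns: removed_key, n_snv, cmac, staar_o

    def max_min_ratio(self) -> float:
        p = self.table["staar_o"].to_numpy()
        return float(p.max() / p.min())


def _omnibus_with_coupling(
    vset: VariantSet,
    stats: ScoreStats,
    annotations: pd.DataFrame,
    block_keys: np.ndarray,
    config: AnalysisConfig,
    mode: str,
    ds_set: VariantSet | None,
) -> float:
    grid = build_channel_grid(vset, stats, annotations, block_keys, config, mode)
    if vset.category == "missense" and ds_set is not None and ds_set.n_snv:
        ds_grid = build_channel_grid(ds_set, stats, annotations, block_keys, config, mode)
        ds_grid["source_category"] = "DS"
        if mode == "modified":
            ds_grid["kept"] = False
            ds_grid["reason"] = R_DS
        grid = pd.concat([grid, ds_grid], ignore_index=True)
    return staar_o(grid)


def lovo(
    vset: VariantSet,
    stats: ScoreStats,
    annotations: pd.DataFrame,
    block_keys: np.ndarray,
    config: AnalysisConfig | None = None,
    mode: str = "modified",
    ds_set: VariantSet | None = None,
) -> LovoResult:
    """Leave-one-variant-out omnibus p-values for a set.

    For each of the set's n variants the aggregate is rebuilt without it —
    recomputing cMAC, the ultra-rare subset and therefore which safeguards
    trigger — and the omnibus is recomputed; the unmodified full-set value
    is reported alongside. For a missense set, `ds_set` couples the gene's
    DS channels exactly as in the main analysis, and a removed variant that
    is also in the DS set is removed from both.
    """
    config = config or AnalysisConfig()
    if vset.n_snv < 2:
        raise ValueError("leave-one-variant-out needs at least 2 variants")
    full_p = _omnibus_with_coupling(
        vset, stats, annotations, block_keys, config, mode, ds_set
    )
    rows = []
    for j in range(vset.n_snv):
        reduced = vset.drop_variant(j)
        removed_idx = vset.variant_indices[j]
        ds_reduced = ds_set
        if ds_set is not None and removed_idx in ds_set.variant_indices:
            local = int(np.flatnonzero(ds_set.variant_indices == removed_idx)[0])
            ds_reduced = ds_set.drop_variant(local)
            if ds_reduced.n_snv == 0:
                ds_reduced = None
        p = _omnibus_with_coupling(
            reduced, stats, annotations, block_keys, config, mode, ds_reduced
        )
        rows.append(
            {
                "removed_key": block_keys[removed_idx],
                "n_snv": reduced.n_snv,
                "cmac": reduced.cmac_total,
                "staar_o": p,
            }
        )
    return LovoResult(vset.gene, vset.category, full_p, pd.DataFrame(rows))


def channel_decomposition(grid: pd.DataFrame, vset: VariantSet | None = None) -> pd.DataFrame:
    """Long-format audit table: one row per (test, setting, channel) entry
    with its p-value, inclusion flag and exclusion reason."""
    out = grid.copy()
    if vset is not None:
        out.insert(0, "gene", vset.gene)
        out.insert(1, "category", vset.category)
    return out
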