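"""Model/Results front end for the whole analysis.

`StaarModel` bundles genotypes, annotations, phenotype/covariates and an
optional kinship matrix; `fit()` fits the null model once, computes score
statistics for every variant, builds the gene-by-category masks and runs
the annotation-weighted omnibus over all of them, returning a
`StaarResults` with the per-aggregate table, `summary()`, the channel audit
and leave-one-variant-out diagnostics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .diagnostics import LovoResult, channel_decomposition, lovo
from .io import GenotypeBlock, SparseKinship, write_results
from .masks import build_variant_sets, imputed_minor_dosage
from .null_model import fit_null_model, score_statistics
from .omnibus import run_gene

logger = logging.getLogger(__name__)

__all__ = ["StaarModel", "StaarResults"]


class StaarModel:
    """Gene-centric annotation-weighted rare-variant association model.

    Parameters
    ----------
    genotypes : GenotypeBlock
    annotations : DataFrame from read_annotations (indexed by variant key)
    phenotype : DataFrame with sample_id, outcome and covariates
    covariate_names : covariates to adjust for (intercept always added)
    config : AnalysisConfig, thresholds and channel list
    kinship : optional SparseKinship or dense ndarray for related samples
    family : "binary" (logistic) or "continuous" (linear)
    """

    def __init__(
        self,
        genotypes: GenotypeBlock,
        annotations: pd.DataFrame,
        phenotype: pd.DataFrame,
        covariate_names,
        config: AnalysisConfig | None = None,
        kinship=None,
        family: str = "binary",
    ):
        self.config = config or AnalysisConfig()
        self.covariate_names = list(covariate_names)
        self.family = family

        pheno_ids = phenotype["sample_id"].to_numpy()
        geno_idx = {s: i for i, s in enumerate(genotypes.samples)}
        missing = [s for s in pheno_ids if s not in geno_idx]
        if missing:
            raise ValueError(
                f"{len(missing)} phenotype samples missing from genotypes, e.g. {missing[:3]}"
            )
        order = np.array([geno_idx[s] for s in pheno_ids])
        self.block = GenotypeBlock(
            genotypes.samples[order],
            genotypes.dosage[order],
            genotypes.variants,
            genotypes.n_skipped_multiallelic,
        )
        self.phenotype = phenotype.reset_index(drop=True)
        self.annotations = annotations
        if isinstance(kinship, SparseKinship):
            kinship = kinship.to_dense(pheno_ids)
        self.kinship = kinship

    def fit(self, mode: str = "modified") -> "StaarResults":
        """Fit the null model and run the omnibus for every aggregate."""
        if mode not in ("legacy", "modified"):
            raise ValueError(f"unknown mode {mode!r}")
        null = fit_null_model(
            self.phenotype, self.covariate_names, family=self.family, kinship=self.kinship
        )
        stats = score_statistics(null, imputed_minor_dosage(self.block))
        sets = build_variant_sets(self.annotations, self.block, self.config)
        keys = self.block.keys
        results = []
        for gene in sorted({s.gene for s in sets}):
            results.extend(
                run_gene(
                    gene, sets, stats, self.annotations, keys,
                    self.config, mode, keep_grids=True,
                )
            )
        logger.info("tested %d aggregates in %s mode", len(results), mode)
        return StaarResults(self, null, stats, sets, results, mode)


class StaarResults:
    """Fitted results: per-aggregate omnibus table plus diagnostics hooks."""

    def __init__(self, model, null_model, stats, sets, results, mode):
        self.model = model
        self.null_model = null_model
        self.stats = stats
        self.sets = sets
        self.results = results
        self.mode = mode

    @property
    def table(self) -> pd.DataFrame:
        from .io import RESULT_COLUMNS

        return pd.DataFrame([r.as_row() for r in self.results], columns=RESULT_COLUMNS)

    def significant(self, suggestive: bool = False) -> pd.DataFrame:
        cfg = self.model.config
        alpha = cfg.alpha_suggestive if suggestive else cfg.alpha
        t = self.table
        return t[(t["staar_o"] < alpha) & (t["cmac"] >= cfg.cmac_report_min)]

    def save(self, path) -> pd.DataFrame:
        """Write the results TSV with the cMAC report filter applied."""
        return write_results(self.table, path, self.model.config.cmac_report_min)

    def _find_set(self, gene: str, category: str):
        for s in self.sets:
            if s.gene == gene and s.category == category:
                return s
        raise KeyError(f"no aggregate for {gene}/{category}")

    def lovo(self, gene: str, category: str) -> LovoResult:
        """Leave-one-variant-out analysis for one aggregate, in this fit's mode."""
        vset = self._find_set(gene, category)
        ds_set = None
        if category == "missense":
            try:
                ds_set = self._find_set(gene, "DS")
            except KeyError:
                pass
        return lovo(
            vset, self.stats, self.model.annotations, self.model.block.keys,
            self.model.config, self.mode, ds_set,
        )

    def channel_audit(self) -> pd.DataFrame:
        """Long-format audit of every grid entry for every aggregate."""
        parts = []
        for r in self.results:
            if r.grid is None:
                continue
            g = r.grid.copy()
            g.insert(0, "gene", r.gene)
            g.insert(1, "category", r.category)
            parts.append(g)
        if not parts:
            return pd.DataFrame()
        return pd.concat(parts, ignore_index=True)

    def summary(self) -> str:
        cfg = self.model.config
        t = self.table
        lines = [
            "Annotation-weighted rare-variant omnibus scan",
            "=" * 46,
            f"mode:                 {self.mode}",
            f"family:               {self.null_model.family}",
            f"samples:              {len(self.null_model.mu_hat)}",
            f"variance component:   tau = {self.null_model.tau:.4g}",
            f"aggregates tested:    {len(t)}",
            f"rare MAF threshold:   {cfg.rare_maf_threshold}",
            f"ultra-rare MAC <      {cfg.mac_threshold}",
            f"significant (p < {cfg.alpha:g}): {int((t.staar_o < cfg.alpha).sum())}",
            f"suggestive (p < {cfg.alpha_suggestive:g}):  {int((t.staar_o < cfg.alpha_suggestive).sum())}",
        ]
        top = t.nsmallest(min(5, len(t)), "staar_o")
        if len(top):
            lines.append("")
            lines.append("top aggregates (gene, category, n_snv, cMAC, STAAR-O):")
            for row in top.itertuples(index=False):
                lines.append(
                    f"  {row.gene:<12} {row.category:<12} {row.n_snv:>5} "
                    f"{row.cmac:>6} {row.staar_o:.3e}"
                )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<StaarResults mode={self.mode!r} aggregates={len(self.results)} "
            f"tau={self.null_model.tau:.3g}>"
        )


# re-export for the diagnostics API surface
StaarResults.channel_decomposition = staticmethod(channel_decomposition)
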