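"""Channel grid assembly, omnibus combination, and the robustness safeguards."""

import numpy as np
import pandas as pd
import pytest

from staarlite.config import AnalysisConfig
from staarlite.masks import build_variant_sets, imputed_minor_dosage
from staarlite.null_model import fit_null_model, score_statistics
from staarlite.omnibus import (
    GRID_COLUMNS,
    annotation_percentile,
    build_channel_grid,
    run_gene,
    staar_o,
)
from tests.conftest import block_from_columns, make_logistic_pheno
from tests.test_masks import annotation_frame
from tests.test_set_tests import brute_force_cauchy


class TestAnnotationPercentile:
    @pytest.mark.parametrize("phred,expected", [(0.0, 0.0), (10.0, 0.9), (20.0, 0.99)])
    def test_closed_form(self, phred, expected):
        assert annotation_percentile(phred) == pytest.approx(expected, abs=1e-12)

    def test_missing_maps_to_zero(self):
        assert annotation_percentile(np.nan) == 0.0

    def test_range(self):
        vals = annotation_percentile(np.linspace(0, 60, 50))
        assert np.all((vals >= 0) & (vals < 1))
        assert np.all(np.diff(vals) > 0)


def _planted_gene(macs, category="pLoF", n=1200, seed=31):
    """Block + annotations + fitted null + stats for one gene with given MACs."""
    rng = np.random.default_rng(seed)
    cols = []
    for mac in macs:
        carriers = rng.choice(n, mac, replace=False)
        col = np.zeros(n)
        col[carriers] = 1
        cols.append(col)
    block = block_from_columns(cols)
    ann = annotation_frame(block, "G1", [category] * len(macs))
    ph = make_logistic_pheno(n, seed=seed + 1)
    model = fit_null_model(ph, ["x"])
    stats = score_statistics(model, imputed_minor_dosage(block))
    sets = build_variant_sets(ann, block)
    return block, ann, stats, sets


class TestModificationFlags:
    def test_all_ultra_rare_excludes_acatv(self):
        block, ann, stats, sets = _planted_gene([1, 1, 9])
        (s,) = [x for x in sets if x.category == "pLoF"]
        grid = build_channel_grid(s, stats, ann, block.keys, mode="modified")
        acatv = grid[grid.test == "ACAT_V"]
        assert (~acatv.kept).all()
        assert (acatv.reason == "acatv_all_ultrarare").all()

    def test_low_ultra_rare_cmac_excludes_acatv(self):
        block, ann, stats, sets = _planted_gene([1, 1, 12])
        (s,) = [x for x in sets if x.category == "pLoF"]
        grid = build_channel_grid(s, stats, ann, block.keys, mode="modified")
        acatv = grid[grid.test == "ACAT_V"]
        assert (~acatv.kept).all()
        assert (acatv.reason == "acatv_ultrarare_cmac").all()

    def test_healthy_set_keeps_acatv(self):
        # ultra-rare subset present but with cMAC >= 10: no ACAT-V exclusion
        # (the coding LINSIGHT channel is still excluded for every test)
        block, ann, stats, sets = _planted_gene([4, 7, 15])
        (s,) = [x for x in sets if x.category == "pLoF"]
        grid = build_channel_grid(s, stats, ann, block.keys, mode="modified")
        acatv = grid[(grid.test == "ACAT_V") & (grid.channel != "LINSIGHT")]
        assert acatv.kept.all()

    def test_no_ultra_rare_subset_untouched(self):
        block, ann, stats, sets = _planted_gene([12, 15])
        (s,) = [x for x in sets if x.category == "pLoF"]
        grid = build_channel_grid(s, stats, ann, block.keys, mode="modified")
        acatv = grid[(grid.test == "ACAT_V") & (grid.channel != "LINSIGHT")]
        assert acatv.kept.all()

    def test_linsight_excluded_for_coding_only(self):
        block, ann, stats, sets = _planted_gene([4, 7, 15], category="pLoF")
        (s,) = [x for x in sets if x.category == "pLoF"]
        grid = build_channel_grid(s, stats, ann, block.keys, mode="modified")
        lin = grid[grid.channel == "LINSIGHT"]
        assert (~lin.kept).all() and (lin.reason == "linsight_coding").all()
        # legacy keeps LINSIGHT even for coding sets
        legacy = build_channel_grid(s, stats, ann, block.keys, mode="legacy")
        assert legacy[legacy.channel == "LINSIGHT"].kept.all()

    def test_linsight_kept_for_noncoding(self):
        rng = np.random.default_rng(3)
        n = 1600
        cols = [np.zeros(n) for _ in range(3)]
        cols[0][rng.choice(n, 4, replace=False)] = 1
        cols[1][rng.choice(n, 7, replace=False)] = 1
        cols[2][rng.choice(n, 15, replace=False)] = 1
        block = block_from_columns(cols)
        ann = annotation_frame(block, "G1", ["none"] * 3, noncoding="upstream")
        ph = make_logistic_pheno(n, seed=5)
        model = fit_null_model(ph, ["x"])
        stats = score_statistics(model, imputed_minor_dosage(block))
        (s,) = build_variant_sets(ann, block)
        grid = build_channel_grid(s, stats, ann, block.keys, mode="modified")
        assert grid[grid.channel == "LINSIGHT"].kept.all()

    def test_exclusion_bookkeeping_exhaustive(self):
        block, ann, stats, sets = _planted_gene([1, 1, 12])
        (s,) = [x for x in sets if x.category == "pLoF"]
        grid = build_channel_grid(s, stats, ann, block.keys, mode="modified")
        assert list(grid.columns) == GRID_COLUMNS
        assert ((grid.reason == "kept") == grid.kept).all()
        assert set(grid.loc[~grid.kept, "reason"]) <= {
            "linsight_coding", "acatv_ultrarare_cmac", "acatv_all_ultrarare", "ds_decoupled",
        }


class TestStaarO:
    def test_symmetric_pool(self):
        grid = pd.DataFrame(
            {
                "test": ["burden"] * 4,
                "a1": 1.0, "a2": 1.0,
                "channel": "MAF_only", "source_category": "pLoF",
                "p": [0.5] * 4, "kept": True, "reason": "kept",
            }
        )
        assert staar_o(grid) == pytest.approx(0.5, abs=1e-12)

    def test_matches_brute_force_cauchy(self):
        block, ann, stats, sets = _planted_gene([1, 1, 12])
        (s,) = [x for x in sets if x.category == "pLoF"]
        grid = build_channel_grid(s, stats, ann, block.keys, mode="modified")
        expected = brute_force_cauchy(grid.loc[grid.kept, "p"].tolist())
        assert staar_o(grid) == pytest.approx(expected, abs=1e-14)

    def test_legacy_pool_duplicates_acatv_on_all_ultra_rare(self):
        # channel-wise ACAT-V == burden for an all-ultra-rare set, so the
        # legacy pool holds every burden p twice; modified holds it once
        block, ann, stats, sets = _planted_gene([1, 1, 9])
        # distinct channel scores so every grid entry carries a distinct p
        rng = np.random.default_rng(55)
        from staarlite.config import ANNOTATION_CHANNELS

        for ch in ANNOTATION_CHANNELS:
            ann[ch] = np.round(rng.gamma(2.0, 4.0, size=len(ann)), 3)
        (s,) = [x for x in sets if x.category == "pLoF"]
        grid = build_channel_grid(s, stats, ann, block.keys, mode="modified")
        burden = grid[grid.test == "burden"].set_index(["a1", "a2", "channel"]).p
        acatv = grid[grid.test == "ACAT_V"].set_index(["a1", "a2", "channel"]).p
        assert np.allclose(burden.values, acatv.values)
        # modified pool: every ACAT_V row excluded, so it is one third
        # smaller than the legacy pool (which keeps the duplicates) apart
        # from the LINSIGHT-coding exclusions
        kept = grid[grid.kept]
        n_linsight_bs = int(((grid.channel == "LINSIGHT") & (grid.test != "ACAT_V")).sum())
        assert len(kept) == len(grid) * 2 / 3 - n_linsight_bs
        # multiset relation: each non-LINSIGHT burden p appears once in the
        # modified pool and (at least) twice in the legacy pool
        mod_pool = kept.p.tolist()
        legacy_pool = grid.p.tolist()
        for p in grid[(grid.test == "burden") & (grid.channel != "LINSIGHT")].p:
            assert mod_pool.count(p) == 1
            assert legacy_pool.count(p) >= 2

    def test_modified_equals_legacy_without_triggers(self):
        # no ultra-rare variants, non-coding category, no DS coupling:
        # bit-identical omnibus in the two modes
        rng = np.random.default_rng(13)
        n = 2100
        cols = []
        for mac in (12, 15, 20):
            col = np.zeros(n)
            col[rng.choice(n, mac, replace=False)] = 1
            cols.append(col)
        block = block_from_columns(cols)
        ann = annotation_frame(block, "G1", ["none"] * 3, noncoding="UTR")
        ph = make_logistic_pheno(n, seed=14)
        model = fit_null_model(ph, ["x"])
        stats = score_statistics(model, imputed_minor_dosage(block))
        (s,) = build_variant_sets(ann, block)
        g_mod = build_channel_grid(s, stats, ann, block.keys, mode="modified")
        g_leg = build_channel_grid(s, stats, ann, block.keys, mode="legacy")
        assert staar_o(g_mod) == staar_o(g_leg)

    def test_excluding_pool_minimum_never_decreases_omnibus(self):
        block, ann, stats, sets = _planted_gene([1, 1, 9])
        (s,) = [x for x in sets if x.category == "pLoF"]
        grid = build_channel_grid(s, stats, ann, block.keys, mode="legacy")
        p_full = staar_o(grid)
        drop = grid.p.idxmin()
        reduced = grid.drop(index=drop)
        assert staar_o(reduced) >= p_full


class TestRunGeneDecoupling:
    def test_gene_without_ds_identical_across_modes(self):
        # isolate the decoupling refinement: with no DS variants, no
        # ultra-rare trigger and LINSIGHT out of the channel list, the
        # missense omnibus is bit-identical across modes
        block, ann, stats, sets = _planted_gene([4, 7, 14], category="missense")
        cfg = AnalysisConfig(channels=["aPC1", "aPC2", "CADD"])
        leg = run_gene("G1", sets, stats, ann, block.keys, cfg, mode="legacy")
        mod = run_gene("G1", sets, stats, ann, block.keys, cfg, mode="modified")
        p_leg = {r.category: r.staar_o for r in leg}
        p_mod = {r.category: r.staar_o for r in mod}
        assert p_leg["missense"] == p_mod["missense"]

    def test_legacy_missense_pool_includes_ds_entries(self):
        rng = np.random.default_rng(41)
        n = 1600
        cols = []
        macs = [2, 3, 8, 12, 15]
        for mac in macs:
            col = np.zeros(n)
            col[rng.choice(n, mac, replace=False)] = 1
            cols.append(col)
        block = block_from_columns(cols)
        ann = annotation_frame(block, "G1", ["DS", "DS", "missense", "missense", "missense"])
        ph = make_logistic_pheno(n, seed=42)
        model = fit_null_model(ph, ["x"])
        stats = score_statistics(model, imputed_minor_dosage(block))
        sets = build_variant_sets(ann, block)
        leg = {r.category: r for r in run_gene("G1", sets, stats, ann, block.keys, mode="legacy")}
        mod = {r.category: r for r in run_gene("G1", sets, stats, ann, block.keys, mode="modified")}
        g_leg, g_mod = leg["missense"].grid, mod["missense"].grid
        assert (g_leg.source_category == "DS").sum() > 0
        assert g_leg[g_leg.source_category == "DS"].kept.any()
        ds_mod = g_mod[g_mod.source_category == "DS"]
        assert (~ds_mod.kept).all() and (ds_mod.reason == "ds_decoupled").all()
        assert "ds_decoupled" in mod["missense"].applied_modifications

    def test_result_rows_carry_counts(self):
        block, ann, stats, sets = _planted_gene([1, 1, 12])
        results = run_gene("G1", sets, stats, ann, block.keys, mode="modified")
        for r in results:
            assert r.n_snv >= 1
            assert r.cmac >= r.cmac_ultra_rare >= 0
            assert 0 < r.staar_o <= 1
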