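"""Synthetic genotypes, annotations and binary phenotypes.

Emulates the data regime of a gene-centric rare-variant association study of
a dichotomous trait: bi-allelic rare variants (in-sample MAF < 1%) with a
site-frequency spectrum dominated by singletons and doubletons, a binary
outcome from a logistic model on covariates calibrated to the study's 37%
case fraction, and PHRED-scaled functional annotation channels.

Besides generic simulation, `make_fixture` constructs the three pathological
aggregate structures that motivate the omnibus safeguards:

* ``ssna1_like`` — 3 SNVs with MACs {1, 1, 12}; one singleton carrier is a
  case with an extreme score-test residual, so the ultra-rare pooled burden
  inside ACAT-V goes extreme while burden/SKAT on the full set stay flat.
* ``lcnl1_like`` — 2 SNVs with MACs {2, 9}: every variant ultra-rare, so
  ACAT-V degenerates to the burden test and duplicates it in the omnibus.
* ``phlda1_like`` — a missense aggregate whose signal lives entirely in its
  two ultra-rare disruptive-missense (DS) variants (combined MAC < 10),
  reproducing the missense/DS coupling pathology.
* ``null_gene`` — a gene with no phenotype effect.

No linkage disequilibrium is simulated: every test consumes the covariance
of realized genotypes, so unlinked sites exercise the full machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ANNOTATION_CHANNELS, AnalysisConfig
from .io import GenotypeBlock
from .masks import VariantSet, compute_mac_maf, imputed_minor_dosage
from .null_model import fit_null_model, score_statistics
from .omnibus import build_channel_grid, staar_o
from .set_tests import cauchy_combine

__all__ = [
    "SimulationConfig",
    "Fixture",
    "simulate_genotypes",
    "simulate_annotations",
    "simulate_phenotype",
    "make_fixture",
    "type1_error_harness",
]

#: default site-frequency spectrum: (mass, kind, params); "mac" targets a
#: fixed expected minor-allele count, "loguniform" a MAF range
DEFAULT_SPECTRUM = (
    (0.40, "mac", 1),
    (0.15, "mac", 2),
    (0.10, "mac", 5),
    (0.35, "loguniform", (1e-3, 9e-3)),
)


@dataclass
class SimulationConfig:
    """All knobs of the generator; every run is a pure function of `seed`."""

    n_samples: int = 10_000
    n_genes: int = 50
    variants_per_gene: tuple = (2, 12)  # inclusive uniform range
    maf_spectrum: tuple = DEFAULT_SPECTRUM
    prevalence: float = 0.37
    covariate_effects: tuple = (("sex", "bernoulli", 0.3), ("pc1", "normal", 0.5))
    causal_fraction: float = 0.0
    effect_size: float = 0.0  # log-odds per minor allele at causal variants
    annotation_shift: float = 10.0  # PHRED offset added to causal variants
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % 2**31, stream])


def _draw_maf(rng, spectrum, n_samples, size):
    masses = np.array([m for m, *_ in spectrum])
    choice = rng.choice(len(spectrum), p=masses / masses.sum(), size=size)
    maf = np.empty(size)
    for i, c in enumerate(choice):
        _, kind, par = spectrum[c]
        if kind == "mac":
            maf[i] = par / (2.0 * n_samples)
        elif kind == "loguniform":
            lo, hi = par
            maf[i] = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        else:
            raise ValueError(f"unknown spectrum component {kind!r}")
    return maf


def _block_from_columns(columns, chrom="1", pos_start=1000, gene_names=None, samples=None):
    m = len(columns)
    n = len(columns[0])
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos_start + 10 * np.arange(m),
            "ref": "A",
            "alt": "T",
        }
    )
    if gene_names is not None:
        variants["gene"] = gene_names
    if samples is None:
        samples = np.array([f"S{i:06d}" for i in range(n)])
    return GenotypeBlock(samples, np.column_stack(columns), variants)


def simulate_genotypes(config: SimulationConfig, rng=None) -> GenotypeBlock:
    """Unlinked rare genotypes: dosage_ij ~ Binomial(2, maf_j) i.i.d. over samples.

    Realized-monomorphic variants are redrawn up to 10 times, then dropped.
    The block's `variants` table carries the gene assignment.
    """
    rng = rng or _rng(config, 0)
    n = config.n_samples
    lo, hi = config.variants_per_gene
    cols, genes, positions = [], [], []
    for g in range(config.n_genes):
        m = int(rng.integers(lo, hi + 1))
        maf = _draw_maf(rng, config.maf_spectrum, n, m)
        for j in range(m):
            for _ in range(10):
                d = rng.binomial(2, maf[j], size=n).astype(float)
                if 0 < d.sum() < 2 * n:
                    break
            else:
                continue  # persistently monomorphic: drop
            cols.append(d)
            genes.append(f"GENE{g:04d}")
            positions.append(1 + g * 1_000_000 + len(positions) * 10)
    variants = pd.DataFrame(
        {"chrom": "1", "pos": positions, "ref": "A", "alt": "T", "gene": genes}
    )
    samples = np.array([f"S{i:06d}" for i in range(n)])
    return GenotypeBlock(samples, np.column_stack(cols), variants)


def simulate_annotations(
    block: GenotypeBlock, config: SimulationConfig, causal=None, rng=None,
    coding_probs=(0.10, 0.15, 0.35, 0.30, 0.10),
) -> pd.DataFrame:
    """FAVOR-style annotation table for a simulated block.

    Coding categories are drawn per variant with probabilities
    (pLoF, DS, missense, synonymous, none); channel scores are PHRED-scaled
    draws (Gamma-shaped, as empirical PHRED scores are), shifted upward by
    `annotation_shift` at causal variants so that annotation weighting has
    signal to find.
    """
    rng = rng or _rng(config, 2)
    m = block.n_variants
    cats = rng.choice(
        ["pLoF", "DS", "missense", "synonymous", "none"], size=m, p=list(coding_probs)
    )
    gene = (
        block.variants["gene"].to_numpy()
        if "gene" in block.variants
        else np.repeat("GENE0000", m)
    )
    df = block.variants[["chrom", "pos", "ref", "alt"]].copy()
    df["gene"] = gene
    df["coding_category"] = cats
    df["noncoding_categories"] = np.where(cats == "none", "upstream", "")
    df["is_ncRNA"] = 0
    shift = np.zeros(m)
    if causal is not None:
        shift[np.asarray(causal)] = config.annotation_shift
    for ch in ANNOTATION_CHANNELS:
        df[ch] = np.round(rng.gamma(2.0, 4.0, size=m) + shift, 3)
    df.index = pd.Index(block.keys, name="key")
    return df


def _calibrate_intercept(eta_no_const: np.ndarray, prevalence: float) -> float:
    """Bisection for the intercept making mean expit(b0 + eta) == prevalence."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        p = 1.0 / (1.0 + np.exp(-(mid + eta_no_const)))
        if p.mean() < prevalence:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return (lo + hi) / 2.0


def _covariates(config: SimulationConfig, n: int, rng) -> pd.DataFrame:
    cov = {}
    for name, dist, _beta in config.covariate_effects:
        if dist == "bernoulli":
            cov[name] = rng.integers(0, 2, size=n).astype(float)
        elif dist == "normal":
            cov[name] = rng.standard_normal(n)
        else:
            raise ValueError(f"unknown covariate distribution {dist!r}")
    return pd.DataFrame(cov)


def simulate_phenotype(
    block: GenotypeBlock, config: SimulationConfig, beta=None, rng=None
) -> pd.DataFrame:
    """Binary trait from logit P(Y=1) = b0 + X gamma + G beta.

    `beta` (per-variant log-odds) defaults to the config effect spec: a
    `causal_fraction` of variants per gene get `effect_size`. b0 is
    calibrated by bisection so the expected prevalence hits the target.
    Returns the phenotype table (sample_id, outcome, covariates).
    """
    rng = rng or _rng(config, 1)
    n = block.n_samples
    X = _covariates(config, n, rng)
    eta = sum(
        float(b) * X[name].to_numpy() for name, _d, b in config.covariate_effects
    )
    if beta is None:
        beta = np.zeros(block.n_variants)
        if config.causal_fraction > 0 and config.effect_size != 0:
            caus = rng.random(block.n_variants) < config.causal_fraction
            beta[caus] = config.effect_size
    beta = np.asarray(beta, dtype=float)
    if np.any(beta != 0):
        G = np.nan_to_num(block.dosage, nan=0.0)
        eta = eta + G @ beta
    b0 = _calibrate_intercept(eta, config.prevalence)
    p = 1.0 / (1.0 + np.exp(-(b0 + eta)))
    y = rng.binomial(1, p)
    out = pd.DataFrame({"sample_id": block.samples, "outcome": y})
    return pd.concat([out, X], axis=1)


# --------------------------------------------------------------------------
# pathological fixtures
# --------------------------------------------------------------------------


@dataclass
class Fixture:
    """A synthetic gene with its genotypes, annotations and aligned phenotype."""

    name: str
    block: GenotypeBlock
    annotations: pd.DataFrame
    phenotype: pd.DataFrame
    covariate_names: list
    notes: dict = field(default_factory=dict)

    def validate(self) -> None:
        mac, _, _ = compute_mac_maf(self.block)
        expect = self.notes.get("macs")
        if expect is not None and sorted(mac.tolist()) != sorted(expect):
            raise AssertionError(f"{self.name}: realized MACs {mac} != planted {expect}")


def _fixture_phenotype(n: int, rng, prevalence=0.37):
    """Covariate-driven binary trait with a wide spread of fitted risks.

    The strong continuous covariate gives some cases a very low
    covariate-predicted risk; planting rare alleles on those individuals
    reproduces the 'extreme single-variant score' behaviour behind the
    pathological aggregates.
    """
    risk = rng.standard_normal(n)
    b0 = _calibrate_intercept(2.0 * risk, prevalence)
    p = 1.0 / (1.0 + np.exp(-(b0 + 2.0 * risk)))
    y = rng.binomial(1, p)
    return risk, p, y


def _plant(n, carriers, dosage_per_carrier=1):
    col = np.zeros(n)
    col[np.asarray(carriers)] = dosage_per_carrier
    return col


def _extreme_cases(y, p, k, exclude=()):
    """Indices of k cases with the lowest covariate-predicted risk."""
    cand = np.flatnonzero(y == 1)
    cand = cand[~np.isin(cand, list(exclude))]
    return cand[np.argsort(p[cand])[:k]]


def _typical_controls(y, p, k, rng, exclude=()):
    cand = np.flatnonzero((y == 0) & (p < np.quantile(p, 0.3)))
    cand = cand[~np.isin(cand, list(exclude))]
    return rng.choice(cand, size=k, replace=False)


def make_fixture(name: str, n_samples: int = 4000, seed: int = 0) -> Fixture:
    """Construct one of the named pathological aggregates (see module docs)."""
    if n_samples < 1000:
        raise ValueError("fixtures need n_samples >= 1000")
    rng = np.random.default_rng([seed % 2**31, 17])
    n = n_samples
    risk, p, y = _fixture_phenotype(n, rng)
    pheno = pd.DataFrame(
        {"sample_id": [f"S{i:06d}" for i in range(n)], "outcome": y, "risk": risk}
    )
    config = SimulationConfig(n_samples=n, seed=seed)

    if name == "ssna1_like":
        # 3 SNVs, MACs {1, 1, 12}; the first singleton sits in a case with an
        # extreme score and carries high conservation-channel scores
        extreme = _extreme_cases(y, p, 1)
        quiet_ctrl = _typical_controls(y, p, 1, rng, exclude=extreme)
        common_carriers = rng.choice(
            np.setdiff1d(np.arange(n), np.r_[extreme, quiet_ctrl]), 12, replace=False
        )
        cols = [
            _plant(n, extreme),
            _plant(n, quiet_ctrl),
            _plant(n, common_carriers),
        ]
        block = _block_from_columns(cols, gene_names=["SSNA1L"] * 3, samples=pheno.sample_id.to_numpy())
        ann = simulate_annotations(block, config, rng=np.random.default_rng([seed % 2**31, 18]))
        ann["coding_category"] = "DS"
        ann["noncoding_categories"] = ""
        # conservation channels load on the planted singleton
        for ch in [f"aPC{i}" for i in range(1, 10)]:
            ann.loc[block.keys[0], ch] = 25.0
        notes = {"macs": [1, 1, 12], "planted_singleton": 0}
    elif name == "lcnl1_like":
        # 2 SNVs, MACs {2, 9}: all ultra-rare, cMAC 11
        c1 = _extreme_cases(y, p, 2)
        c2 = rng.choice(np.setdiff1d(np.arange(n), c1), 9, replace=False)
        cols = [_plant(n, c1), _plant(n, c2)]
        block = _block_from_columns(cols, gene_names=["LCNL1L"] * 2, samples=pheno.sample_id.to_numpy())
        ann = simulate_annotations(block, config, rng=np.random.default_rng([seed % 2**31, 18]))
        ann["coding_category"] = ["pLoF", "DS"]
        ann["noncoding_categories"] = ""
        notes = {"macs": [2, 9]}
    elif name == "phlda1_like":
        # missense aggregate of 12 SNVs whose signal is 2 ultra-rare DS
        # variants (combined MAC 5) carried exclusively by extreme cases
        ds1 = _extreme_cases(y, p, 2)
        ds2 = _extreme_cases(y, p, 3, exclude=ds1)
        cols = [_plant(n, ds1), _plant(n, ds2)]
        used = np.r_[ds1, ds2]
        nullrng = np.random.default_rng([seed % 2**31, 19])
        for mac in (1, 2, 4, 6, 8, 9, 11, 12, 13, 15):
            carriers = nullrng.choice(np.setdiff1d(np.arange(n), used), mac, replace=False)
            cols.append(_plant(n, carriers))
        block = _block_from_columns(cols, gene_names=["PHLDA1L"] * len(cols), samples=pheno.sample_id.to_numpy())
        ann = simulate_annotations(block, config, rng=np.random.default_rng([seed % 2**31, 18]))
        ann["coding_category"] = ["DS", "DS"] + ["missense"] * 10
        ann["noncoding_categories"] = ""
        notes = {"macs": [2, 3, 1, 2, 4, 6, 8, 9, 11, 12, 13, 15], "ds_local": [0, 1]}
    elif name == "null_gene":
        grng = np.random.default_rng([seed % 2**31, 20])
        maf = _draw_maf(grng, DEFAULT_SPECTRUM, n, 8)
        cols = []
        for j in range(8):
            for _ in range(10):
                d = grng.binomial(2, maf[j], size=n).astype(float)
                if 0 < d.sum() < 2 * n:
                    break
            cols.append(d)
        block = _block_from_columns(cols, gene_names=["NULLG"] * 8, samples=pheno.sample_id.to_numpy())
        ann = simulate_annotations(block, config, rng=np.random.default_rng([seed % 2**31, 18]))
        ann["coding_category"] = "missense"
        ann["noncoding_categories"] = ""
        notes = {}
    else:
        raise ValueError(f"unknown fixture {name!r}")

    fx = Fixture(name, block, ann, pheno, ["risk"], notes)
    fx.validate()
    return fx


# --------------------------------------------------------------------------
# null calibration harness
# --------------------------------------------------------------------------


def _exact_binom_ci(k: int, n: int, level: float = 0.99):
    from scipy import stats as ss

    a = (1 - level) / 2
    lo = ss.beta.ppf(a, k, n - k + 1) if k > 0 else 0.0
    hi = ss.beta.ppf(1 - a, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def _cmac_band(cmac: int) -> str:
    if cmac < 10:
        return "cmac_lt10"
    if cmac < 20:
        return "cmac_10_19"
    return "cmac_ge20"


def type1_error_harness(
    config: SimulationConfig,
    alpha_list=(0.05, 0.01),
    n_replicates: int = 2000,
    channels=("aPC1", "CADD"),
) -> pd.DataFrame:
    """Empirical type-I error of the component tests and the omnibus.

    One null model is fitted to a covariates-only trait; `n_replicates`
    independent gene sets are then simulated and tested under both modes.
    Because p-values are mode-independent and only the pooling differs, the
    channel grid is computed once per set; the legacy omnibus pools every
    entry, the modified omnibus only the kept ones. Results are stratified
    by cMAC band, with an extra all-ultra-rare stratum (cMAC bands tally the
    set's total; the all-ultra-rare band collects sets where every variant
    is below the MAC threshold regardless of total cMAC).
    """
    if config.causal_fraction != 0 or config.effect_size != 0:
        raise ValueError("the null harness requires a no-effect config")
    acfg = AnalysisConfig(channels=list(channels))
    rng = _rng(config, 7)
    n = config.n_samples
    risk = rng.standard_normal(n)
    b0 = _calibrate_intercept(0.8 * risk, config.prevalence)
    mu_true = 1.0 / (1.0 + np.exp(-(b0 + 0.8 * risk)))
    y = rng.binomial(1, mu_true)
    pheno = pd.DataFrame(
        {"sample_id": [f"S{i:06d}" for i in range(n)], "outcome": y, "risk": risk}
    )
    model = fit_null_model(pheno, ["risk"], family="binary")

    lo, hi = config.variants_per_gene
    records = []
    for rep in range(n_replicates):
        m = int(rng.integers(lo, hi + 1))
        maf_t = _draw_maf(rng, config.maf_spectrum, n, m)
        G = rng.binomial(2, maf_t, size=(n, m)).astype(float)
        poly = (G.sum(0) > 0) & (G.sum(0) < 2 * n)
        if not poly.any():
            continue
        G = G[:, poly]
        m = G.shape[1]
        block = _block_from_columns(
            [G[:, j] for j in range(m)], gene_names=[f"R{rep}"] * m,
            samples=pheno.sample_id.to_numpy(),
        )
        ann = simulate_annotations(block, config, rng=rng)
        mac, maf, _ = compute_mac_maf(block)
        ok = maf < acfg.rare_maf_threshold
        if not ok.any():
            continue
        idx = np.flatnonzero(ok)
        vset = VariantSet(
            f"R{rep}", "missense", "1", idx, maf[idx], mac[idx], acfg.mac_threshold
        )
        stats = score_statistics(model, imputed_minor_dosage(block))
        grid = build_channel_grid(vset, stats, ann, block.keys, acfg, mode="modified")
        p_mod = staar_o(grid)
        p_leg = cauchy_combine(grid["p"].to_numpy())
        maf_only = grid[(grid.channel == "MAF_only") & (grid.a2 == 25.0)]
        rec = {
            "cmac_band": _cmac_band(int(mac[idx].sum())),
            "all_ultra_rare": bool(np.all(mac[idx] < acfg.mac_threshold)),
            "STAAR_O_modified": p_mod,
            "STAAR_O_legacy": p_leg,
        }
        for test in ("burden", "SKAT", "ACAT_V"):
            rec[test] = float(maf_only.loc[maf_only.test == test, "p"].iloc[0])
        records.append(rec)

    raw = pd.DataFrame(records)
    rows = []
    tests = ["burden", "SKAT", "ACAT_V", "STAAR_O_legacy", "STAAR_O_modified"]
    strata = ["all", "cmac_lt10", "cmac_10_19", "cmac_ge20", "all_ultra_rare"]
    for stratum in strata:
        if stratum == "all":
            sub = raw
        elif stratum == "all_ultra_rare":
            sub = raw[raw["all_ultra_rare"]]
        else:
            sub = raw[raw["cmac_band"] == stratum]
        for test in tests:
            for alpha in alpha_list:
                nn = len(sub)
                k = int((sub[test] <= alpha).sum())
                lo_, hi_ = _exact_binom_ci(k, nn) if nn else (0.0, 1.0)
                rows.append(
                    {
                        "stratum": stratum, "test": test, "alpha": alpha,
                        "n": nn, "rejections": k,
                        "rate": k / nn if nn else np.nan,
                        "ci99_low": lo_, "ci99_high": hi_,
                    }
                )
    table = pd.DataFrame(rows)
    table.attrs["raw"] = raw
    return table
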