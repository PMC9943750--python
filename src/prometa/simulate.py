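"""Synthetic GWAS study generator.

Emulates the statistical structure that the downstream pipeline assumes:
multi-cohort European-style GWAS of a log-transformed fasting biomarker
(proinsulin-like), block-structured LD with controllable decay, planted
causal effects shared or distinct across companion traits, cis-eQTL studies,
and annotation tracks with a planted enrichment of causal variants.

Genotypes are drawn through a Gaussian copula: each haplotype carries a
latent AR(1) Gaussian per LD block and an allele is present when the latent
falls below the quantile of the planted allele frequency. This gives
block-diagonal LD with exponential decay in the latent correlation, zero
correlation across blocks, and exact control of allele frequencies in
expectation.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LDPanel

_BASES = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]


def _stable_hash(text: str) -> int:
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class BlockSpec:
    """One LD block: variant count, planted MAF range, latent AR(1) decay."""

    n_variants: int
    maf_range: tuple[float, float]
    correlation_decay: float
    chrom: str = "1"

    def validate(self) -> None:
        if self.n_variants <= 0:
            raise ValueError("degenerate block: a block needs at least one variant")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.correlation_decay < 1):
            raise ValueError("correlation_decay must be in [0, 1)")


@dataclass(frozen=True)
class CausalEffect:
    """A planted per-allele effect of one variant on one trait."""

    marker: str
    trait: str
    beta: float


@dataclass
class SimulationScenario:
    """Study conditions for a multi-cohort GWAS simulation.

    Defaults mirror the emulated study design: 16 European-ancestry cohorts
    totalling 45,861 individuals, with the two largest cohorts (METSIM- and
    Fenland-sized) contributing 10,070 and 8,925 samples. Traits are modelled
    on the residual scale (unit-variance after adjustment), so planted betas
    are in trait-SD-per-allele units.
    """

    n_cohorts: int = 16
    cohort_sizes: Sequence[int] = field(
        default_factory=lambda: (
            10070, 8925, 3500, 3200, 2900, 2600, 2300, 2000,
            1800, 1600, 1500, 1300, 1200, 1100, 1000, 866,
        )
    )
    causal_config: Sequence[CausalEffect] = field(default_factory=tuple)
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.05, "sex": 0.1, "bmi": 0.1}
    )
    noise_sd: float | Sequence[float] = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cohort_sizes) != self.n_cohorts:
            raise ValueError("cohort_sizes must have n_cohorts entries")

    def betas_for(self, trait: str) -> dict[str, float]:
        return {c.marker: c.beta for c in self.causal_config if c.trait == trait}

    def cohort_noise_sd(self, cohort: int) -> float:
        if np.isscalar(self.noise_sd):
            return float(self.noise_sd)  # type: ignore[arg-type]
        return float(self.noise_sd[cohort])  # type: ignore[index]


class HaplotypePanel(LDPanel):
    """Simulated genotype panel that remembers its generative block structure.

    ``resample`` draws a fresh sample of individuals from the same generative
    model (same variants, planted MAFs, and LD), which is how independent
    cohorts and external LD reference panels are produced.
    """

    def __init__(
        self,
        dosages: np.ndarray,
        variant_meta: pd.DataFrame,
        block_specs: Sequence[BlockSpec],
        block_map: np.ndarray,
        source: str = "panel",
        sample_ids: Sequence[str] | None = None,
    ) -> None:
        super().__init__(dosages, variant_meta, source=source, sample_ids=sample_ids)
        self.block_specs = tuple(block_specs)
        self.block_map = np.asarray(block_map, dtype=int)

    def resample(self, n_samples: int, seed: int, source: str | None = None) -> "HaplotypePanel":
        rng = np.random.default_rng(seed)
        dos = _draw_dosages(
            n_samples,
            self.block_specs,
            self.variant_meta["planted_maf"].to_numpy(),
            self.block_map,
            rng,
        )
        return HaplotypePanel(
            dos,
            self.variant_meta.copy(),
            self.block_specs,
            self.block_map,
            source=source or f"{self.source}_resample",
        )


def _draw_dosages(
    n_samples: int,
    blocks: Sequence[BlockSpec],
    mafs: np.ndarray,
    block_map: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Two independent copula haplotypes per sample, summed to dosage."""
    n_variants = len(mafs)
    out = np.zeros((n_samples, n_variants), dtype=np.int8)
    thresh = stats.norm.ppf(mafs)
    for b, spec in enumerate(blocks):
        cols = np.flatnonzero(block_map == b)
        m = len(cols)
        rho = spec.correlation_decay
        for _hap in range(2):
            z = np.empty((n_samples, m))
            eps = rng.standard_normal((n_samples, m))
            z[:, 0] = eps[:, 0]
            if rho > 0:
                scale = np.sqrt(1.0 - rho**2)
                for j in range(1, m):
                    z[:, j] = rho * z[:, j - 1] + scale * eps[:, j]
            else:
                z[:, 1:] = eps[:, 1:]
            out[:, cols] += (z < thresh[cols]).astype(np.int8)
    return out


def simulate_ld_panel(
    n_samples: int,
    blocks: Sequence[BlockSpec | tuple],
    seed: int,
    spacing: int = 2000,
    block_gap: int = 2_000_000,
    start_pos: int = 1_000_000,
    source: str = "sim",
) -> HaplotypePanel:
    """Simulate a genotype panel with block-diagonal LD.

    Blocks may be ``BlockSpec`` instances or plain
    ``(n_variants, maf_range, correlation_decay)`` tuples. Variants within a
    block are ``spacing`` bp apart; consecutive blocks on the same chromosome
    are separated by ``block_gap`` bp so they form distinct loci.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    specs = [b if isinstance(b, BlockSpec) else BlockSpec(*b) for b in blocks]
    if not specs:
        raise ValueError("at least one block is required")
    for s in specs:
        s.validate()
    rng = np.random.default_rng(seed)

    rows = []
    block_map = []
    pos = start_pos
    prev_chrom: str | None = None
    for b, spec in enumerate(specs):
        if prev_chrom == spec.chrom:
            pos += block_gap
        else:
            pos = start_pos
        lo, hi = spec.maf_range
        mafs = rng.uniform(lo, hi, size=spec.n_variants)
        for j in range(spec.n_variants):
            ref, alt = _BASES[rng.integers(len(_BASES))]
            rows.append(
                {
                    "marker": f"rs{spec.chrom}_{pos}",
                    "chr": spec.chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "planted_maf": mafs[j],
                    "block": b,
                }
            )
            block_map.append(b)
            pos += spacing
        prev_chrom = spec.chrom
    meta = pd.DataFrame(rows)
    block_map = np.array(block_map)
    dosages = _draw_dosages(
        n_samples, specs, meta["planted_maf"].to_numpy(), block_map, rng
    )
    return HaplotypePanel(dosages, meta, specs, block_map, source=source)


# ---------------------------------------------------------------------------
# covariates and phenotypes
# ---------------------------------------------------------------------------

def simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Age/sex/BMI-like covariate table standing in for structure adjustment."""
    return pd.DataFrame(
        {
            "age": rng.normal(55.0, 8.0, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "bmi": rng.normal(27.0, 4.0, n),
        }
    )


def simulate_phenotype(
    panel: HaplotypePanel,
    scenario: SimulationScenario,
    trait: str,
    rng: np.random.Generator | None = None,
    covariates: pd.DataFrame | None = None,
    noise_sd: float | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Additive genetic trait: sum of planted effects + covariates + noise.

    Returns the raw trait values and the covariate table used (so callers can
    re-run the two-step adjustment).
    """
    if rng is None:
        rng = np.random.default_rng([scenario.seed, _stable_hash(trait)])
    betas = scenario.betas_for(trait)
    missing = [m for m in betas if not panel.has(m)]
    if missing:
        raise ValueError(f"causal variants absent from panel: {missing}")
    n = panel.n_samples
    if covariates is None:
        covariates = simulate_covariates(n, rng)
    if noise_sd is None:
        noise_sd = (
            float(scenario.noise_sd)
            if np.isscalar(scenario.noise_sd)
            else float(scenario.noise_sd[0])  # type: ignore[index]
        )
    y = rng.normal(0.0, noise_sd, n)
    for marker, beta in betas.items():
        y = y + beta * panel.dosages[:, panel.idx(marker)[0]].astype(float)
    for name, eff in scenario.covariate_effects.items():
        if eff and name in covariates:
            col = covariates[name].to_numpy(float)
            sd = col.std()
            if sd > 0:
                y = y + eff * (col - col.mean()) / sd
    return y, covariates


def inverse_normal_transform(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offset (r-3/8)/(n+1/4).

    Ties receive the average rank.
    """
    x = np.asarray(x, dtype=float)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (len(x) + 0.25))


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def two_step_adjust(
    trait: np.ndarray | pd.Series, covariates: pd.DataFrame
) -> pd.Series:
    """Two-step covariate adjustment for low-frequency-variant robustness.

    Step 1 residualizes the trait on the covariates, the residuals are
    inverse-normal transformed (Blom), and step 2 residualizes the transformed
    values on the covariates again. Rows with missing covariate cells are
    dropped; constant covariate columns are dropped with a warning.
    """
    y = pd.Series(np.asarray(trait, dtype=float))
    cov = covariates.reset_index(drop=True).astype(float)
    if len(cov) != len(y):
        raise ValueError("trait and covariates must have the same length")
    ok = ~cov.isna().any(axis=1) & y.notna()
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} rows with missing values")
    y = y[ok]
    cov = cov.loc[ok]
    keep_cols = []
    for c in cov.columns:
        if cov[c].nunique() <= 1:
            warnings.warn(f"dropping constant covariate column {c!r}")
        else:
            keep_cols.append(c)
    X = cov[keep_cols].to_numpy() if keep_cols else np.empty((len(y), 0))
    step1 = _residualize(y.to_numpy(), X)
    transformed = inverse_normal_transform(step1)
    final = _residualize(transformed, X)
    return pd.Series(final, index=y.index)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

SUMSTAT_COLUMNS = [
    "MARKER", "CHR", "POS", "EA", "NEA", "EAF", "BETA", "SE", "P", "N",
    "INFO", "HWE_P", "CALLRATE",
]


def marginal_ols(y: np.ndarray, dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant simple-regression beta, SE, and two-sided normal p.

    Monomorphic variants get NaN beta/SE and p = 1.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    g = dosages.astype(float)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc**2).sum(axis=0)
    sxy = gc.T @ yc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        sigma2 = np.maximum(syy - beta * sxy, 0.0) / max(n - 2, 1)
        se = np.sqrt(sigma2 / sxx)
        z = beta / se
    mono = sxx == 0
    beta[mono] = np.nan
    se[mono] = np.nan
    z = np.where(np.isfinite(z), z, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[mono] = 1.0
    return beta, se, p


def simulate_cohort_sumstats(
    panel: HaplotypePanel,
    scenario: SimulationScenario,
    trait: str,
    cohort: int = 0,
    n_samples: int | None = None,
    resample: bool = True,
    seed: int | None = None,
) -> pd.DataFrame:
    """One cohort's GWAS summary statistics for ``trait``.

    A fresh cohort of ``scenario.cohort_sizes[cohort]`` individuals is drawn
    from the panel's generative model (``resample=False`` reuses the panel's
    own samples, which is what exact-OLS oracle comparisons need). The
    adjusted residuals from :func:`two_step_adjust` are regressed on each
    variant's dosage. Imputation-quality, HWE, and call-rate columns are drawn
    independently of the genotypes: they exist to exercise QC filters.
    """
    if seed is None:
        seed = int(
            np.random.default_rng(
                [scenario.seed, _stable_hash(trait), cohort]
            ).integers(2**31)
        )
    rng = np.random.default_rng(seed)
    if resample:
        size = n_samples or scenario.cohort_sizes[cohort]
        cohort_panel = panel.resample(size, seed=int(rng.integers(2**31)),
                                      source=f"cohort{cohort}")
    else:
        cohort_panel = panel
    y, cov = simulate_phenotype(
        panel=cohort_panel,
        scenario=scenario,
        trait=trait,
        rng=rng,
        noise_sd=scenario.cohort_noise_sd(cohort),
    )
    adj = two_step_adjust(y, cov).to_numpy()
    beta, se, p = marginal_ols(adj, cohort_panel.dosages)
    n = cohort_panel.n_samples
    meta = cohort_panel.variant_meta
    return pd.DataFrame(
        {
            "MARKER": meta["marker"],
            "CHR": meta["chr"],
            "POS": meta["pos"],
            "EA": meta["alt"],
            "NEA": meta["ref"],
            "EAF": cohort_panel.freqs(),
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": n,
            "INFO": rng.uniform(0.75, 1.0, len(meta)),
            "HWE_P": rng.uniform(0.0, 1.0, len(meta)),
            "CALLRATE": rng.uniform(0.97, 1.0, len(meta)),
        }
    )


@dataclass(frozen=True)
class GeneConfig:
    """A cis-eQTL study configuration for one gene."""

    gene: str
    causal_marker: str
    beta: float = 0.8
    n_samples: int = 420
    noise_sd: float = 1.0
    mode: str = "shared"  # shared | distinct | null; bookkeeping label only


def simulate_eqtl_sumstats(
    panel: HaplotypePanel, gene_config: GeneConfig, seed: int
) -> pd.DataFrame:
    """Cis-window eQTL summary statistics with one planted causal variant.

    Whether the planted eQTL variant is shared with or distinct from a trait's
    causal variant is the caller's choice of ``causal_marker``; the ``mode``
    label records intent for truth-known testing. ``beta=0`` gives a null
    gene.
    """
    cfg = gene_config
    if cfg.beta != 0 and not panel.has(cfg.causal_marker):
        raise ValueError(f"causal variant {cfg.causal_marker!r} absent from panel")
    rng = np.random.default_rng(seed)
    study = panel.resample(cfg.n_samples, seed=int(rng.integers(2**31)),
                           source=f"eqtl_{cfg.gene}")
    expr = rng.normal(0.0, cfg.noise_sd, cfg.n_samples)
    if cfg.beta != 0:
        expr = expr + cfg.beta * study.dosages[:, study.idx(cfg.causal_marker)[0]]
    beta, se, p = marginal_ols(expr, study.dosages)
    meta = study.variant_meta
    out = pd.DataFrame(
        {
            "GENE": cfg.gene,
            "MARKER": meta["marker"],
            "CHR": meta["chr"],
            "POS": meta["pos"],
            "EA": meta["alt"],
            "NEA": meta["ref"],
            "EAF": study.freqs(),
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": cfg.n_samples,
        }
    )
    return out


# ---------------------------------------------------------------------------
# annotations and gene maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentConfig:
    """Planted annotation enrichment.

    ``fold`` is the target ratio between a causal index variant's probability
    of overlapping the annotation (itself or an r^2 > 0.8 proxy, the estimand
    of matched-control enrichment tests) and the same probability for a
    background variant with the same number of proxies.
    """

    fold: float = 1.0
    width: int = 400
    background_fraction: float = 0.05
    causal_markers: tuple[str, ...] = ()
    proxy_r2: float = 0.8

    def validate(self) -> None:
        if self.fold < 1:
            raise ValueError("fold must be >= 1")
        if not (0 < self.background_fraction <= 1):
            raise ValueError("background_fraction must be in (0, 1]")


def simulate_annotations(
    panel: HaplotypePanel,
    enrichment_config: EnrichmentConfig,
    seed: int,
) -> tuple[pd.DataFrame, float]:
    """BED intervals with causal variants covered at ``fold`` x background.

    The genome is tiled with ``width``-bp bins centred on variant positions;
    background bins switch on with probability ``background_fraction``. For
    each causal index, overlap (of the index or any of its proxies) is forced
    on with probability ``fold * q_b`` — where ``q_b`` is the background
    proxy-inclusive overlap probability for that index — or forced entirely
    off otherwise. Returns the BED table (0-based half-open) and the realized
    background coverage fraction.
    """
    cfg = enrichment_config
    cfg.validate()
    rng = np.random.default_rng(seed)
    meta = panel.variant_meta
    bg = cfg.background_fraction
    half = cfg.width // 2

    causal = set(cfg.causal_markers)
    proxy_sets: dict[str, list[str]] = {
        m: panel.proxies(m, cfg.proxy_r2) for m in causal
    }
    protected = set(causal)
    for plist in proxy_sets.values():
        protected.update(plist)

    covered = np.zeros(panel.n_variants, dtype=bool)
    is_protected = meta["marker"].isin(protected).to_numpy()
    covered[~is_protected] = rng.random((~is_protected).sum()) < bg

    pos_of = dict(zip(meta["marker"], zip(meta["chr"], meta["pos"])))
    midx = {m: i for i, m in enumerate(meta["marker"])}
    for m in sorted(causal):
        k = len(proxy_sets[m])
        q_b = 1.0 - (1.0 - bg) ** (k + 1)
        q_s = min(cfg.fold * q_b, 1.0)
        if rng.random() < q_s:
            covered[midx[m]] = True
        # uncovered draw: index and proxies stay off (initialized off)

    rows = []
    for i in np.flatnonzero(covered):
        chrom, pos = meta["chr"].iloc[i], int(meta["pos"].iloc[i])
        rows.append({"chrom": chrom, "start": max(pos - 1 - half, 0),
                     "end": pos - 1 + half + 1})
    bed = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    realized_bg = float(covered[~is_protected].mean()) if (~is_protected).any() else float(covered.mean())
    return bed, realized_bg


def simulate_gene_map(
    panel: HaplotypePanel, n_genes: int, seed: int, gene_length: int = 20_000
) -> pd.DataFrame:
    """Random gene intervals spanning the panel's coordinate range (BED-like)."""
    rng = np.random.default_rng(seed)
    rows = []
    g = 0
    for chrom, grp in panel.variant_meta.groupby("chr", sort=True):
        lo, hi = int(grp["pos"].min()), int(grp["pos"].max())
        n_here = max(1, int(round(n_genes * len(grp) / panel.n_variants)))
        starts = np.sort(rng.integers(max(lo - 100_000, 0), hi + 100_000, n_here))
        for s in starts:
            rows.append({"chrom": chrom, "start": int(s),
                         "end": int(s) + gene_length, "name": f"GENE{g}"})
            g += 1
    return pd.DataFrame(rows)
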