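"""Summary-data Mendelian randomization and the HEIDI heterogeneity test.

SMR uses the top cis-eQTL variant as an instrument for gene expression:
b_xy = b_zy / b_zx estimates the trait change per unit expression, and
T_SMR = z_zy^2 z_zx^2 / (z_zy^2 + z_zx^2) is referred to chi-square_1.
HEIDI asks whether the b_xy estimates from other cis-SNPs in LD with the
top variant agree with the top variant's estimate: a single shared causal
variant (pleiotropy) predicts agreement, two linked causal variants predict
heterogeneity. The HEIDI statistic is the sum of squared standardized
deviations d_i = b_xy(i) - b_xy(top), whose null distribution is a weighted
sum of chi-square_1 (eigenvalues of the correlation matrix of d), evaluated
by Imhof numerical integration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .ld import LDPanel

DEFAULT_BONFERRONI_P = 0.0029  # 0.05 / 17 tested genes, recomputable
HEIDI_ELIGIBILITY_P = 1.57e-3  # eQTL chi-square_1 > 10
HEIDI_LD_WINDOW = (0.05, 0.9)
HEIDI_MAX_SNPS = 20


@dataclass
class SMRResult:
    gene: str
    top_marker: str
    b_xy: float
    se_xy: float
    p_smr: float
    p_heidi: float | None = None
    n_heidi_snps: int = 0
    passes_bonferroni: bool = False
    heidi_reason: str = ""


def smr_test(
    b_zy: float,
    se_zy: float,
    b_zx: float,
    se_zx: float,
    gene: str = "",
    top_marker: str = "",
    bonferroni_p: float | None = None,
    n_genes_tested: int | None = None,
) -> SMRResult:
    """Single-instrument SMR at the top cis-eQTL variant.

    The Bonferroni threshold defaults to 0.0029 and is recomputed as
    0.05 / ``n_genes_tested`` when a gene count is supplied.
    """
    if b_zx == 0:
        raise ValueError("b_zx = 0: no instrument")
    z_zy = b_zy / se_zy
    z_zx = b_zx / se_zx
    denom = z_zy**2 + z_zx**2
    t_smr = (z_zy**2 * z_zx**2) / denom if denom > 0 else 0.0
    p_smr = float(stats.chi2.sf(t_smr, df=1)) if t_smr > 0 else 1.0
    b_xy = b_zy / b_zx
    var_xy = se_zy**2 / b_zx**2 + b_zy**2 * se_zx**2 / b_zx**4
    thresh = bonferroni_p
    if thresh is None:
        thresh = 0.05 / n_genes_tested if n_genes_tested else DEFAULT_BONFERRONI_P
    return SMRResult(
        gene=gene, top_marker=top_marker, b_xy=b_xy, se_xy=float(np.sqrt(var_xy)),
        p_smr=p_smr, passes_bonferroni=bool(p_smr < thresh),
    )


def imhof_sf(q: float, lambdas: np.ndarray) -> float:
    """Upper tail P(Q > q) of Q = sum lambda_k chi^2_1 by Imhof integration."""
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0

    def integrand(u: float) -> float:
        theta = 0.5 * float(np.sum(np.arctan(lam * u))) - 0.5 * q * u
        rho = float(np.prod((1.0 + (lam * u) ** 2) ** 0.25))
        return np.sin(theta) / (u * rho)

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 1e-9, np.inf, limit=400)
    p = 0.5 + val / np.pi
    return float(min(max(p, 1e-300), 1.0))


def heidi_test(
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    panel: LDPanel,
    top: str,
    eligibility_p: float = HEIDI_ELIGIBILITY_P,
    ld_window: tuple[float, float] = HEIDI_LD_WINDOW,
    max_snps: int = HEIDI_MAX_SNPS,
) -> tuple[float | None, int, str]:
    """HEIDI test for heterogeneity of b_xy across cis-SNPs.

    ``gwas`` and ``eqtl`` are summary tables (MARKER, BETA, SE) over a shared
    cis-window. Eligible SNPs have eQTL p below ``eligibility_p`` and LD r^2
    with the top variant inside ``ld_window`` (avoiding both collinearity and
    independence); at most ``max_snps`` (strongest eQTL first) are used.
    Returns (p_heidi, n_snps, reason) with p_heidi None when fewer than 3
    SNPs are eligible.
    """
    merged = gwas.merge(eqtl, on="MARKER", suffixes=("_zy", "_zx"))
    merged = merged[
        np.isfinite(merged["BETA_zy"]) & np.isfinite(merged["BETA_zx"])
        & (merged["SE_zy"] > 0) & (merged["SE_zx"] > 0)
    ].reset_index(drop=True)
    if top not in set(merged["MARKER"]):
        return None, 0, "top variant missing from the merged cis-window"
    if not panel.has(top):
        return None, 0, "top variant missing from LD panel"

    z_zx = merged["BETA_zx"] / merged["SE_zx"]
    p_zx = 2.0 * stats.norm.sf(np.abs(z_zx))
    r2_top = panel.r2_with(top)
    r2 = merged["MARKER"].map(lambda m: r2_top.get(m, np.nan))
    lo, hi = ld_window
    eligible = merged[
        (merged["MARKER"] != top)
        & (p_zx < eligibility_p)
        & (r2 >= lo) & (r2 <= hi)
    ].copy()
    eligible["_pzx"] = p_zx[eligible.index]
    eligible = eligible.sort_values(["_pzx", "MARKER"]).head(max_snps)
    m = len(eligible)
    if m < 3:
        return None, m, "insufficient instruments"

    top_row = merged[merged["MARKER"] == top].iloc[0]
    snps = [top] + list(eligible["MARKER"])
    R = panel.corr(snps)  # signed correlations; index 0 is the top variant
    u = np.concatenate([[top_row["BETA_zy"]], eligible["BETA_zy"].to_numpy()])
    su = np.concatenate([[top_row["SE_zy"]], eligible["SE_zy"].to_numpy()])
    v = np.concatenate([[top_row["BETA_zx"]], eligible["BETA_zx"].to_numpy()])
    sv = np.concatenate([[top_row["SE_zx"]], eligible["SE_zx"].to_numpy()])

    # delta-method covariance of g_i = u_i / v_i across SNPs (GWAS and eQTL
    # errors independent; within-study errors correlated through LD)
    cov_u = R * np.outer(su, su)
    cov_v = R * np.outer(sv, sv)
    G = cov_u / np.outer(v, v) + np.outer(u, u) * cov_v / np.outer(v**2, v**2)

    g = u / v
    d = g[1:] - g[0]
    # cov(d_i, d_j) = G_ij - G_i0 - G_j0 + G_00
    C = G[1:, 1:] - G[1:, [0]] - G[[0], 1:] + G[0, 0]
    sd = np.sqrt(np.diag(C))
    if np.any(sd <= 0):
        return None, m, "degenerate deviation variance"
    zd = d / sd
    t_heidi = float(zd @ zd)
    corr_d = C / np.outer(sd, sd)
    lam = np.linalg.eigvalsh(corr_d)
    p = imhof_sf(t_heidi, lam)
    return p, m, ""


def smr_with_heidi(
    gwas: pd.DataFrame,
    eqtl: pd.DataFrame,
    panel: LDPanel,
    gene: str,
    instrument_p: float = 5e-8,
    bonferroni_p: float | None = None,
    n_genes_tested: int | None = None,
) -> SMRResult:
    """SMR at the strongest eligible cis-eQTL variant, then HEIDI.

    The instrument is the smallest-p eQTL variant present in both tables; it
    must reach ``instrument_p`` in the eQTL study.
    """
    merged = gwas.merge(eqtl, on="MARKER", suffixes=("_zy", "_zx"))
    merged = merged[
        np.isfinite(merged["BETA_zy"]) & np.isfinite(merged["BETA_zx"])
        & (merged["SE_zy"] > 0) & (merged["SE_zx"] > 0)
    ].reset_index(drop=True)
    if merged.empty:
        raise ValueError("no shared variants between trait and eQTL tables")
    z_zx = merged["BETA_zx"] / merged["SE_zx"]
    p_zx = 2.0 * stats.norm.sf(np.abs(z_zx))
    i_top = int(np.argmin(p_zx))
    if p_zx[i_top] >= instrument_p:
        raise ValueError(
            f"top cis-eQTL p {p_zx[i_top]:.2e} does not reach the instrument "
            f"threshold {instrument_p:g}"
        )
    row = merged.iloc[i_top]
    res = smr_test(
        b_zy=float(row["BETA_zy"]), se_zy=float(row["SE_zy"]),
        b_zx=float(row["BETA_zx"]), se_zx=float(row["SE_zx"]),
        gene=gene, top_marker=str(row["MARKER"]),
        bonferroni_p=bonferroni_p, n_genes_tested=n_genes_tested,
    )
    p_heidi, n_snps, reason = heidi_test(gwas, eqtl, panel, res.top_marker)
    res.p_heidi = p_heidi
    res.n_heidi_snps = n_snps
    res.heidi_reason = reason
    return res


def smr_table(results: list[SMRResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "top_marker": [r.top_marker for r in results],
            "b_xy": [r.b_xy for r in results],
            "se_xy": [r.se_xy for r in results],
            "p_smr": [r.p_smr for r in results],
            "p_heidi": [r.p_heidi for r in results],
            "n_heidi_snps": [r.n_heidi_snps for r in results],
            "passes_bonferroni": [r.passes_bonferroni for r in results],
        }
    )
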