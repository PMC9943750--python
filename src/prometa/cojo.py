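"""Approximate conditional/joint analysis from summary statistics.

Implements stepwise model selection in the COJO style: the joint model's
normal equations are assembled from an external panel's dosage correlations
and variances together with the marginal effect sizes, so that with the
panel equal to the generating sample the joint solution reproduces exact
multiple-regression OLS. Also provides the multi-panel consensus rule and
the MAF-consistency screen used to vet signals found with external panels.

Notation: for selected variants S, B[j,k] = r_jk * sqrt(d_j d_k N_j N_k) with
d_j the panel dosage variance, and (X'y)_j = d_j N_j b_j from the marginal
beta; joint betas solve B beta = X'y. The phenotypic variance is taken as
the median across window variants of d_j N_j se_j^2 + d_j b_j^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LDPanel
from .meta import GENOME_WIDE_P


@dataclass
class Signal:
    """A conditionally distinct association signal."""

    marker: str
    locus: str
    beta: float
    se: float
    p: float
    bC: float
    bC_se: float
    pC: float
    panel_support: set[str] = field(default_factory=set)
    ld_with_primary: float = float("nan")


class _JointEngine:
    """Normal-equations assembly for one analysis window."""

    def __init__(self, window: pd.DataFrame, panel: LDPanel):
        w = window[np.isfinite(window["BETA"]) & np.isfinite(window["SE"])
                   & (window["SE"] > 0)].reset_index(drop=True)
        in_panel = w["MARKER"].map(panel.has).to_numpy(bool)
        coverage = in_panel.mean() if len(w) else 0.0
        if coverage < 0.95:
            warnings.warn(
                f"panel {panel.source!r} covers only {coverage:.0%} of window variants"
            )
        self.window = w.loc[in_panel].reset_index(drop=True)
        self.panel = panel
        self.markers = list(self.window["MARKER"])
        self.pos = {m: i for i, m in enumerate(self.markers)}
        self.b = self.window["BETA"].to_numpy(float)
        self.se = self.window["SE"].to_numpy(float)
        self.n = self.window["N"].to_numpy(float)
        self.d = panel.dosage_var(self.markers)
        ok = self.d > 0
        # monomorphic-in-panel variants cannot enter the joint model
        if not ok.all():
            self.window = self.window.loc[ok].reset_index(drop=True)
            self.markers = list(self.window["MARKER"])
            self.pos = {m: i for i, m in enumerate(self.markers)}
            self.b, self.se, self.n, self.d = (
                a[ok] for a in (self.b, self.se, self.n, self.d)
            )
        self.R = panel.corr(self.markers)
        # implied phenotypic variance per variant; median is robust to the
        # few variants with large effects
        self.s2y = float(np.median(self.d * self.n * self.se**2 + self.d * self.b**2))
        self.xy = self.d * self.n * self.b

    def _B(self, idx: np.ndarray) -> np.ndarray:
        scale = np.sqrt(self.d[idx] * self.n[idx])
        return self.R[np.ix_(idx, idx)] * np.outer(scale, scale)

    def joint_fit(self, markers: list[str]) -> pd.DataFrame:
        """Joint betas/SEs/p for a set of markers; raises LinAlgError if singular."""
        idx = np.array([self.pos[m] for m in markers], dtype=int)
        B = self._B(idx)
        xy = self.xy[idx]
        beta = np.linalg.solve(B, xy)
        n_eff = float(np.median(self.n[idx]))
        rss = self.s2y * n_eff - float(beta @ xy)
        dof = max(n_eff - len(idx) - 1, 1.0)
        sigma2 = max(rss / dof, 1e-12 * self.s2y)
        cov = sigma2 * np.linalg.inv(B)
        se = np.sqrt(np.diag(cov))
        z = beta / se
        return pd.DataFrame(
            {"MARKER": markers, "bJ": beta, "bJ_se": se,
             "pJ": 2.0 * stats.norm.sf(np.abs(z))}
        )

    def collinearity_r2(self, marker: str, selected: list[str]) -> float:
        """Multiple-regression R^2 of a candidate on the selected set."""
        if not selected:
            return 0.0
        i = self.pos[marker]
        idx = np.array([self.pos[m] for m in selected], dtype=int)
        r = self.R[i, idx]
        Rss = self.R[np.ix_(idx, idx)]
        try:
            return float(r @ np.linalg.solve(Rss, r))
        except np.linalg.LinAlgError:
            return 1.0


def cojo_select(
    meta_window: pd.DataFrame,
    panel: LDPanel,
    p_threshold: float = GENOME_WIDE_P,
    collinearity_r2: float = 0.8,
    max_signals: int = 3,
    locus: str = "",
) -> list[Signal]:
    """Stepwise forward selection of conditionally distinct signals.

    Seeds with the smallest-p variant, then repeatedly adds the variant with
    the smallest conditional p (its estimate in the joint model with the
    current selection) provided it is below ``p_threshold`` and its multiple
    regression r^2 on the selected set does not exceed ``collinearity_r2``.
    Stops at ``max_signals``. Conditional statistics for each reported signal
    come from the final joint fit (i.e. conditioning on all other selected
    signals); a lone signal keeps its marginal statistics.
    """
    eng = _JointEngine(meta_window, panel)
    if not eng.markers:
        return []
    order = np.lexsort(
        (eng.window["MARKER"], eng.se, eng.window["P"].to_numpy(float))
    )
    first = order[0]
    if eng.window["P"].iloc[first] >= p_threshold:
        return []
    selected = [eng.markers[first]]

    while len(selected) < max_signals:
        best_marker, best_p, best_fit = None, None, None
        for m in eng.markers:
            if m in selected:
                continue
            if eng.collinearity_r2(m, selected) > collinearity_r2:
                continue
            try:
                fit = eng.joint_fit(selected + [m])
            except np.linalg.LinAlgError:
                warnings.warn(f"singular joint model adding {m!r}; skipped")
                continue
            p_cond = float(fit["pJ"].iloc[-1])
            if best_p is None or p_cond < best_p or (
                p_cond == best_p and m < best_marker
            ):
                best_marker, best_p, best_fit = m, p_cond, fit
        if best_marker is None or best_p >= p_threshold:
            break
        selected.append(best_marker)

    primary = selected[0]
    signals: list[Signal] = []
    if len(selected) == 1:
        row = eng.window.iloc[eng.pos[primary]]
        signals.append(
            Signal(
                marker=primary, locus=locus,
                beta=float(row["BETA"]), se=float(row["SE"]), p=float(row["P"]),
                bC=float(row["BETA"]), bC_se=float(row["SE"]), pC=float(row["P"]),
                panel_support={panel.source}, ld_with_primary=1.0,
            )
        )
        return signals

    fit = eng.joint_fit(selected).set_index("MARKER")
    for m in selected:
        row = eng.window.iloc[eng.pos[m]]
        signals.append(
            Signal(
                marker=m, locus=locus,
                beta=float(row["BETA"]), se=float(row["SE"]), p=float(row["P"]),
                bC=float(fit.loc[m, "bJ"]), bC_se=float(fit.loc[m, "bJ_se"]),
                pC=float(fit.loc[m, "pJ"]),
                panel_support={panel.source},
                ld_with_primary=panel.r2(m, primary),
            )
        )
    return signals


def conditional_estimates(
    meta_window: pd.DataFrame,
    panel: LDPanel,
    conditioning: list[str],
    collinear_drop_r2: float = 0.99,
) -> pd.DataFrame:
    """Per-variant estimates conditional on a fixed set of signals.

    Each window variant is fitted jointly with the conditioning set and its
    own joint-model estimate reported. Variants nearly collinear with the
    conditioning set (r^2 > ``collinear_drop_r2``) are dropped.
    """
    eng = _JointEngine(meta_window, panel)
    cond = [m for m in conditioning if m in eng.pos]
    rows = []
    for m in eng.markers:
        if m in cond:
            continue
        if cond and eng.collinearity_r2(m, cond) > collinear_drop_r2:
            continue
        if not cond:
            row = eng.window.iloc[eng.pos[m]]
            rows.append({"MARKER": m, "bC": row["BETA"], "bC_se": row["SE"],
                         "pC": row["P"]})
            continue
        try:
            fit = eng.joint_fit(cond + [m])
        except np.linalg.LinAlgError:
            continue
        rows.append({"MARKER": m, "bC": float(fit["bJ"].iloc[-1]),
                     "bC_se": float(fit["bJ_se"].iloc[-1]),
                     "pC": float(fit["pJ"].iloc[-1])})
    return pd.DataFrame(rows, columns=["MARKER", "bC", "bC_se", "pC"])


# ---------------------------------------------------------------------------
# multi-panel consensus
# ---------------------------------------------------------------------------

def consensus_signals(
    per_panel: dict[str, list[Signal]],
    ld_source: LDPanel,
    proxy_r2: float = 0.8,
    min_panels: int = 2,
    max_signals: int = 3,
) -> list[Signal]:
    """Cross-panel consensus: keep signals found in >= 2 panels as proxies.

    Signals from different panels are grouped when their variants are proxies
    of each other (r^2 > ``proxy_r2`` in ``ld_source``, or the same variant).
    Groups supported by at least ``min_panels`` panels are accepted; the
    representative is the group member with the smallest conditional p. At
    most ``max_signals`` consensus signals are reported (smallest pC first).
    """
    if len(per_panel) < 2:
        raise ValueError("consensus requires results from at least 2 panels")
    entries: list[tuple[str, Signal]] = [
        (panel, s) for panel, sigs in per_panel.items() for s in sigs
    ]
    if not entries:
        return []
    markers = sorted({s.marker for _, s in entries})
    parent = {m: m for m in markers}

    def find(m: str) -> str:
        while parent[m] != m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m

    for i, a in enumerate(markers):
        for b in markers[i + 1:]:
            if a == b:
                continue
            if ld_source.has(a) and ld_source.has(b) and ld_source.r2(a, b) > proxy_r2:
                parent[find(a)] = find(b)

    groups: dict[str, list[tuple[str, Signal]]] = {}
    for panel, s in entries:
        groups.setdefault(find(s.marker), []).append((panel, s))

    accepted: list[Signal] = []
    for members in groups.values():
        support = {panel for panel, _ in members}
        if len(support) < min_panels:
            continue
        rep = min(members, key=lambda ps: (ps[1].pC, ps[1].marker))[1]
        accepted.append(replace(rep, panel_support=support))
    accepted.sort(key=lambda s: (s.pC, s.marker))
    return accepted[:max_signals]


# ---------------------------------------------------------------------------
# MAF consistency
# ---------------------------------------------------------------------------

@dataclass
class MafDecision:
    keep: bool
    reason: str
    panel_mafs: dict[str, float]


def maf_consistency(
    marker: str,
    meta_eaf: float,
    panels: list[LDPanel],
    tol: float = 0.05,
) -> MafDecision:
    """Exclude signals whose meta-analysis MAF disagrees with the panels.

    The signal is excluded when |meta MAF - panel MAF| > ``tol`` in a
    majority of the panels that contain the variant, or when no panel
    contains it at all.
    """
    meta_maf = min(meta_eaf, 1.0 - meta_eaf)
    mafs = {
        p.source: float(p.maf([marker])[0]) for p in panels if p.has(marker)
    }
    if not mafs:
        return MafDecision(False, "no panel frequency", {})
    n_discordant = sum(1 for v in mafs.values() if abs(meta_maf - v) > tol)
    if n_discordant > len(mafs) / 2:
        return MafDecision(
            False,
            f"meta MAF {meta_maf:.3f} inconsistent in {n_discordant}/{len(mafs)} panels",
            mafs,
        )
    return MafDecision(True, "consistent", mafs)


def signals_table(signals: list[Signal]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker": [s.marker for s in signals],
            "locus": [s.locus for s in signals],
            "beta": [s.beta for s in signals],
            "se": [s.se for s in signals],
            "p": [s.p for s in signals],
            "bC": [s.bC for s in signals],
            "bC_se": [s.bC_se for s in signals],
            "pC": [s.pC for s in signals],
            "ld_with_primary": [s.ld_with_primary for s in signals],
            "panel_support": [",".join(sorted(s.panel_support)) for s in signals],
        }
    )
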