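"""Approximate-Bayes-factor fine-mapping and extended credible sets.

Per-variant evidence is ln BF = z^2 / 2 (the proportionality constant cancels
under normalization), posteriors follow by log-domain normalization over the
analysis window (lead +/- 500 kb), and the 99% credible set is the smallest
posterior-ranked prefix reaching the coverage target. The extended credible
set additionally unions in every panel variant in high LD (r^2 >= 0.8 by
default) with the lead — capturing candidates absent from the meta-analysis —
flagged ``extension_only`` and carrying no posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .cojo import conditional_estimates
from .ld import LDPanel

MEMBER_COLUMNS = [
    "variant", "posterior", "cumulative", "in_bayesian_set",
    "extension_only", "r2_with_lead",
]


@dataclass
class CredibleSet:
    signal: str
    members: pd.DataFrame  # MEMBER_COLUMNS
    coverage: float = 0.99
    notes: list[str] = field(default_factory=list)

    @property
    def bayesian_size(self) -> int:
        return int(self.members["in_bayesian_set"].sum())

    @property
    def size(self) -> int:
        return int(
            (self.members["in_bayesian_set"] | self.members["extension_only"]).sum()
        )

    def variants(self) -> list[str]:
        m = self.members
        return list(m.loc[m["in_bayesian_set"] | m["extension_only"], "variant"])


def abf_posteriors(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Normalized single-causal posteriors from ln BF = 0.5 z^2."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if beta.size == 0:
        raise ValueError("empty window: no variants to fine-map")
    if np.any(se <= 0) or np.any(~np.isfinite(se)):
        raise ValueError("all standard errors must be finite and > 0")
    lnbf = 0.5 * (beta / se) ** 2
    return np.exp(lnbf - logsumexp(lnbf))


def credible_set(
    markers: list[str] | np.ndarray,
    posteriors: np.ndarray,
    coverage: float = 0.99,
    signal: str | None = None,
) -> CredibleSet:
    """Smallest posterior-ranked set reaching the coverage target.

    Variants are ranked by descending posterior with ties broken by marker
    name for determinism, and included until the cumulative posterior first
    reaches ``coverage``.
    """
    markers = np.asarray(markers)
    posteriors = np.asarray(posteriors, dtype=float)
    order = np.lexsort((markers, -posteriors))
    post = posteriors[order]
    cum = np.cumsum(post)
    n_in = int(np.searchsorted(cum, coverage - 1e-12) + 1)
    n_in = min(n_in, len(post))
    members = pd.DataFrame(
        {
            "variant": markers[order],
            "posterior": post,
            "cumulative": cum,
            "in_bayesian_set": np.arange(len(post)) < n_in,
            "extension_only": False,
            "r2_with_lead": np.nan,
        }
    )
    lead = signal if signal is not None else str(markers[order][0])
    return CredibleSet(signal=lead, members=members, coverage=coverage)


def finemap_window(
    window: pd.DataFrame, coverage: float = 0.99, signal: str | None = None
) -> CredibleSet:
    """ABF posteriors + credible set straight from a (BETA, SE) window table."""
    w = window[np.isfinite(window["BETA"]) & (window["SE"] > 0)]
    post = abf_posteriors(w["BETA"].to_numpy(), w["SE"].to_numpy())
    return credible_set(list(w["MARKER"]), post, coverage=coverage, signal=signal)


def conditional_credible_set(
    meta_window: pd.DataFrame,
    other_signals: list[str],
    panel: LDPanel,
    coverage: float = 0.99,
    signal: str | None = None,
) -> CredibleSet:
    """Credible set from statistics conditioned on the locus's other signals.

    For a single-signal locus (``other_signals`` empty) this reduces to the
    unconditional credible set.
    """
    cond = conditional_estimates(meta_window, panel, other_signals)
    if cond.empty:
        raise ValueError("no variants left after conditioning")
    post = abf_posteriors(cond["bC"].to_numpy(), cond["bC_se"].to_numpy())
    return credible_set(list(cond["MARKER"]), post, coverage=coverage, signal=signal)


def extend_credible_set(
    cs: CredibleSet,
    lead: str,
    panel: LDPanel,
    r2_threshold: float = 0.8,
    window: int = 500_000,
    strict: bool = False,
) -> CredibleSet:
    """Union the Bayesian set with the lead's high-LD proxies from the panel.

    Proxies (r^2 >= ``r2_threshold`` by default; ``strict`` switches to >)
    within ``window`` bp of the lead are added. Proxies missing from the
    scored window get ``extension_only`` and no posterior — these are exactly
    the variants the meta-analysis could not score. The lead being absent
    from the panel returns the set unchanged with a warning.
    """
    if not panel.has(lead):
        warnings.warn(f"lead {lead!r} absent from panel; extension skipped")
        out = CredibleSet(cs.signal, cs.members.copy(), cs.coverage,
                          cs.notes + ["lead absent from extension panel"])
        return out
    r2 = panel.r2_with(lead)
    lead_pos = int(panel.variant_meta.loc[panel.idx(lead)[0], "pos"])
    lead_chr = panel.variant_meta.loc[panel.idx(lead)[0], "chr"]
    meta_pos = panel.variant_meta.set_index("marker")
    members = cs.members.copy()
    known = set(members["variant"])
    sel = r2 > r2_threshold if strict else r2 >= r2_threshold
    new_rows = []
    for m in r2.index[sel]:
        row = meta_pos.loc[m]
        if row["chr"] != lead_chr or abs(int(row["pos"]) - lead_pos) > window:
            continue
        if m in known:
            continue
        new_rows.append(
            {"variant": m, "posterior": np.nan, "cumulative": np.nan,
             "in_bayesian_set": False, "extension_only": True,
             "r2_with_lead": float(r2[m])}
        )
    # annotate r2 with lead for existing members where the panel knows them
    members["r2_with_lead"] = [
        float(r2[v]) if v in r2.index else np.nan for v in members["variant"]
    ]
    if new_rows:
        members = pd.concat([members, pd.DataFrame(new_rows)], ignore_index=True)
    return CredibleSet(cs.signal, members, cs.coverage, list(cs.notes))


def credible_sets_table(sets: list[CredibleSet]) -> pd.DataFrame:
    frames = []
    for cs in sets:
        df = cs.members.copy()
        df.insert(0, "signal", cs.signal)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["signal"] + MEMBER_COLUMNS)
    return pd.concat(frames, ignore_index=True)
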