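"""Bayesian colocalization, sensitivity scoring, and direction consensus.

Pairwise colocalization is the standard five-hypothesis enumeration over
Wakefield approximate Bayes factors (H0 no association, H1/H2 one trait
only, H3 two distinct causal variants, H4 one shared causal variant) with
per-variant priors p1, p2 and shared prior p12. Multi-trait colocalization
follows the hierarchical single-causal-variant model: for every subset of
traits the evidence of a shared causal configuration (prior p1 * gamma^(m-1),
gamma the conditional colocalization prior) competes with independent causal
configurations (prior p1^m), and the posterior that the full trait set is
both regionally associated (PR) and aligned on one variant (PA) gives
PPFC = PR * PA. When the full set fails its thresholds the trait set is
divisively split — dropping the trait whose removal most improves PPFC —
and the largest colocalizing cluster is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import logsumexp

DEFAULT_PRIOR_SD_QUANT = 0.15
DEFAULT_PRIOR_SD_CC = 0.2


def trait_abf(
    beta: np.ndarray, se: np.ndarray, prior_sd: float = DEFAULT_PRIOR_SD_QUANT
) -> np.ndarray:
    """Per-variant log Wakefield approximate Bayes factors.

    ln ABF = 0.5 [ ln(se^2/(se^2+W)) + W z^2 / (se^2+W) ] with W = prior_sd^2.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be > 0")
    W = float(prior_sd) ** 2
    if W == 0:
        return np.zeros_like(beta)
    z2 = (beta / se) ** 2
    return 0.5 * (np.log(se**2 / (se**2 + W)) + W * z2 / (se**2 + W))


@dataclass
class ColocResult:
    locus: str
    traits: tuple[str, ...]
    posteriors: dict[str, float]
    candidate: str | None = None
    sensitivity_score: float = float("nan")
    lead_pair_r2: float = float("nan")
    decision: bool | None = None
    clusters: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def pp4(self) -> float:
        return self.posteriors.get("PP4", float("nan"))

    @property
    def ppfc(self) -> float:
        return self.posteriors.get("PPFC", float("nan"))


def _log1mexp(a: float) -> float:
    """log(1 - exp(a)) for a <= 0, stable near both ends."""
    if a >= 0:
        return -np.inf
    if a > -0.693:
        return float(np.log(-np.expm1(a)))
    return float(np.log1p(-np.exp(a)))


def coloc_pair(
    trait_a: pd.DataFrame,
    trait_b: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd_a: float = DEFAULT_PRIOR_SD_QUANT,
    prior_sd_b: float = DEFAULT_PRIOR_SD_QUANT,
    locus: str = "",
    labels: tuple[str, str] = ("traitA", "traitB"),
) -> ColocResult:
    """Five-hypothesis pairwise colocalization over shared variants.

    Inputs are summary tables with MARKER, BETA, SE; only variants present in
    both tables are used.
    """
    import warnings

    merged = trait_a.merge(trait_b, on="MARKER", suffixes=("_a", "_b"))
    merged = merged[
        np.isfinite(merged["BETA_a"]) & np.isfinite(merged["BETA_b"])
        & (merged["SE_a"] > 0) & (merged["SE_b"] > 0)
    ]
    n = len(merged)
    if n == 0:
        raise ValueError("no shared variants between the two traits")
    if n < 50:
        warnings.warn(f"only {n} shared variants; colocalization may be unstable")
    l1 = trait_abf(merged["BETA_a"].to_numpy(), merged["SE_a"].to_numpy(), prior_sd_a)
    l2 = trait_abf(merged["BETA_b"].to_numpy(), merged["SE_b"].to_numpy(), prior_sd_b)
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    lH = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            np.log(p1) + np.log(p2) + s1 + s2 + _log1mexp(min(s12 - s1 - s2, 0.0)),
            np.log(p12) + s12,
        ]
    )
    pp = np.exp(lH - logsumexp(lH))
    best = str(merged["MARKER"].iloc[int(np.argmax(l1 + l2))])
    return ColocResult(
        locus=locus,
        traits=labels,
        posteriors={f"PP{i}": float(pp[i]) for i in range(5)},
        candidate=best,
    )


# ---------------------------------------------------------------------------
# multi-trait colocalization
# ---------------------------------------------------------------------------

def _multi_masses(
    labfs: dict[str, np.ndarray], p1: float, gamma: float
) -> tuple[dict[frozenset, float], dict[frozenset, float]]:
    """Log evidence of aligned and non-aligned configs per trait subset."""
    traits = list(labfs)
    S_t = {t: float(logsumexp(labfs[t])) for t in traits}
    aligned: dict[frozenset, float] = {}
    non_aligned: dict[frozenset, float] = {}
    for m in range(1, len(traits) + 1):
        for combo in combinations(traits, m):
            key = frozenset(combo)
            stacked = np.sum([labfs[t] for t in combo], axis=0)
            sh = float(logsumexp(stacked))
            aligned[key] = np.log(p1) + (m - 1) * np.log(gamma) + sh
            if m >= 2:
                tot = float(np.sum([S_t[t] for t in combo]))
                rest = tot + _log1mexp(min(sh - tot, 0.0))
                non_aligned[key] = m * np.log(p1) + rest
    return aligned, non_aligned


def _ppfc(
    labfs: dict[str, np.ndarray], p1: float, gamma: float
) -> tuple[float, float, float]:
    """(PR, PA, PPFC) for the full trait set in ``labfs``."""
    aligned, non_aligned = _multi_masses(labfs, p1, gamma)
    full = frozenset(labfs)
    terms = [0.0] + list(aligned.values()) + list(non_aligned.values())
    log_total = logsumexp(np.array(terms))
    full_terms = [aligned[full]] + ([non_aligned[full]] if full in non_aligned else [])
    log_full = logsumexp(np.array(full_terms))
    pr = float(np.exp(log_full - log_total))
    pa = float(np.exp(aligned[full] - log_full))
    return pr, pa, pr * pa


def multi_coloc(
    block: Mapping[str, pd.DataFrame],
    prior1: float = 1e-4,
    prior2: float = 0.98,
    regional_thresh: float = 0.6,
    align_thresh: float = 0.6,
    prior_sd: float | Mapping[str, float] = DEFAULT_PRIOR_SD_QUANT,
    locus: str = "",
) -> ColocResult:
    """Multi-trait colocalization with divisive clustering.

    ``block`` maps trait name -> summary table (MARKER, BETA, SE) over a
    predefined approximately-independent LD block; tables are intersected on
    shared markers. ``prior1`` is the per-variant causal prior and ``prior2``
    the conditional probability that a causal variant is shared with one more
    trait. The full trait set is reported colocalized when PR >= the regional
    threshold and PA >= the alignment threshold; otherwise the set is split
    divisively and the largest passing cluster reported.
    """
    traits = list(block)
    if len(traits) < 2:
        raise ValueError("multi-trait colocalization needs at least 2 traits")
    shared: set[str] | None = None
    for t in traits:
        m = set(block[t]["MARKER"])
        shared = m if shared is None else shared & m
    shared_list = sorted(shared or set())
    if not shared_list:
        raise ValueError("no variants shared across all traits in the block")

    labfs: dict[str, np.ndarray] = {}
    for t in traits:
        df = block[t].set_index("MARKER").loc[shared_list]
        sd = prior_sd[t] if isinstance(prior_sd, Mapping) else prior_sd
        labfs[t] = trait_abf(df["BETA"].to_numpy(), df["SE"].to_numpy(), sd)

    def evaluate(subset: tuple[str, ...]) -> tuple[float, float, float]:
        return _ppfc({t: labfs[t] for t in subset}, prior1, prior2)

    def cluster(subset: tuple[str, ...]) -> list[tuple[tuple[str, ...], float, float, float]]:
        if len(subset) < 2:
            return []
        pr, pa, ppfc = evaluate(subset)
        if pr >= regional_thresh and pa >= align_thresh:
            return [(subset, pr, pa, ppfc)]
        if len(subset) == 2:
            return []
        drop_scores = []
        for t in subset:
            rest = tuple(x for x in subset if x != t)
            drop_scores.append((evaluate(rest)[2], t, rest))
        drop_scores.sort(key=lambda x: (-x[0], x[1]))
        _, dropped, rest = drop_scores[0]
        return cluster(rest)

    full = tuple(traits)
    pr, pa, ppfc = evaluate(full)
    found = cluster(full)
    clusters = [c[0] for c in found]
    posteriors = {"PR": pr, "PA": pa, "PPFC": ppfc}
    if found and found[0][0] != full:
        posteriors["PPFC_cluster"] = found[0][3]
    stacked = np.sum([labfs[t] for t in (found[0][0] if found else full)], axis=0)
    candidate = shared_list[int(np.argmax(stacked))]
    return ColocResult(
        locus=locus,
        traits=full,
        posteriors=posteriors,
        candidate=candidate,
        clusters=clusters,
        decision=bool(found),
    )


# ---------------------------------------------------------------------------
# sensitivity and decisions
# ---------------------------------------------------------------------------

def sensitivity_score(
    engine: Callable[..., bool], grid: Iterable[dict]
) -> float:
    """Proportion of grid re-analyses in which the colocalization persists."""
    grid = list(grid)
    if not grid:
        raise ValueError("sensitivity grid is empty")
    passed = sum(1 for params in grid if engine(**params))
    return passed / len(grid)


def coloc_p12_grid(n: int = 100, low: float = 1e-8, high: float = 1e-4) -> list[dict]:
    """Log-uniform p12 grid for pairwise-coloc sensitivity analyses."""
    return [{"p12": float(v)} for v in np.geomspace(low, high, n)]


def hyprcoloc_grid(
    regional: Iterable[float] = (0.6, 0.7, 0.8, 0.9),
    align: Iterable[float] = (0.6, 0.7, 0.8, 0.9),
    prior2: Iterable[float] = (0.98, 0.985, 0.99, 0.995),
) -> list[dict]:
    """Threshold/prior grid for multi-trait sensitivity analyses."""
    return [
        {"regional_thresh": r, "align_thresh": a, "prior2": g}
        for r in regional for a in align for g in prior2
    ]


def coloc_decision(
    pp: float, sensitivity: float | None, lead_pair_r2: float | None,
    pp_threshold: float = 0.6, sens_threshold: float = 0.4,
    r2_threshold: float = 0.8,
) -> bool:
    """Composite call: PP > 0.6 AND (sensitivity > 0.4 OR lead r^2 > 0.8)."""
    import warnings

    if lead_pair_r2 is None or not np.isfinite(lead_pair_r2):
        warnings.warn("missing lead-pair r^2 treated as 0")
        lead_pair_r2 = 0.0
    if sensitivity is None or not np.isfinite(sensitivity):
        sensitivity = 0.0
    return bool(
        pp > pp_threshold
        and (sensitivity > sens_threshold or lead_pair_r2 > r2_threshold)
    )


# ---------------------------------------------------------------------------
# direction-of-effect consensus
# ---------------------------------------------------------------------------

PRIMARY_TRAITS = ("T2D", "FG")


@dataclass
class DirectionCall:
    direction: int | None  # +1, -1, or None
    rule: str | None  # "primary" | "fallback" | None
    conflict: bool = False


def classify_direction(
    lookups: Mapping[str, tuple[float, float]],
    primary_p: float = 1e-4,
    fallback_p: float = 0.01,
) -> DirectionCall:
    """Consensus direction of a lead variant's effect on companion traits.

    ``lookups`` maps trait name -> (beta, p) with effect alleles harmonized
    to the index trait's effect allele. Primary rule: T2D or fasting glucose
    with p < 1e-4 fix the sign (conflicting primary signs -> unclassified
    with a conflict flag). Fallback: at least two companion traits with
    p < 0.01 sharing a sign.
    """
    primary_signs = {
        int(np.sign(b))
        for t, (b, p) in lookups.items()
        if t in PRIMARY_TRAITS and p < primary_p and b != 0
    }
    if len(primary_signs) > 1:
        return DirectionCall(None, None, conflict=True)
    if len(primary_signs) == 1:
        return DirectionCall(primary_signs.pop(), "primary")
    signs = [int(np.sign(b)) for b, p in lookups.values() if p < fallback_p and b != 0]
    pos, neg = signs.count(1), signs.count(-1)
    if pos >= 2 and neg >= 2:
        return DirectionCall(None, None, conflict=True)
    if pos >= 2:
        return DirectionCall(1, "fallback")
    if neg >= 2:
        return DirectionCall(-1, "fallback")
    return DirectionCall(None, None)
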