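"""Annotation enrichment of GWAS signals with matched control variants.

A signal "overlaps" an annotation track when its lead variant or any LD
proxy (r^2 > 0.8) falls inside a track interval. Global enrichment compares
the observed number of overlapping index variants with the expectation under
matched controls — variants drawn from the same LD-proxy-count, MAF, and
distance-to-nearest-gene bin as each index — and the p-value is the exact
upper tail of the Poisson-binomial distribution with per-index control
overlap rates, evaluated by dynamic programming.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ld import LDPanel

PROXY_COUNT_BINS = (0, 1, 5, 10, 25)  # {0}, 1-4, 5-9, 10-24, >=25


class AnnotationTrack:
    """BED-style intervals (0-based half-open) with fast point queries."""

    def __init__(self, intervals: pd.DataFrame, name: str = "track",
                 tissue: str = ""):
        self.name = name
        self.tissue = tissue
        self._per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if len(intervals):
            if (intervals["end"] < intervals["start"]).any():
                raise ValueError("intervals must have non-negative length")
            for chrom, grp in intervals.groupby("chrom"):
                grp = grp.sort_values("start")
                starts, ends = [], []
                cur_s, cur_e = None, None
                for s, e in zip(grp["start"], grp["end"]):
                    if cur_s is None:
                        cur_s, cur_e = s, e
                    elif s <= cur_e:
                        cur_e = max(cur_e, e)
                    else:
                        starts.append(cur_s)
                        ends.append(cur_e)
                        cur_s, cur_e = s, e
                if cur_s is not None:
                    starts.append(cur_s)
                    ends.append(cur_e)
                self._per_chrom[str(chrom)] = (
                    np.asarray(starts, dtype=np.int64),
                    np.asarray(ends, dtype=np.int64),
                )

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether the 1-based position falls in an interval."""
        return bool(self.contains_many(np.array([str(chrom)]), np.array([pos]))[0])

    def contains_many(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        out = np.zeros(len(positions), dtype=bool)
        pos0 = np.asarray(positions, dtype=np.int64) - 1
        chroms = np.asarray(chroms).astype(str)
        for chrom in np.unique(chroms):
            if chrom not in self._per_chrom:
                continue
            starts, ends = self._per_chrom[chrom]
            mask = chroms == chrom
            j = np.searchsorted(starts, pos0[mask], side="right") - 1
            hit = (j >= 0) & (pos0[mask] < ends[np.clip(j, 0, None)])
            out[np.flatnonzero(mask)] = hit
        return out


def _proxy_matrix(panel: LDPanel, r2_threshold: float = 0.8) -> list[np.ndarray]:
    """Per-variant index arrays of proxies with r^2 > threshold (self excluded).

    Computed blockwise when the panel carries a block map; otherwise from the
    full correlation matrix.
    """
    blocks = getattr(panel, "block_map", None)
    n = panel.n_variants
    out: list[np.ndarray] = [np.empty(0, dtype=int)] * n
    if blocks is None:
        blocks = np.zeros(n, dtype=int)
    for b in np.unique(blocks):
        cols = np.flatnonzero(blocks == b)
        r2 = panel.corr([panel.markers[i] for i in cols]) ** 2
        for local_i, i in enumerate(cols):
            hits = cols[(r2[local_i] > r2_threshold)]
            out[i] = hits[hits != i]
    return out


def variant_overlap_vector(
    panel: LDPanel, track: AnnotationTrack, proxy_r2: float = 0.8
) -> np.ndarray:
    """Proxy-inclusive overlap flag for every panel variant."""
    meta = panel.variant_meta
    direct = track.contains_many(meta["chr"].to_numpy(), meta["pos"].to_numpy())
    proxies = _proxy_matrix(panel, proxy_r2)
    out = direct.copy()
    for i, prox in enumerate(proxies):
        if not out[i] and len(prox):
            out[i] = bool(direct[prox].any())
    return out


def signal_overlap(
    lead: str, panel: LDPanel, track: AnnotationTrack, proxy_r2: float = 0.8
) -> bool:
    """True iff the lead or any r^2 > proxy_r2 proxy lies in the track."""
    i = panel.idx(lead)[0]
    meta = panel.variant_meta
    if track.contains(meta["chr"].iloc[i], int(meta["pos"].iloc[i])):
        return True
    for m in panel.proxies(lead, proxy_r2):
        j = panel.idx(m)[0]
        if track.contains(meta["chr"].iloc[j], int(meta["pos"].iloc[j])):
            return True
    return False


# ---------------------------------------------------------------------------
# control matching
# ---------------------------------------------------------------------------

@dataclass
class MatchingFeatures:
    """Per-variant matching features and bin assignments over the pool."""

    proxy_counts: np.ndarray
    maf: np.ndarray
    gene_distance: np.ndarray
    proxy_bin: np.ndarray
    maf_bin: np.ndarray
    dist_bin: np.ndarray
    proxies: list[np.ndarray]


def compute_matching_features(
    panel: LDPanel,
    gene_map: pd.DataFrame,
    proxy_r2: float = 0.8,
    n_maf_bins: int = 10,
    n_dist_bins: int = 4,
) -> MatchingFeatures:
    """LD-proxy counts, MAF deciles, and distance-to-gene quartiles."""
    proxies = _proxy_matrix(panel, proxy_r2)
    counts = np.array([len(p) for p in proxies])
    maf = panel.maf()
    meta = panel.variant_meta
    dist = np.full(panel.n_variants, np.inf)
    for chrom, grp in gene_map.groupby("chrom"):
        mask = (meta["chr"].astype(str) == str(chrom)).to_numpy()
        if not mask.any():
            continue
        pos = meta.loc[mask, "pos"].to_numpy(np.int64)
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        d = np.full(mask.sum(), np.inf)
        for s, e in zip(starts, ends):
            inside = (pos > s) & (pos <= e)
            gap = np.where(pos <= s, s - pos + 1, pos - e)
            d = np.minimum(d, np.where(inside, 0, gap))
        dist[mask] = d
    proxy_bin = np.digitize(counts, PROXY_COUNT_BINS[1:], right=False)
    maf_edges = np.quantile(maf, np.linspace(0, 1, n_maf_bins + 1)[1:-1])
    maf_bin = np.digitize(maf, maf_edges, right=False)
    finite = np.where(np.isfinite(dist), dist, np.nanmax(np.where(np.isfinite(dist), dist, 0)))
    dist_edges = np.quantile(finite, np.linspace(0, 1, n_dist_bins + 1)[1:-1])
    dist_bin = np.digitize(finite, dist_edges, right=False)
    return MatchingFeatures(counts, maf, dist, proxy_bin, maf_bin, dist_bin, proxies)


def match_controls(
    lead: str,
    panel: LDPanel,
    features: MatchingFeatures,
    n_controls: int,
    rng: np.random.Generator,
    excluded_extra: set[int] | None = None,
) -> np.ndarray:
    """Indices of control variants matched to the index variant's bin cell.

    Controls come from the same (proxy-count, MAF, gene-distance) bin as the
    index, never include the index or its proxies (nor any index in
    ``excluded_extra``, typically the full lead list), and are drawn without
    replacement. Undersized cells are relaxed to neighbouring bins (expanding
    Chebyshev distance) with a warning.
    """
    i = panel.idx(lead)[0]
    excluded = set(features.proxies[i].tolist()) | {i} | set(excluded_extra or ())
    target = np.array([features.proxy_bin[i], features.maf_bin[i], features.dist_bin[i]])
    bins = np.column_stack([features.proxy_bin, features.maf_bin, features.dist_bin])
    for relax in range(0, 11):
        dist = np.abs(bins - target).max(axis=1)
        eligible = np.flatnonzero(dist <= relax)
        eligible = np.array([j for j in eligible if j not in excluded])
        if len(eligible) >= n_controls:
            if relax > 0:
                warnings.warn(
                    f"matching cell for {lead!r} undersized; relaxed bins by {relax}"
                )
            return rng.choice(eligible, size=n_controls, replace=False)
    warnings.warn(
        f"pool smaller than n_controls for {lead!r}; using all {len(eligible)} eligible"
    )
    return eligible


# ---------------------------------------------------------------------------
# enrichment test
# ---------------------------------------------------------------------------

def poisson_binomial_pmf(ps: np.ndarray) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_i) by DP convolution."""
    pmf = np.array([1.0])
    for p in np.asarray(ps, dtype=float):
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def poisson_binomial_sf(k: int, ps: np.ndarray) -> float:
    """P(X >= k) for the Poisson-binomial sum."""
    pmf = poisson_binomial_pmf(ps)
    if k <= 0:
        return 1.0
    return float(pmf[k:].sum())


@dataclass
class EnrichmentResult:
    track: str
    observed: int
    expected: float
    fold: float
    p_value: float
    n_controls_per_index: int
    control_rates: np.ndarray
    fold_infinite: bool = False

    @property
    def p_mid(self) -> float:
        """Mid-p upper tail (half weight on the observed count)."""
        pmf = poisson_binomial_pmf(self.control_rates)
        k = self.observed
        tail_excl = float(pmf[k + 1:].sum()) if k + 1 <= len(pmf) else 0.0
        at = float(pmf[k]) if k < len(pmf) else 0.0
        return tail_excl + 0.5 * at


def enrichment_test(
    leads: list[str],
    panel: LDPanel,
    track: AnnotationTrack,
    gene_map: pd.DataFrame,
    n_controls: int = 500,
    seed: int = 0,
    proxy_r2: float = 0.8,
    features: MatchingFeatures | None = None,
    overlap: np.ndarray | None = None,
) -> EnrichmentResult:
    """Matched-control enrichment of index variants in one annotation track.

    Per index i, p_i is the fraction of its matched controls whose
    proxy-inclusive overlap is true; expected = sum p_i; fold =
    observed/expected; the p-value is the exact Poisson-binomial upper tail
    at the observed count. ``features``/``overlap`` may be precomputed and
    shared across tracks or replicates.
    """
    if not leads:
        raise ValueError("at least one lead variant is required")
    rng = np.random.default_rng(seed)
    if features is None:
        features = compute_matching_features(panel, gene_map, proxy_r2)
    if overlap is None:
        overlap = variant_overlap_vector(panel, track, proxy_r2)
    lead_idx = {int(panel.idx(lead)[0]) for lead in leads}
    observed = 0
    rates = []
    for lead in leads:
        i = panel.idx(lead)[0]
        observed += int(overlap[i])
        controls = match_controls(lead, panel, features, n_controls, rng,
                                  excluded_extra=lead_idx)
        rates.append(float(overlap[controls].mean()) if len(controls) else 0.0)
    rates = np.array(rates)
    expected = float(rates.sum())
    if expected > 0:
        fold = observed / expected
        infinite = False
        p = poisson_binomial_sf(observed, rates)
    elif observed > 0:
        fold = float("inf")
        infinite = True
        p = 1.0 / (n_controls + 1)
    else:
        fold = float("nan")
        infinite = False
        p = 1.0
    return EnrichmentResult(
        track=track.name, observed=observed, expected=expected, fold=fold,
        p_value=p, n_controls_per_index=n_controls, control_rates=rates,
        fold_infinite=infinite,
    )
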