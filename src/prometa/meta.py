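"""Study-level QC, double genomic control, IVW meta-analysis, and loci.

The meta-analysis model is the standard fixed-effects inverse-variance
weighted pool: per variant, w_i = 1/se_i^2, pooled beta = sum(w_i b_i)/sum(w_i),
pooled se = sqrt(1/sum(w_i)). Genomic control is applied twice — to each
study's statistics before pooling and to the pooled statistics afterwards —
with lambda = median(z^2) / 0.455936 (the chi-square_1 median) and standard
errors inflated by sqrt(lambda) only when lambda > 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LDPanel

CHI2_1_MEDIAN = 0.455936

QC_COLUMNS = ["EAF", "BETA", "SE", "N", "INFO", "HWE_P", "CALLRATE"]

GENOME_WIDE_P = 5e-8

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(study: pd.DataFrame, n_study: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """EasyQC-style per-study variant filters.

    Removes variants with minor allele count < 3, MAF < 0.005, call rate
    < 0.95, HWE p < 1e-5, imputation quality < 0.3, or SE > 10 (strict).
    The exclusion log records one reason code per removed variant: the first
    failing rule in the order MAC, MAF, CALLRATE, HWE, INFO, SE.
    """
    missing = [c for c in QC_COLUMNS if c not in study.columns]
    if missing:
        raise ValueError(f"missing QC column(s): {missing}")
    eaf = study["EAF"].to_numpy(float)
    maf = np.minimum(eaf, 1.0 - eaf)
    n = study["N"].to_numpy(float) if n_study is None else float(n_study)
    mac = 2.0 * n * maf
    rules = [
        ("MAC", mac < 3),
        ("MAF", maf < 0.005),
        ("CALLRATE", study["CALLRATE"].to_numpy(float) < 0.95),
        ("HWE", study["HWE_P"].to_numpy(float) < 1e-5),
        ("INFO", study["INFO"].to_numpy(float) < 0.3),
        ("SE", study["SE"].to_numpy(float) > 10.0),
    ]
    reason = np.full(len(study), "", dtype=object)
    for code, mask in rules:
        mask = np.asarray(mask) & (reason == "")
        reason[mask] = code
    excluded = reason != ""
    log = pd.DataFrame(
        {"MARKER": study.loc[excluded, "MARKER"].to_numpy(),
         "reason": reason[excluded]}
    )
    return study.loc[~excluded].reset_index(drop=True), log


# ---------------------------------------------------------------------------
# genomic control
# ---------------------------------------------------------------------------

def genomic_control(assocs: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Median-based genomic-control correction.

    lambda = median((beta/se)^2) / 0.455936. When lambda > 1 the SEs are
    inflated by sqrt(lambda) and p-values recomputed from the corrected z;
    when lambda <= 1 the table is returned unchanged (lambda still reported).
    """
    z = assocs["BETA"].to_numpy(float) / assocs["SE"].to_numpy(float)
    finite = np.isfinite(z)
    if not finite.any():
        raise ValueError("no finite z-scores; cannot estimate lambda")
    if finite.sum() < 100:
        warnings.warn(
            f"only {int(finite.sum())} finite z-scores; lambda is unreliable"
        )
    lam = float(np.median(z[finite] ** 2) / CHI2_1_MEDIAN)
    out = assocs.copy()
    if lam > 1:
        out["SE"] = out["SE"] * np.sqrt(lam)
        zc = out["BETA"].to_numpy(float) / out["SE"].to_numpy(float)
        out["P"] = 2.0 * stats.norm.sf(np.abs(zc))
    return out, lam


# ---------------------------------------------------------------------------
# allele harmonization
# ---------------------------------------------------------------------------

def align_alleles(
    study: pd.DataFrame, reference: pd.DataFrame | dict
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Harmonize EA/NEA to a reference orientation.

    ``reference`` maps marker -> (ea, nea), either as a dict or a DataFrame
    with columns ``MARKER, EA, NEA``. Swapped records get their beta sign and
    EAF flipped; strand flips are resolved by complementing. Strand-ambiguous
    (A/T, C/G) variants with MAF > 0.4 and irreconcilable allele pairs are
    dropped and logged.
    """
    if isinstance(reference, pd.DataFrame):
        ref = {
            m: (ea, nea)
            for m, ea, nea in zip(reference["MARKER"], reference["EA"], reference["NEA"])
        }
    else:
        ref = dict(reference)

    rows = []
    log = []
    for rec in study.to_dict("records"):
        m = rec["MARKER"]
        if m not in ref:
            log.append({"MARKER": m, "reason": "not in reference"})
            continue
        ea, nea = str(rec["EA"]).upper(), str(rec["NEA"]).upper()
        ref_ea, ref_nea = (str(a).upper() for a in ref[m])
        ambiguous = (ea, nea) in AMBIGUOUS_PAIRS
        maf = min(rec["EAF"], 1.0 - rec["EAF"])
        if ambiguous and maf > 0.4:
            log.append({"MARKER": m, "reason": "strand-ambiguous"})
            continue
        flipped = (_COMPLEMENT.get(ea, "?"), _COMPLEMENT.get(nea, "?"))
        if (ea, nea) == (ref_ea, ref_nea) or flipped == (ref_ea, ref_nea):
            pass
        elif (nea, ea) == (ref_ea, ref_nea) or (flipped[1], flipped[0]) == (ref_ea, ref_nea):
            rec = dict(rec)
            rec["BETA"] = -rec["BETA"]
            rec["EAF"] = 1.0 - rec["EAF"]
        else:
            log.append({"MARKER": m, "reason": "irreconcilable alleles"})
            continue
        rec["EA"], rec["NEA"] = ref_ea, ref_nea
        rows.append(rec)
    harmonized = pd.DataFrame(rows, columns=study.columns)
    return harmonized, pd.DataFrame(log, columns=["MARKER", "reason"])


# ---------------------------------------------------------------------------
# IVW meta-analysis
# ---------------------------------------------------------------------------

@dataclass
class MetaResult:
    """Pooled summary statistics plus the genomic-control bookkeeping."""

    table: pd.DataFrame
    lambda_meta: float
    lambda_per_study: dict[str, float] = field(default_factory=dict)


def ivw_meta(
    studies: list[pd.DataFrame],
    apply_meta_gc: bool = True,
    study_labels: list[str] | None = None,
    gc_per_study: bool = False,
) -> MetaResult:
    """Fixed-effects inverse-variance weighted meta-analysis.

    Studies are assumed allele-harmonized (see :func:`align_alleles`) and,
    unless ``gc_per_study`` is set, already genomic-control corrected. EAF is
    pooled as the sample-size-weighted mean. Post-meta genomic control is
    applied to the pooled statistics by default.
    """
    if not studies:
        raise ValueError("no studies supplied")
    labels = study_labels or [f"study{i}" for i in range(len(studies))]
    lambda_per_study: dict[str, float] = {}
    frames = []
    for label, df in zip(labels, studies):
        if gc_per_study:
            df, lam = genomic_control(df)
            lambda_per_study[label] = lam
        frames.append(df.assign(_study=label))
    stacked = pd.concat(frames, ignore_index=True)
    stacked = stacked[np.isfinite(stacked["BETA"]) & np.isfinite(stacked["SE"])
                      & (stacked["SE"] > 0)]

    w = 1.0 / stacked["SE"] ** 2
    stacked = stacked.assign(_w=w, _wb=w * stacked["BETA"],
                             _wn=stacked["N"] * stacked["EAF"])
    grp = stacked.groupby("MARKER", sort=False)
    agg = grp.agg(
        CHR=("CHR", "first"),
        POS=("POS", "first"),
        EA=("EA", "first"),
        NEA=("NEA", "first"),
        _w=("_w", "sum"),
        _wb=("_wb", "sum"),
        N=("N", "sum"),
        _wn=("_wn", "sum"),
        N_STUDIES=("_study", "nunique"),
    ).reset_index()
    agg["BETA"] = agg["_wb"] / agg["_w"]
    agg["SE"] = np.sqrt(1.0 / agg["_w"])
    agg["EAF"] = agg["_wn"] / agg["N"]
    z = agg["BETA"] / agg["SE"]
    agg["P"] = 2.0 * stats.norm.sf(np.abs(z))
    table = agg[["MARKER", "CHR", "POS", "EA", "NEA", "EAF",
                 "BETA", "SE", "P", "N", "N_STUDIES"]]
    lam_meta = 1.0
    if apply_meta_gc:
        table, lam_meta = genomic_control(table)
    return MetaResult(table=table.reset_index(drop=True),
                      lambda_meta=lam_meta,
                      lambda_per_study=lambda_per_study)


def post_meta_filter(meta: MetaResult, max_n: int | None = None) -> MetaResult:
    """Post-meta inclusion: N >= max_n/4, >= 2 studies, pooled MAF > 0.005."""
    t = meta.table
    if max_n is None:
        max_n = int(t["N"].max())
    maf = np.minimum(t["EAF"], 1.0 - t["EAF"])
    keep = (t["N"] >= max_n / 4.0) & (t["N_STUDIES"] >= 2) & (maf > 0.005)
    return MetaResult(table=t.loc[keep].reset_index(drop=True),
                      lambda_meta=meta.lambda_meta,
                      lambda_per_study=meta.lambda_per_study)


# ---------------------------------------------------------------------------
# locus definition
# ---------------------------------------------------------------------------

@dataclass
class Locus:
    lead: str
    chrom: str
    start: int
    end: int
    lead_p: float
    members: list[str]
    merged_from: list[str] = field(default_factory=list)
    no_ld_info: bool = False

    @property
    def span(self) -> str:
        return f"{self.chrom}:[{self.start},{self.end}]"


def define_loci(
    meta: MetaResult | pd.DataFrame,
    panel: LDPanel | None = None,
    p_threshold: float = GENOME_WIDE_P,
    window: int = 500_000,
    merge_r2: float = 0.4,
) -> list[Locus]:
    """Greedy lead selection and LD-based locus merging.

    Leads are chosen by ascending p (ties broken by smaller SE, then marker)
    among variants with p < ``p_threshold``; each locus spans lead +/- the
    window and claims all variants inside. Loci whose leads have panel
    r^2 > ``merge_r2`` are merged into one extended region led by the
    smallest-p lead. Leads absent from the panel keep their locus and are
    flagged ``no_ld_info``.
    """
    t = meta.table if isinstance(meta, MetaResult) else meta
    sig = t[t["P"] < p_threshold].sort_values(
        ["P", "SE", "MARKER"], kind="mergesort"
    )
    claimed: set[str] = set()
    loci: list[Locus] = []
    for rec in sig.to_dict("records"):
        if rec["MARKER"] in claimed:
            continue
        chrom, pos = rec["CHR"], rec["POS"]
        in_span = t[(t["CHR"] == chrom) & (t["POS"] >= pos - window)
                    & (t["POS"] <= pos + window)]
        members = list(in_span["MARKER"])
        claimed.update(in_span.loc[in_span["P"] < p_threshold, "MARKER"])
        loci.append(
            Locus(
                lead=rec["MARKER"], chrom=str(chrom),
                start=int(pos - window), end=int(pos + window),
                lead_p=float(rec["P"]), members=members,
                no_ld_info=panel is not None and not panel.has(rec["MARKER"]),
            )
        )

    if panel is None or len(loci) < 2:
        return loci

    # union-find merge of loci whose leads are in LD
    parent = list(range(len(loci)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            a, b = loci[i], loci[j]
            if a.chrom != b.chrom:
                continue
            if not (panel.has(a.lead) and panel.has(b.lead)):
                continue
            if panel.r2(a.lead, b.lead) > merge_r2:
                parent[find(i)] = find(j)

    groups: dict[int, list[Locus]] = {}
    for i, loc in enumerate(loci):
        groups.setdefault(find(i), []).append(loc)
    merged: list[Locus] = []
    for group in groups.values():
        if len(group) == 1:
            merged.append(group[0])
            continue
        group = sorted(group, key=lambda l: (l.lead_p, l.lead))
        lead = group[0]
        members = sorted({m for l in group for m in l.members})
        merged.append(
            Locus(
                lead=lead.lead, chrom=lead.chrom,
                start=min(l.start for l in group),
                end=max(l.end for l in group),
                lead_p=lead.lead_p, members=members,
                merged_from=[l.lead for l in group],
                no_ld_info=any(l.no_ld_info for l in group),
            )
        )
    merged.sort(key=lambda l: (l.chrom, l.start))
    return merged


def loci_table(loci: list[Locus]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lead": [l.lead for l in loci],
            "chr": [l.chrom for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
            "p": [l.lead_p for l in loci],
            "n_members": [len(l.members) for l in loci],
            "merged_from": [",".join(l.merged_from) for l in loci],
        }
    )


# ---------------------------------------------------------------------------
# variance explained
# ---------------------------------------------------------------------------

def variance_explained(beta: float, eaf: float) -> float:
    """Proportion of trait variance explained by one variant: 2 b^2 f (1-f)."""
    if not (0 < eaf < 1):
        raise ValueError("eaf must be strictly inside (0, 1): monomorphic")
    return 2.0 * beta**2 * eaf * (1.0 - eaf)


def total_variance_explained(leads: pd.DataFrame) -> float:
    """Sum of per-lead variance explained over a leads table (BETA, EAF)."""
    return float(
        sum(variance_explained(b, f) for b, f in zip(leads["BETA"], leads["EAF"]))
    )
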