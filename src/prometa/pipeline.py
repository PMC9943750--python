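"""End-to-end pipeline orchestration over a synthetic study.

Stages run in order: simulate -> qc -> meta -> loci -> conditional ->
finemap -> coloc -> direction -> enrich -> smr. Each stage writes its
tables into the run directory and records row counts in the manifest;
reruns with the same config are bit-identical for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import io
from .cojo import cojo_select, consensus_signals, maf_consistency, signals_table
from .coloc import (
    classify_direction,
    coloc_decision,
    coloc_pair,
    coloc_p12_grid,
    multi_coloc,
    sensitivity_score,
)
from .enrich import AnnotationTrack, enrichment_test
from .finemap import (
    conditional_credible_set,
    credible_sets_table,
    extend_credible_set,
    finemap_window,
)
from .meta import (
    define_loci,
    ivw_meta,
    loci_table,
    post_meta_filter,
    qc_filter,
    variance_explained,
)
from .simulate import (
    BlockSpec,
    CausalEffect,
    EnrichmentConfig,
    GeneConfig,
    SimulationScenario,
    simulate_annotations,
    simulate_cohort_sumstats,
    simulate_eqtl_sumstats,
    simulate_gene_map,
    simulate_ld_panel,
)
from .smr import smr_table, smr_with_heidi

STAGES = (
    "simulate", "qc", "meta", "loci", "conditional", "finemap",
    "coloc", "direction", "enrich", "smr",
)

INDEX_TRAIT = "proinsulin"


class BlockConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_variants: int
    maf_low: float = 0.05
    maf_high: float = 0.5
    decay: float = 0.9
    chrom: str = "1"


class CausalConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    block: int
    index: int
    traits: dict[str, float]


class GeneSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    gene: str
    block: int
    index: int
    beta: float = 0.8
    n_samples: int = 420
    mode: Literal["shared", "distinct", "null"] = "shared"


class EnrichSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fold: float = 4.0
    width: int = 400
    background_fraction: float = 0.05
    n_genes: int = 40


class Thresholds(BaseModel):
    model_config = ConfigDict(extra="forbid")
    gw_p: float = 5e-8
    merge_r2: float = 0.4
    proxy_r2: float = 0.8
    locus_window: int = 500_000
    cojo_window: int = 1_000_000
    max_signals: int = 3
    collinearity_r2: float = 0.8
    maf_tol: float = 0.05
    coverage: float = 0.99
    trait_block_p: float = 1e-4
    coloc_pp: float = 0.6
    coloc_sens: float = 0.4
    decision_r2: float = 0.8
    n_controls: int = 500
    smr_instrument_p: float = 5e-8


class PipelineConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 1
    out_dir: str = "runs/demo"
    stages: list[str] = Field(default_factory=lambda: list(STAGES))
    bmi_adjusted: bool = True
    blocks: list[BlockConfig]
    causal: list[CausalConfig] = Field(default_factory=list)
    n_cohorts: int = 16
    cohort_size: int = 800
    companion_traits: list[str] = Field(
        default_factory=lambda: ["T2D", "FG", "FI", "HbA1c", "2hGlu"]
    )
    companion_n: int = 20_000
    ref_panel_sizes: dict[str, int] = Field(
        default_factory=lambda: {"metsim_like": 2000, "fenland_like": 1800,
                                 "emerge_like": 1500}
    )
    eqtl_genes: list[GeneSpec] = Field(default_factory=list)
    enrichment: EnrichSpec = Field(default_factory=EnrichSpec)
    thresholds: Thresholds = Field(default_factory=Thresholds)

    @model_validator(mode="after")
    def _check_stages(self) -> "PipelineConfig":
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class PipelineRun:
    """Mutable state threaded through the stages of one run."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "thresholds": config.thresholds.model_dump(),
            "stages": {},
        }
        self.log_path = self.out / "log.jsonl"
        self._log_fh = open(self.log_path, "w")
        self.panel = None
        self.ref_panels: dict = {}
        self.cohort_stats: list[pd.DataFrame] = []
        self.companion_meta: dict[str, pd.DataFrame] = {}
        self.meta = None
        self.loci = []
        self.signals = []
        self.credible_sets = []

    def log(self, stage: str, **payload) -> None:
        self._log_fh.write(json.dumps({"stage": stage, **payload}) + "\n")

    def record(self, stage: str, **counts) -> None:
        self.manifest["stages"][stage] = counts

    def close(self) -> None:
        self._log_fh.close()
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _scenario(config: PipelineConfig, causal: list[CausalEffect]) -> SimulationScenario:
    return SimulationScenario(
        n_cohorts=config.n_cohorts,
        cohort_sizes=[config.cohort_size] * config.n_cohorts,
        causal_config=causal,
        seed=config.seed,
    )


def run_pipeline(config: PipelineConfig) -> PipelineRun:
    run = PipelineRun(config)
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            try:
                globals()[f"_stage_{stage}"](run)
            except Exception as exc:
                run.log(stage, error=str(exc))
                run.close()
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        run.close()
    return run


def _resolve_causal(run: PipelineRun) -> list[CausalEffect]:
    effects = []
    meta = run.panel.variant_meta
    for c in run.config.causal:
        rows = meta[meta["block"] == c.block]
        marker = rows["marker"].iloc[c.index]
        for trait, beta in c.traits.items():
            effects.append(CausalEffect(marker=marker, trait=trait, beta=beta))
    return effects


def _stage_simulate(run: PipelineRun) -> None:
    cfg = run.config
    blocks = [
        BlockSpec(b.n_variants, (b.maf_low, b.maf_high), b.decay, b.chrom)
        for b in cfg.blocks
    ]
    run.panel = simulate_ld_panel(
        n_samples=2000, blocks=blocks, seed=cfg.seed, source="truth"
    )
    causal = _resolve_causal(run)
    run.causal = causal
    run.scenario = _scenario(cfg, causal)
    for name, size in cfg.ref_panel_sizes.items():
        run.ref_panels[name] = run.panel.resample(
            size, seed=cfg.seed + 1000 + len(run.ref_panels), source=name
        )
    run.cohort_stats = [
        simulate_cohort_sumstats(run.panel, run.scenario, INDEX_TRAIT, cohort=i)
        for i in range(cfg.n_cohorts)
    ]
    for i, df in enumerate(run.cohort_stats):
        io.write_sumstats(df, run.out / f"cohort{i}_{INDEX_TRAIT}.tsv.gz")
    # companion traits as single large external studies
    comp_scenario = SimulationScenario(
        n_cohorts=1, cohort_sizes=[cfg.companion_n], causal_config=causal,
        seed=cfg.seed + 77,
    )
    for trait in cfg.companion_traits:
        df = simulate_cohort_sumstats(run.panel, comp_scenario, trait, cohort=0)
        run.companion_meta[trait] = df
        io.write_sumstats(df, run.out / f"companion_{trait}.tsv.gz")
    run.record("simulate", n_variants=run.panel.n_variants,
               n_cohorts=cfg.n_cohorts,
               n_companion=len(cfg.companion_traits))


def _stage_qc(run: PipelineRun) -> None:
    kept, n_excluded = [], 0
    for i, df in enumerate(run.cohort_stats):
        out, log = qc_filter(df)
        kept.append(out)
        n_excluded += len(log)
        for rec in log.to_dict("records"):
            run.log("qc", cohort=i, **rec)
    run.cohort_stats = kept
    run.record("qc", n_excluded=n_excluded,
               n_kept=int(sum(len(df) for df in kept)))


def _stage_meta(run: PipelineRun) -> None:
    result = ivw_meta(run.cohort_stats, gc_per_study=True)
    result = post_meta_filter(result)
    run.meta = result
    io.write_sumstats(result.table, run.out / "meta.tsv.gz")
    with open(run.out / "lambda.json", "w") as fh:
        json.dump({"lambda_meta": result.lambda_meta,
                   "lambda_per_study": result.lambda_per_study}, fh, indent=2)
    run.record("meta", n_variants=len(result.table),
               lambda_meta=round(result.lambda_meta, 4))


def _stage_loci(run: PipelineRun) -> None:
    th = run.config.thresholds
    ld = next(iter(run.ref_panels.values()))
    run.loci = define_loci(run.meta, panel=ld, p_threshold=th.gw_p,
                           window=th.locus_window, merge_r2=th.merge_r2)
    df = loci_table(run.loci)
    df["variance_explained"] = [
        variance_explained(
            float(run.meta.table.set_index("MARKER").loc[l.lead, "BETA"]),
            float(run.meta.table.set_index("MARKER").loc[l.lead, "EAF"]),
        )
        for l in run.loci
    ]
    df.to_csv(run.out / "loci.tsv", sep="\t", index=False)
    run.record("loci", n_loci=len(run.loci),
               total_variance_explained=float(df["variance_explained"].sum()))


def _cojo_window(run: PipelineRun, locus) -> pd.DataFrame:
    th = run.config.thresholds
    t = run.meta.table
    lead_pos = int(t.set_index("MARKER").loc[locus.lead, "POS"])
    start = min(locus.start, lead_pos - th.cojo_window)
    end = max(locus.end, lead_pos + th.cojo_window)
    return t[(t["CHR"].astype(str) == locus.chrom)
             & (t["POS"] >= start) & (t["POS"] <= end)]


def _stage_conditional(run: PipelineRun) -> None:
    th = run.config.thresholds
    ld_source = max(run.ref_panels.values(), key=lambda p: p.n_samples)
    all_signals = []
    for locus in run.loci:
        window = _cojo_window(run, locus)
        per_panel = {
            name: cojo_select(
                window, panel, p_threshold=th.gw_p,
                collinearity_r2=th.collinearity_r2,
                max_signals=th.max_signals, locus=locus.lead,
            )
            for name, panel in run.ref_panels.items()
        }
        consensus = consensus_signals(
            per_panel, ld_source, proxy_r2=th.proxy_r2,
            max_signals=th.max_signals,
        )
        meta_by_marker = run.meta.table.set_index("MARKER")
        for s in consensus:
            decision = maf_consistency(
                s.marker, float(meta_by_marker.loc[s.marker, "EAF"]),
                list(run.ref_panels.values()), tol=th.maf_tol,
            )
            if decision.keep:
                all_signals.append(s)
            else:
                run.log("conditional", marker=s.marker, excluded=decision.reason,
                        panel_mafs=decision.panel_mafs)
    run.signals = all_signals
    signals_table(all_signals).to_csv(run.out / "signals.tsv", sep="\t",
                                      index=False)
    run.record("conditional", n_signals=len(all_signals))


def _stage_finemap(run: PipelineRun) -> None:
    th = run.config.thresholds
    t = run.meta.table
    emerge_like = list(run.ref_panels.values())[-1]
    sets = []
    by_locus: dict[str, list] = {}
    for s in run.signals:
        by_locus.setdefault(s.locus, []).append(s)
    for locus_lead, sigs in by_locus.items():
        for s in sigs:
            pos = int(t.set_index("MARKER").loc[s.marker, "POS"])
            chrom = str(t.set_index("MARKER").loc[s.marker, "CHR"])
            window = t[(t["CHR"].astype(str) == chrom)
                       & (t["POS"] >= pos - th.locus_window)
                       & (t["POS"] <= pos + th.locus_window)]
            others = [o.marker for o in sigs if o.marker != s.marker]
            if others:
                cs = conditional_credible_set(
                    window, others, emerge_like, coverage=th.coverage,
                    signal=s.marker,
                )
            else:
                cs = finemap_window(window, coverage=th.coverage, signal=s.marker)
            cs = extend_credible_set(cs, s.marker, emerge_like,
                                     r2_threshold=th.proxy_r2,
                                     window=th.locus_window)
            sets.append(cs)
    run.credible_sets = sets
    credible_sets_table(sets).to_csv(run.out / "credible_sets.tsv", sep="\t",
                                     index=False)
    run.record("finemap", n_sets=len(sets),
               n_members=int(sum(cs.size for cs in sets)))


def _trait_block(run: PipelineRun, locus) -> dict[str, pd.DataFrame]:
    """Traits with min p < 1e-4 inside the locus's LD block."""
    th = run.config.thresholds
    block_ids = set(
        run.panel.variant_meta.set_index("marker").loc[
            [m for m in locus.members if run.panel.has(m)], "block"
        ]
    )
    markers = set(
        run.panel.variant_meta.loc[
            run.panel.variant_meta["block"].isin(block_ids), "marker"
        ]
    )
    block = {}
    index = run.meta.table[run.meta.table["MARKER"].isin(markers)]
    if (index["P"] < th.trait_block_p).any():
        block[INDEX_TRAIT] = index
    for trait, df in run.companion_meta.items():
        sub = df[df["MARKER"].isin(markers)]
        if (sub["P"] < th.trait_block_p).any():
            block[trait] = sub
    return block


def _stage_coloc(run: PipelineRun) -> None:
    th = run.config.thresholds
    ld = next(iter(run.ref_panels.values()))
    rows = []
    for locus in run.loci:
        block = _trait_block(run, locus)
        if INDEX_TRAIT not in block or len(block) < 2:
            continue
        multi = multi_coloc(block, locus=locus.lead)
        for trait in block:
            if trait == INDEX_TRAIT:
                continue
            pair = coloc_pair(block[INDEX_TRAIT], block[trait], locus=locus.lead,
                              labels=(INDEX_TRAIT, trait))
            sens = sensitivity_score(
                lambda p12: coloc_pair(
                    block[INDEX_TRAIT], block[trait], p12=p12
                ).pp4 > th.coloc_pp,
                coloc_p12_grid(),
            )
            comp = run.companion_meta[trait]
            comp_lead = comp.loc[comp["P"].idxmin(), "MARKER"]
            r2 = (
                ld.r2(locus.lead, comp_lead)
                if ld.has(locus.lead) and ld.has(comp_lead)
                else float("nan")
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                decision = coloc_decision(
                    pair.pp4, sens, r2, pp_threshold=th.coloc_pp,
                    sens_threshold=th.coloc_sens, r2_threshold=th.decision_r2,
                )
            rows.append(
                {
                    "locus": locus.lead, "trait": trait,
                    **{k: round(v, 6) for k, v in pair.posteriors.items()},
                    "PPFC": round(multi.ppfc, 6),
                    "in_multi_cluster": any(
                        trait in c and INDEX_TRAIT in c for c in multi.clusters
                    ),
                    "candidate": pair.candidate,
                    "sensitivity": sens, "lead_pair_r2": r2,
                    "colocalized": decision,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(run.out / "coloc.tsv", sep="\t", index=False)
    run.coloc_table = df
    run.record("coloc", n_tests=len(df),
               n_colocalized=int(df["colocalized"].sum()) if len(df) else 0)


def _stage_direction(run: PipelineRun) -> None:
    rows = []
    for locus in run.loci:
        lookups = {}
        for trait, df in run.companion_meta.items():
            sub = df[df["MARKER"] == locus.lead]
            if len(sub):
                lookups[trait] = (float(sub["BETA"].iloc[0]),
                                  float(sub["P"].iloc[0]))
        call = classify_direction(lookups)
        rows.append(
            {"locus": locus.lead, "direction": call.direction,
             "rule": call.rule, "conflict": call.conflict}
        )
    df = pd.DataFrame(rows)
    df.to_csv(run.out / "direction.tsv", sep="\t", index=False)
    run.record("direction", n_classified=int(df["direction"].notna().sum()) if len(df) else 0)


def _stage_enrich(run: PipelineRun) -> None:
    cfg = run.config
    causal_markers = tuple(sorted({c.marker for c in run.causal}))
    enr_cfg = EnrichmentConfig(
        fold=cfg.enrichment.fold, width=cfg.enrichment.width,
        background_fraction=cfg.enrichment.background_fraction,
        causal_markers=causal_markers,
    )
    bed, bg = simulate_annotations(run.panel, enr_cfg, seed=cfg.seed + 31)
    io.write_bed(bed, run.out / "annotations.bed")
    gene_map = simulate_gene_map(run.panel, cfg.enrichment.n_genes,
                                 seed=cfg.seed + 32)
    io.write_bed(gene_map, run.out / "genes.bed")
    track = AnnotationTrack(bed, name="synthetic_enhancers")
    leads = [l.lead for l in run.loci if run.panel.has(l.lead)]
    if not leads:
        run.record("enrich", n_leads=0)
        return
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = enrichment_test(
            leads, run.panel, track, gene_map,
            n_controls=cfg.thresholds.n_controls, seed=cfg.seed + 33,
        )
    pd.DataFrame(
        [{"track": res.track, "observed": res.observed,
          "expected": res.expected, "fold": res.fold, "p": res.p_value,
          "background": bg}]
    ).to_csv(run.out / "enrichment.tsv", sep="\t", index=False)
    run.record("enrich", n_leads=len(leads), observed=res.observed,
               fold=None if np.isnan(res.fold) else round(res.fold, 3))


def _stage_smr(run: PipelineRun) -> None:
    cfg = run.config
    results = []
    n_genes = len(cfg.eqtl_genes) or None
    for i, spec in enumerate(cfg.eqtl_genes):
        rows = run.panel.variant_meta[run.panel.variant_meta["block"] == spec.block]
        marker = rows["marker"].iloc[spec.index]
        gcfg = GeneConfig(gene=spec.gene, causal_marker=marker,
                          beta=spec.beta, n_samples=spec.n_samples,
                          mode=spec.mode)
        eqtl = simulate_eqtl_sumstats(run.panel, gcfg, seed=cfg.seed + 500 + i)
        window_markers = set(rows["marker"])
        gwas = run.meta.table[run.meta.table["MARKER"].isin(window_markers)]
        panel = next(iter(run.ref_panels.values()))
        try:
            res = smr_with_heidi(
                gwas, eqtl, panel, gene=spec.gene,
                instrument_p=cfg.thresholds.smr_instrument_p,
                n_genes_tested=n_genes,
            )
            results.append(res)
        except ValueError as exc:
            run.log("smr", gene=spec.gene, skipped=str(exc))
    smr_table(results).to_csv(run.out / "smr.tsv", sep="\t", index=False)
    run.record("smr", n_genes=len(results))
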