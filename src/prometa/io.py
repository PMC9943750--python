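"""Readers and writers for the text formats the pipeline exchanges.

Summary statistics travel as (optionally gzipped) tab-delimited tables with
METAL-compatible columns ``MARKER CHR POS EA NEA EAF BETA SE P N INFO HWE_P
CALLRATE``; panels as VCFv4.2 with GT fields or a plain dosage matrix;
annotations and gene maps as BED (0-based half-open).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ld import LDPanel


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, compression="infer")


def read_sumstats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", compression="infer")


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name") if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_dosage_matrix(panel: LDPanel, path: str | Path) -> None:
    """Plain dosage matrix: variant metadata columns then one column/sample."""
    meta = panel.variant_meta[["marker", "chr", "pos", "ref", "alt"]].copy()
    dos = pd.DataFrame(panel.dosages.T, columns=panel.sample_ids)
    pd.concat([meta.reset_index(drop=True), dos], axis=1).to_csv(
        path, sep="\t", index=False
    )


def read_dosage_matrix(path: str | Path, source: str | None = None) -> LDPanel:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["marker", "chr", "pos", "ref", "alt"]
    meta = df[meta_cols].copy()
    meta["chr"] = meta["chr"].astype(str)
    sample_ids = [c for c in df.columns if c not in meta_cols]
    dosages = df[sample_ids].to_numpy(dtype=np.int8).T
    return LDPanel(dosages, meta, source=source or Path(path).stem,
                   sample_ids=sample_ids)


_VCF_HEADER = """##fileformat=VCFv4.2
##source=prometa
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(panel: LDPanel, path: str | Path) -> None:
    """Write the panel as an unphased VCFv4.2 with GT fields."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        meta = panel.variant_meta
        for j in range(panel.n_variants):
            gts = "\t".join(_GT[int(d)] for d in panel.dosages[:, j])
            fh.write(
                f"{meta['chr'].iloc[j]}\t{meta['pos'].iloc[j]}\t"
                f"{meta['marker'].iloc[j]}\t{meta['ref'].iloc[j]}\t"
                f"{meta['alt'].iloc[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_panel_vcf(path: str | Path, source: str | None = None) -> LDPanel:
    """Read a GT-only VCF back into a panel (plain-text parser, biallelic)."""
    sample_ids: list[str] = []
    rows = []
    dosage_rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                sample_ids = fields[9:]
                continue
            chrom, pos, vid, ref, alt = fields[:5]
            rows.append(
                {"marker": vid, "chr": str(chrom), "pos": int(pos),
                 "ref": ref, "alt": alt}
            )
            dosage_rows.append(
                [gt.count("1") for gt in (f.split(":")[0] for f in fields[9:])]
            )
    meta = pd.DataFrame(rows)
    dosages = np.array(dosage_rows, dtype=np.int8).T
    return LDPanel(dosages, meta, source=source or Path(path).stem,
                   sample_ids=sample_ids)
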