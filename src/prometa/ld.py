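"""LD reference panels backed by integer dosage matrices.

A panel plays the role that METSIM-, Fenland-, or eMERGE-style genotype
reference sets play in summary-statistics analyses: it answers allele-frequency
and pairwise correlation (r, r^2) queries for the variants it covers.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REQUIRED_META = ("marker", "chr", "pos", "ref", "alt")


class LDPanel:
    """Reference genotype panel.

    Parameters
    ----------
    dosages
        ``n_samples x n_variants`` matrix of alt-allele dosages in {0, 1, 2}.
    variant_meta
        Per-variant table with at least columns ``marker, chr, pos, ref, alt``
        (``pos`` is 1-based).
    source
        Free-text label identifying the panel (e.g. a cohort name).
    """

    def __init__(
        self,
        dosages: np.ndarray,
        variant_meta: pd.DataFrame,
        source: str = "panel",
        sample_ids: Sequence[str] | None = None,
    ) -> None:
        dosages = np.ascontiguousarray(dosages)
        if dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (samples x variants) matrix")
        missing = [c for c in REQUIRED_META if c not in variant_meta.columns]
        if missing:
            raise ValueError(f"variant_meta missing columns: {missing}")
        if len(variant_meta) != dosages.shape[1]:
            raise ValueError("variant_meta rows must match dosage columns")
        if dosages.size and (dosages.min() < 0 or dosages.max() > 2):
            raise ValueError("dosage values must lie in {0, 1, 2}")
        self.dosages = dosages
        self.variant_meta = variant_meta.reset_index(drop=True)
        self.source = source
        if sample_ids is None:
            sample_ids = [f"{source}_s{i}" for i in range(dosages.shape[0])]
        self.sample_ids = list(sample_ids)
        self._index: dict[str, int] = {
            m: i for i, m in enumerate(self.variant_meta["marker"])
        }

    # -- basic shape ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    # alias used in summary-statistics formulas
    @property
    def n_panel(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def markers(self) -> list[str]:
        return list(self.variant_meta["marker"])

    def has(self, marker: str) -> bool:
        return marker in self._index

    def idx(self, markers: Iterable[str] | str) -> np.ndarray:
        if isinstance(markers, str):
            markers = [markers]
        try:
            return np.array([self._index[m] for m in markers], dtype=int)
        except KeyError as exc:  # pragma: no cover - message clarity
            raise KeyError(f"marker {exc.args[0]!r} not in panel {self.source!r}")

    # -- frequency / variance queries ---------------------------------------
    def freqs(self, markers: Iterable[str] | None = None) -> np.ndarray:
        """Empirical alt-allele frequencies."""
        d = self.dosages if markers is None else self.dosages[:, self.idx(markers)]
        return d.mean(axis=0) / 2.0

    def maf(self, markers: Iterable[str] | None = None) -> np.ndarray:
        f = self.freqs(markers)
        return np.minimum(f, 1.0 - f)

    def dosage_var(self, markers: Iterable[str] | None = None) -> np.ndarray:
        """Empirical per-variant dosage variance (population convention)."""
        d = self.dosages if markers is None else self.dosages[:, self.idx(markers)]
        return d.var(axis=0)

    # -- correlation queries -------------------------------------------------
    def corr(self, markers: Iterable[str] | None = None) -> np.ndarray:
        """Signed correlation matrix between variant dosages.

        Monomorphic variants get zero correlation with everything (and unit
        diagonal) rather than NaN, so downstream solvers see a valid matrix.
        """
        d = (
            self.dosages if markers is None else self.dosages[:, self.idx(markers)]
        ).astype(float)
        d = d - d.mean(axis=0)
        sd = d.std(axis=0)
        ok = sd > 0
        d[:, ok] /= sd[ok]
        r = d.T @ d / d.shape[0]
        r[~ok, :] = 0.0
        r[:, ~ok] = 0.0
        np.fill_diagonal(r, 1.0)
        return r

    def r(self, a: str, b: str) -> float:
        return float(self.corr([a, b])[0, 1])

    def r2(self, a: str, b: str) -> float:
        return self.r(a, b) ** 2

    def r2_with(self, marker: str) -> pd.Series:
        """r^2 of every panel variant with ``marker``."""
        j = self.idx(marker)[0]
        d = self.dosages.astype(float)
        d = d - d.mean(axis=0)
        sd = d.std(axis=0)
        x = d[:, j]
        if sd[j] == 0:
            r = np.zeros(self.n_variants)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (d.T @ x) / (self.n_samples * sd * sd[j])
            r[sd == 0] = 0.0
        r[j] = 1.0
        return pd.Series(r**2, index=self.variant_meta["marker"].to_numpy())

    def proxies(self, marker: str, r2_threshold: float = 0.8, strict: bool = True) -> list[str]:
        """Markers in LD with ``marker`` above the threshold (lead excluded)."""
        r2 = self.r2_with(marker)
        keep = r2 > r2_threshold if strict else r2 >= r2_threshold
        out = [m for m in r2.index[keep] if m != marker]
        return out

    def subset(self, markers: Iterable[str]) -> "LDPanel":
        ix = self.idx(markers)
        return LDPanel(
            self.dosages[:, ix],
            self.variant_meta.iloc[ix].reset_index(drop=True),
            source=self.source,
            sample_ids=self.sample_ids,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<LDPanel {self.source!r}: {self.n_samples} samples x "
            f"{self.n_variants} variants>"
        )
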