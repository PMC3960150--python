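"""Transcript quantification, outlier-expression detection and signature-based
pathway-activity scoring.

Pathway activity is the nearest-template cosine: per signature gene the
cohort is z-scored, and each sample's standardized vector over the signature
genes is compared with the signature's +/-1 direction vector by cosine
similarity, giving a score in [-1, 1] (positive = relative activation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with a scale tag."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    scale: str = "rpkm"  # rpkm | log2_array

    def __post_init__(self) -> None:
        if self.scale not in ("rpkm", "log2_array"):
            raise ExpressionError(f"unknown scale {self.scale!r}")
        if self.scale == "rpkm" and (self.values.values < 0).any():
            raise ExpressionError("RPKM values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.values.to_csv(path, sep="\t", index_label="gene")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, scale: str = "rpkm") -> "ExpressionMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="gene")
        frame.index.name = None
        return cls(frame, scale)


@dataclass
class SignatureTemplate:
    """Directional gene signature: (gene, +1/-1) pairs."""

    entries: list[tuple[str, int]]
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ExpressionError("signature must be non-empty")
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            raise ExpressionError("duplicate genes in signature")
        if set(genes) & set(self.excluded):
            raise ExpressionError("excluded genes present in signature")
        if any(d not in (1, -1) for _, d in self.entries):
            raise ExpressionError("directions must be +1 or -1")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(self.entries, columns=["gene", "direction"]).to_csv(
            path, sep="\t", index=False
        )
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureTemplate":
        frame = pd.read_csv(path, sep="\t")
        return cls([(r.gene, int(r.direction)) for r in frame.itertuples()])


def compute_rpkm(
    counts: pd.Series | dict[str, int],
    exonic_lengths: pd.Series | dict[str, int],
    total_mapped_reads: int,
) -> pd.Series:
    """RPKM_g = 1e9 * c_g / (L_g * N), L_g the summed exon length."""
    counts = pd.Series(counts, dtype=float)
    lengths = pd.Series(exonic_lengths, dtype=float).reindex(counts.index)
    if total_mapped_reads <= 0:
        raise ExpressionError("total mapped reads must be positive")
    if (lengths <= 0).any() or lengths.isna().any():
        raise ExpressionError("every gene needs a positive exonic length")
    return 1e9 * counts / (lengths * total_mapped_reads)


def detect_outlier_samples(
    values: pd.Series,
    background: float = 1.0,
    k: float = 5.0,
) -> list[str]:
    """Samples with expression above background and far above the cohort.

    Outlier iff value > background and value > median + k * MAD, with the
    MAD floored at 0.1 * median + eps so all-but-outlier-zero cohorts are
    still callable.
    """
    if len(values) < 10:
        raise ExpressionError("need >= 10 samples for outlier detection")
    med = float(values.median())
    mad = float((values - med).abs().median())
    eps = 1e-9
    mad = max(mad, 0.1 * med + eps)
    cut = med + k * mad
    return [s for s, v in values.items() if v > background and v > cut]


def array_background(values: pd.Series, quantile: float = 0.95) -> float:
    """Background level for array-scale data: the cohort 95th percentile."""
    return float(values.quantile(quantile))


def derive_signature(
    treated: pd.Series,
    controls: pd.DataFrame | Sequence[pd.Series],
    fold_cutoff: float = 2.0,
    exclude: Sequence[str] = (),
) -> SignatureTemplate:
    """Differential signature: treated vs mean of controls, linear scale.

    A gene enters the signature iff its linear ratio is >= fold_cutoff (up,
    direction +1) or <= 1/fold_cutoff (down, -1), boundaries inclusive;
    excluded genes (e.g. the receptor itself) are removed last.
    """
    if not isinstance(controls, pd.DataFrame):
        controls = pd.concat(list(controls), axis=1)
    if controls.shape[1] < 1:
        raise ExpressionError("need at least one control profile")
    if set(treated.index) != set(controls.index):
        raise ExpressionError("treated and control profiles cover different genes")
    mean_control = controls.mean(axis=1).reindex(treated.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = treated / mean_control
    entries = []
    for gene in treated.index:
        r = ratio[gene]
        if not np.isfinite(r):
            continue
        if r >= fold_cutoff:
            entries.append((gene, 1))
        elif r <= 1.0 / fold_cutoff:
            entries.append((gene, -1))
    excluded = [g for g in exclude if g in {g_ for g_, _ in entries}]
    entries = [(g, d) for g, d in entries if g not in set(exclude)]
    return SignatureTemplate(entries, excluded=list(exclude))


def score_activity(
    matrix: ExpressionMatrix, template: SignatureTemplate
) -> pd.Series:
    """Nearest-template cosine activity per sample, in [-1, 1].

    Signature genes missing from the matrix are dropped with a warning;
    fewer than 3 usable genes is an error.
    """
    if len(matrix.samples) < 2:
        raise ExpressionError("need >= 2 samples for per-gene standardization")
    present = [(g, d) for g, d in template.entries if g in matrix.values.index]
    missing = len(template.entries) - len(present)
    if missing:
        log.warning("score_activity: %d signature genes missing from matrix", missing)
    if len(present) < 3:
        raise ExpressionError("template too small: fewer than 3 genes present")

    genes = [g for g, _ in present]
    direction = np.array([d for _, d in present], dtype=float)
    sub = matrix.values.loc[genes]
    mean = sub.mean(axis=1)
    std = sub.std(axis=1, ddof=0).replace(0.0, np.nan)
    z = sub.sub(mean, axis=0).div(std, axis=0).fillna(0.0)

    dir_norm = np.linalg.norm(direction)
    scores = {}
    for sample in matrix.samples:
        v = z[sample].to_numpy()
        nv = np.linalg.norm(v)
        scores[sample] = float(v @ direction / (nv * dir_norm)) if nv > 0 else 0.0
    out = pd.Series(scores, name="activity")
    return out.clip(-1.0, 1.0)  # guard rounding at the exact bounds
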