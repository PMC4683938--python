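"""Marker and sample quality control.

Filters, applied in a fixed order on the currently retained data:

1. drop non-autosomal / unmapped markers
2. marker call rate
3. sample call rate
4. marker quality score (only when quality is present)
5. marker heterozygosity outliers (mean +/- k sd over markers)
6. Hardy-Weinberg exact test

Each step recomputes its statistic on what the previous steps retained; a
single pass, not iterated to convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, PopulationPartition, subset

__all__ = ["QCConfig", "QCReport", "hwe_exact_test", "heterozygosity_outlier_filter", "apply_qc"]


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for :func:`apply_qc`; defaults follow common chip QC."""

    min_marker_call_rate: float = 0.95
    min_sample_call_rate: float = 0.95
    min_quality: float = 0.6
    het_sd_window: float = 3.0
    hwe_alpha: float = 1e-16
    drop_nonautosomal: bool = True

    def __post_init__(self) -> None:
        for name in ("min_marker_call_rate", "min_sample_call_rate", "min_quality"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0.0 < self.hwe_alpha < 1.0):
            raise ValueError(f"hwe_alpha={self.hwe_alpha} outside (0, 1)")
        if self.het_sd_window <= 0:
            raise ValueError("het_sd_window must be positive")


@dataclass
class QCReport:
    """Counts removed per filter step, in application order."""

    input_markers: int = 0
    input_samples: int = 0
    removed_nonautosomal: int = 0
    removed_marker_call_rate: int = 0
    removed_sample_call_rate: int = 0
    removed_quality: int = 0
    removed_het_outlier: int = 0
    removed_hwe: int = 0
    retained_markers: int = 0
    retained_samples: int = 0

    @property
    def removed_markers_total(self) -> int:
        return (
            self.removed_nonautosomal
            + self.removed_marker_call_rate
            + self.removed_quality
            + self.removed_het_outlier
            + self.removed_hwe
        )

    def to_tsv(self, path: str | Path) -> None:
        steps = [
            ("input_markers", self.input_markers),
            ("input_samples", self.input_samples),
            ("removed_nonautosomal", self.removed_nonautosomal),
            ("removed_marker_call_rate", self.removed_marker_call_rate),
            ("removed_sample_call_rate", self.removed_sample_call_rate),
            ("removed_quality", self.removed_quality),
            ("removed_het_outlier", self.removed_het_outlier),
            ("removed_hwe", self.removed_hwe),
            ("retained_markers", self.retained_markers),
            ("retained_samples", self.retained_samples),
        ]
        with open(path, "w") as fh:
            fh.write("step\tcount\n")
            for name, count in steps:
                fh.write(f"{name}\t{count}\n")


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count (same parity as allowed by the margin) whose
    conditional probability does not exceed that of the observed count.
    Exact integer weights; p in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no data: all genotype counts zero")
    n_A = 2 * n_AA + n_Aa  # count of A gene copies; parity of het fixed by n_A

    rare = min(n_A, 2 * n - n_A)
    # weight(h) proportional to P(n_het = h | n, n_A):
    #   n! / (nAA! h! naa!) * 2^h   (margin terms constant, cancel)
    hets = range(rare % 2, rare + 1, 2)
    weights: dict[int, int] = {}
    for h in hets:
        n_hom_rare = (rare - h) // 2
        n_hom_common = n - h - n_hom_rare
        w = (
            comb(n, h)
            * comb(n - h, n_hom_rare)
            * (2**h)
        )
        weights[h] = w
    total = sum(weights.values())
    observed = weights[n_Aa]
    p = sum(w for w in weights.values() if w <= observed) / total
    return min(p, 1.0)


def _marker_het_fraction(gm: GenotypeMatrix) -> np.ndarray:
    """Observed heterozygote fraction per marker, NaN if no calls."""
    called = gm.dosages != MISSING
    n_called = called.sum(axis=0)
    n_het = ((gm.dosages == 1) & called).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)


def heterozygosity_outlier_filter(gm: GenotypeMatrix, sd_window: float = 3.0) -> np.ndarray:
    """Boolean mask over markers: True = flagged as a heterozygosity outlier.

    A marker is flagged when its observed heterozygote fraction falls
    outside mean +/- sd_window * sd computed over all markers.  Zero
    variance across markers flags nothing.
    """
    het = _marker_het_fraction(gm)
    ok = np.isfinite(het)
    if ok.sum() < 2:
        return np.zeros(gm.n_markers, dtype=bool)
    mean = het[ok].mean()
    sd = het[ok].std(ddof=0)
    if sd == 0 or not np.isfinite(sd_window):
        return np.zeros(gm.n_markers, dtype=bool)
    mask = np.zeros(gm.n_markers, dtype=bool)
    mask[ok] = np.abs(het[ok] - mean) > sd_window * sd
    return mask


def _hwe_pvalues(gm: GenotypeMatrix) -> np.ndarray:
    called = gm.dosages != MISSING
    p = np.ones(gm.n_markers)
    for j in range(gm.n_markers):
        col = gm.dosages[called[:, j], j]
        if col.size == 0:
            continue
        n_aa = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_AA = int((col == 2).sum())
        p[j] = hwe_exact_test(n_AA, n_het, n_aa)
    return p


def apply_qc(
    gm: GenotypeMatrix,
    config: QCConfig | None = None,
    partition: PopulationPartition | None = None,
    stratify_hwe: bool = False,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply all QC filters in fixed order; returns the filtered matrix and report.

    ``stratify_hwe`` tests HWE within each population of ``partition`` and
    removes a marker if it fails in any; default is a single pooled test.
    Raises ``ValueError`` (with the report attached as ``.report``) when no
    markers survive.
    """
    config = config or QCConfig()
    report = QCReport(input_markers=gm.n_markers, input_samples=gm.n_samples)

    # 1. non-autosomal / unmapped
    if config.drop_nonautosomal:
        keep = [m.id for m in gm.markers if m.is_autosomal]
        report.removed_nonautosomal = gm.n_markers - len(keep)
        gm = subset(gm, marker_ids=keep)

    # 2. marker call rate
    if gm.n_markers and gm.n_samples:
        call_rate = (gm.dosages != MISSING).mean(axis=0)
        keep = [m.id for m, cr in zip(gm.markers, call_rate) if cr >= config.min_marker_call_rate]
        report.removed_marker_call_rate = gm.n_markers - len(keep)
        gm = subset(gm, marker_ids=keep)

    # 3. sample call rate
    if gm.n_markers and gm.n_samples:
        call_rate = (gm.dosages != MISSING).mean(axis=1)
        keep_s = [s for s, cr in zip(gm.sample_ids, call_rate) if cr >= config.min_sample_call_rate]
        report.removed_sample_call_rate = gm.n_samples - len(keep_s)
        gm = subset(gm, sample_ids=keep_s)

    # 4. quality score
    if gm.has_quality:
        keep = [m.id for m in gm.markers if m.quality >= config.min_quality]
        report.removed_quality = gm.n_markers - len(keep)
        gm = subset(gm, marker_ids=keep)

    # 5. heterozygosity outliers
    if gm.n_markers:
        flagged = heterozygosity_outlier_filter(gm, config.het_sd_window)
        keep = [m.id for m, f in zip(gm.markers, flagged) if not f]
        report.removed_het_outlier = gm.n_markers - len(keep)
        gm = subset(gm, marker_ids=keep)

    # 6. HWE
    if gm.n_markers and gm.n_samples:
        if stratify_hwe and partition is not None:
            fail = np.zeros(gm.n_markers, dtype=bool)
            for pop in partition.populations:
                sub = subset(gm, sample_ids=partition.samples_in(pop))
                fail |= _hwe_pvalues(sub) < config.hwe_alpha
        else:
            fail = _hwe_pvalues(gm) < config.hwe_alpha
        keep = [m.id for m, f in zip(gm.markers, fail) if not f]
        report.removed_hwe = gm.n_markers - len(keep)
        gm = subset(gm, marker_ids=keep)

    report.retained_markers = gm.n_markers
    report.retained_samples = gm.n_samples
    if gm.n_markers == 0:
        err = ValueError("QC removed all markers")
        err.report = report  # type: ignore[attr-defined]
        raise err
    return gm, report
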