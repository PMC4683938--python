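"""VanRaden (method 1) genomic relationship matrix, summaries and PCA.

G = Z Z' / (2 sum_j p_j (1 - p_j)) where Z is the dosage matrix centered
at 2p per marker.  Missing dosages are replaced by the per-marker mean
dosage before centering; monomorphic markers are excluded from numerator
and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, PopulationPartition, subset

__all__ = ["GRM", "build_grm", "grm_summaries", "pca_from_grm", "related_pairs"]


@dataclass
class GRM:
    matrix: np.ndarray  # samples x samples, symmetric
    sample_ids: list[str]
    n_markers: int
    frequencies: np.ndarray  # per retained marker

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\t" + "\t".join(self.sample_ids) + "\n")
            for sid, row in zip(self.sample_ids, self.matrix):
                fh.write(sid + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")


def build_grm(gm: GenotypeMatrix, frequencies: np.ndarray | None = None) -> GRM:
    """Build the relationship matrix; reference frequencies default to the
    analyzed samples' own ("own" mode).

    Raises ``ValueError`` when no polymorphic marker remains.
    """
    d = gm.dosages.astype(float)
    miss = gm.dosages == MISSING
    n_called = (~miss).sum(axis=0)
    col_mean = np.where(n_called > 0, np.where(miss, 0, d).sum(axis=0) / np.maximum(n_called, 1), np.nan)
    d = np.where(miss, col_mean, d)  # mean-impute missing dosages

    if frequencies is None:
        p = col_mean / 2.0
    else:
        p = np.asarray(frequencies, dtype=float)
        if p.shape != (gm.n_markers,):
            raise ValueError("frequencies length must match marker count")
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic markers")
    z = d[:, poly] - 2.0 * p[poly]
    denom = 2.0 * float((p[poly] * (1 - p[poly])).sum())
    g = z @ z.T / denom
    g = (g + g.T) / 2.0
    return GRM(g, list(gm.sample_ids), int(poly.sum()), p[poly])


def grm_summaries(
    gm: GenotypeMatrix,
    partition: PopulationPartition,
    pooled_frequencies: bool = False,
) -> dict[str, tuple[float, float]]:
    """Per-population (mean diagonal, mean upper-triangle off-diagonal).

    By default each population's GRM is built separately with its own
    within-population frequencies; ``pooled_frequencies`` uses frequencies
    from the full sample set instead.  Populations of one sample report
    NaN off-diagonal.
    """
    partition.validate_against(gm)
    pooled_p = None
    if pooled_frequencies:
        pooled_p = build_grm(gm).frequencies  # frequencies over retained markers only
        # recompute over all markers for alignment
        d = gm.dosages.astype(float)
        miss = gm.dosages == MISSING
        n_called = (~miss).sum(axis=0)
        pooled_p = np.where(n_called > 0, np.where(miss, 0, d).sum(axis=0) / (2 * np.maximum(n_called, 1)), np.nan)
    out: dict[str, tuple[float, float]] = {}
    for pop in partition.populations:
        sub = subset(gm, sample_ids=partition.samples_in(pop))
        grm = build_grm(sub, frequencies=pooled_p)
        diag = float(np.diag(grm.matrix).mean())
        n = len(grm.sample_ids)
        if n < 2:
            out[pop] = (diag, float("nan"))
        else:
            iu = np.triu_indices(n, k=1)
            out[pop] = (diag, float(grm.matrix[iu].mean()))
    return out


def related_pairs(grm: GRM, threshold: float = 0.25) -> list[tuple[str, str, float]]:
    """Off-diagonal pairs above ``threshold`` (relationship-status check)."""
    n = len(grm.sample_ids)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if grm.matrix[i, j] > threshold:
                out.append((grm.sample_ids[i], grm.sample_ids[j], float(grm.matrix[i, j])))
    return out


def pca_from_grm(grm: GRM, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of G: (coordinates, explained-variance fractions).

    Coordinates are eigenvectors scaled by sqrt(eigenvalue), ordered by
    descending eigenvalue, sign fixed so the largest-magnitude loading of
    each component is positive.
    """
    if n_components > len(grm.sample_ids):
        raise ValueError("n_components exceeds sample count")
    if not np.isfinite(grm.matrix).all():
        raise ValueError("non-finite entries in G")
    vals, vecs = np.linalg.eigh(grm.matrix)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals_clipped = np.clip(vals, 0.0, None)
    total = vals_clipped.sum()
    explained = vals_clipped[:n_components] / total if total > 0 else np.zeros(n_components)
    coords = vecs[:, :n_components] * np.sqrt(vals_clipped[:n_components])
    for k in range(n_components):
        i = int(np.argmax(np.abs(vecs[:, k])))
        if vecs[i, k] < 0:
            coords[:, k] *= -1.0
    return coords, explained
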