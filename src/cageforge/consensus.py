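"""Consensus promoters across samples and expression-profile clustering.

Tag clusters called independently in each sample are projected onto the
genome and merged per strand into consensus clusters — one promoter region
per locus for all samples — after which per-sample expression is recomputed
from the CTSS signal inside the consensus span.  Expression profiles over
the promoter x sample matrix are grouped with k-means or a rectangular
self-organizing map (SOM), whose grid arranges similar profiles on
neighbouring units.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Optional

import numpy as np
import pandas as pd

from .cluster import TagCluster, annotate_dominant
from .ctss import CtssTable

DEFAULT_MAX_GAP = 100
DEFAULT_TPM_THRESHOLD = 5.0


@dataclasses.dataclass
class ConsensusCluster:
    id: str
    chrom: str
    start: int
    end: int
    strand: str
    per_sample_total: dict
    per_sample_dominant: dict
    member_tag_clusters: list  # (sample_id, tag cluster id)

    @property
    def total(self) -> float:
        return float(sum(self.per_sample_total.values()))


def build_consensus(tag_clusters: dict, table: CtssTable,
                    tpm_threshold: float = DEFAULT_TPM_THRESHOLD,
                    max_gap: int = DEFAULT_MAX_GAP) -> list[ConsensusCluster]:
    """Merge per-sample tag clusters into cross-sample consensus clusters.

    ``tag_clusters`` maps sample id -> list of TagCluster called on the
    *normalized* table.  Clusters with total signal >= tpm_threshold are
    projected per (chrom, strand); projections separated by at most
    ``max_gap`` bp are merged transitively.  Per-sample totals and dominant
    TSSs are then recomputed from the CTSS signal within the span, including
    samples whose own clusters fell below threshold.
    """
    if not table.normalized:
        raise ValueError("build_consensus expects a normalized CtssTable "
                         "(tag clusters and signal on one scale)")
    proj: dict[tuple, list] = {}
    for sample, clusters in tag_clusters.items():
        for cl in clusters:
            if cl.total_signal >= tpm_threshold:
                proj.setdefault((cl.chrom, cl.strand), []).append(
                    (cl.start, cl.end, sample, cl.id))
    out: list[ConsensusCluster] = []
    for (chrom, strand), ivs in sorted(proj.items()):
        ivs.sort()
        merged: list[list] = []
        for start, end, sample, cid in ivs:
            if merged and start - merged[-1][1] <= max_gap:
                merged[-1][1] = max(merged[-1][1], end)
                merged[-1][2].append((sample, cid))
            else:
                merged.append([start, end, [(sample, cid)]])
        for start, end, members in merged:
            sub = table.subset(chrom, strand, start, end)
            totals, doms = {}, {}
            pos = sub["pos"].to_numpy()
            for s in table.sample_ids:
                sig = sub[s].to_numpy()
                totals[s] = float(sig.sum())
                if totals[s] > 0:
                    doms[s], _ = annotate_dominant(pos[sig > 0], sig[sig > 0],
                                                   strand)
            out.append(ConsensusCluster(
                id=f"{chrom}:{start}-{end},{strand}", chrom=chrom,
                start=start, end=end, strand=strand, per_sample_total=totals,
                per_sample_dominant=doms, member_tag_clusters=members))
    return out


def expression_matrix(consensus: list[ConsensusCluster],
                      table: CtssTable) -> pd.DataFrame:
    """Promoter x sample matrix of summed signal within each consensus span."""
    rows = {}
    for cc in consensus:
        sub = table.subset(cc.chrom, cc.strand, cc.start, cc.end)
        rows[cc.id] = [float(sub[s].sum()) for s in table.sample_ids]
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(table.sample_ids))


def scale_profiles(matrix: pd.DataFrame, min_signal: float = DEFAULT_TPM_THRESHOLD,
                   method: str = "zscore"):
    """log2(x+1) then per-row standardization; weak/constant rows dropped.

    Returns (scaled DataFrame, kept row index).  ``method='rowmax'`` divides
    the logged row by its maximum instead of z-scoring.
    """
    mat = matrix.to_numpy(dtype=float)
    keep = mat.max(axis=1) >= min_signal
    logged = np.log2(mat[keep] + 1.0)
    if method == "zscore":
        sd = logged.std(axis=1)
        ok = sd > 0
        scaled = (logged[ok] - logged[ok].mean(axis=1, keepdims=True)) \
            / sd[ok][:, None]
    elif method == "rowmax":
        mx = logged.max(axis=1)
        ok = mx > 0
        scaled = logged[ok] / mx[ok][:, None]
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    idx = matrix.index[keep][ok]
    return pd.DataFrame(scaled, index=idx, columns=matrix.columns), idx


@dataclasses.dataclass
class ExpressionClustering:
    algorithm: str
    labels: pd.Series        # promoter id -> class id
    centroids: np.ndarray    # class x sample
    seed: int
    grid: Optional[tuple] = None
    objective_history: Optional[list] = None
    scaled_matrix_digest: str = ""


def _digest(mat: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(mat, dtype=np.float64)
                          .tobytes()).hexdigest()


def kmeans_profiles(scaled: pd.DataFrame, k: int, seed: int = 0,
                    n_init: int = 10, max_iter: int = 300) -> ExpressionClustering:
    """Lloyd's k-means, best of ``n_init`` seeded random initializations.

    The within-class sum of squares is recorded per iteration of the winning
    run; it is non-increasing by construction of the algorithm.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = scaled.to_numpy(dtype=float)
    if k > len(X):
        raise ValueError("k exceeds the number of profiles")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centres = X[rng.choice(len(X), size=k, replace=False)].copy()
        history = []
        labels = None
        for _ in range(max_iter):
            d2 = ((X[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
            new_labels = d2.argmin(axis=1)
            history.append(float(d2[np.arange(len(X)), new_labels].sum()))
            if labels is not None and np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                m = labels == c
                if m.any():
                    centres[c] = X[m].mean(axis=0)
        if best is None or history[-1] < best[2][-1]:
            best = (labels, centres, history)
    labels, centres, history = best
    return ExpressionClustering(
        algorithm="kmeans", labels=pd.Series(labels, index=scaled.index),
        centroids=centres, seed=seed, objective_history=history,
        scaled_matrix_digest=_digest(X))


def som_profiles(scaled: pd.DataFrame, xdim: int, ydim: int, seed: int = 0,
                 n_updates: Optional[int] = None, lr0: float = 0.1,
                 radius0: Optional[float] = None) -> ExpressionClustering:
    """Online self-organizing map on an xdim x ydim rectangular grid.

    Codebook vectors start from random data rows; each update pulls the
    best-matching unit (BMU) and its Gaussian neighbourhood toward one
    profile, with learning rate and radius decaying linearly to ~0.  The
    trained map places similar expression profiles on adjacent units.
    """
    if xdim < 1 or ydim < 1:
        raise ValueError("SOM grid dimensions must be >= 1")
    X = scaled.to_numpy(dtype=float)
    n_units = xdim * ydim
    if n_units > len(X):
        import warnings
        warnings.warn("SOM grid has more units than profiles")
    rng = np.random.default_rng(seed)
    if n_updates is None:
        n_updates = 200 * len(X)
    if radius0 is None:
        radius0 = max(xdim, ydim) / 2.0
    grid = np.array([(i, j) for i in range(xdim) for j in range(ydim)], float)
    code = X[rng.choice(len(X), size=n_units, replace=n_units > len(X))].copy()
    order = rng.integers(0, len(X), size=n_updates)
    for t, ridx in enumerate(order):
        frac = 1.0 - t / n_updates
        lr = max(lr0 * frac, 1e-3)
        sigma = max(radius0 * frac, 0.05)
        x = X[ridx]
        bmu = int(((code - x) ** 2).sum(axis=1).argmin())
        d2 = ((grid - grid[bmu]) ** 2).sum(axis=1)
        h = np.exp(-d2 / (2.0 * sigma ** 2))
        code += lr * h[:, None] * (x - code)
    labels = ((X[:, None, :] - code[None, :, :]) ** 2).sum(axis=2).argmin(axis=1)
    return ExpressionClustering(
        algorithm="som", labels=pd.Series(labels, index=scaled.index),
        centroids=code, seed=seed, grid=(xdim, ydim),
        scaled_matrix_digest=_digest(X))
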