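"""TSS clustering: distance-based (distclu), density-based (paraclu), custom.

CTSSs on one strand are grouped into tag clusters, the per-sample view of a
promoter.  ``distclu`` merges neighbours within a fixed distance; ``paraclu``
recursively segments the signal at its weakest prefix/suffix density,
producing nested candidate clusters that are stable across a range of
initiation-density thresholds; ``custom`` assigns CTSSs to user-provided
windows (e.g. around annotated TSSs).  Every cluster records its dominant
(highest-signal) TSS.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
import pandas as pd

from .ctss import CtssTable, GenomicWindow

DEFAULT_MAX_DIST = 20
DEFAULT_MIN_STABILITY = 2.0
DEFAULT_MAX_LENGTH = 500


@dataclasses.dataclass
class TagCluster:
    """One promoter in one sample: contiguous CTSS run with a dominant TSS."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    sample_id: str
    n_ctss: int
    total_signal: float
    dominant_pos: int
    dominant_signal: float
    min_density: Optional[float] = None
    max_density: Optional[float] = None
    iq_positions: Optional[dict] = None  # quantile -> 1-based position
    iq_width: Optional[int] = None
    shape_class: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.start <= self.dominant_pos <= self.end:
            raise ValueError(f"cluster {self.id}: dominant TSS outside span")
        if self.dominant_signal <= 0 or self.total_signal < self.dominant_signal - 1e-9:
            raise ValueError(f"cluster {self.id}: inconsistent signal totals")
        if (self.min_density is not None and self.max_density is not None
                and self.max_density < self.min_density):
            raise ValueError(f"cluster {self.id}: max_density < min_density")

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def filter_ctss(table: CtssTable, threshold: float, n_pass: int = 1) -> np.ndarray:
    """Keep a CTSS iff its signal is >= threshold in at least n_pass samples."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if n_pass > len(table.sample_ids):
        raise ValueError("n_pass exceeds the number of samples")
    mat = table.data[table.sample_ids].to_numpy()
    if threshold == 0:
        return (mat > 0).sum(axis=1) >= n_pass
    return (mat >= threshold).sum(axis=1) >= n_pass


def _iter_groups(table: CtssTable, sample: str, mask=None):
    d = table.data if mask is None else table.data.loc[mask]
    d = d[d[sample] > 0]
    for (chrom, strand), grp in d.groupby(["chrom", "strand"], sort=True):
        yield chrom, strand, grp["pos"].to_numpy(), grp[sample].to_numpy()


def cluster_dist(table: CtssTable, sample: str,
                 max_dist: int = DEFAULT_MAX_DIST, mask=None) -> list[TagCluster]:
    """Transitively merge same-strand CTSSs at distance <= max_dist."""
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    clusters = []
    for chrom, strand, pos, sig in _iter_groups(table, sample, mask):
        breaks = np.flatnonzero(np.diff(pos) > max_dist)
        bounds = np.concatenate([[0], breaks + 1, [len(pos)]])
        for i, j in zip(bounds[:-1], bounds[1:]):
            clusters.append(_make_cluster(
                f"{sample}:{chrom}:{pos[i]}:{strand}", chrom, strand, sample,
                pos[i:j], sig[i:j]))
    return clusters


def _make_cluster(cid, chrom, strand, sample, pos, sig,
                  min_density=None, max_density=None) -> TagCluster:
    dom, domsig = annotate_dominant(pos, sig, strand)
    return TagCluster(id=cid, chrom=chrom, start=int(pos[0]), end=int(pos[-1]),
                      strand=strand, sample_id=sample, n_ctss=len(pos),
                      total_signal=float(sig.sum()), dominant_pos=dom,
                      dominant_signal=domsig, min_density=min_density,
                      max_density=max_density)


def annotate_dominant(pos: np.ndarray, sig: np.ndarray, strand: str):
    """Dominant TSS = argmax signal; ties resolved toward the
    signal-weighted centre of the cluster, then 5'-most."""
    best = sig.max()
    cand = pos[sig >= best - 1e-12]
    if len(cand) == 1:
        return int(cand[0]), float(best)
    centre = float(np.average(pos, weights=sig))
    dist = np.abs(cand - centre)
    near = cand[dist <= dist.min() + 1e-9]
    dom = near.min() if strand != "-" else near.max()
    return int(dom), float(best)


# ---------------------------------------------------------------------------
# paraclu


def _paraclu_segments(pos: np.ndarray, sig: np.ndarray):
    """Recursive weakest-link segmentation.

    Yields (i, j, min_density, max_density) over site-index ranges
    (inclusive).  A segment's max_density is the weakest density over its
    proper prefixes and suffixes (total signal / genomic span); it splits at
    the minimizing boundary and children inherit min_density from it.
    Singletons are unsplittable and get max_density = +inf.
    """
    csum = np.concatenate([[0.0], np.cumsum(sig)])
    stack = [(0, len(pos) - 1, 0.0)]
    while stack:
        i, j, min_d = stack.pop()
        if i == j:
            yield i, j, min_d, math.inf
            continue
        # prefixes end at k in [i, j-1]; suffixes start at k in [i+1, j]
        ks = np.arange(i, j)
        pre_d = (csum[ks + 1] - csum[i]) / (pos[ks] - pos[i] + 1)
        suf_d = (csum[j + 1] - csum[ks + 1]) / (pos[j] - pos[ks + 1] + 1)
        kp = int(np.argmin(pre_d))
        ksuf = int(np.argmin(suf_d))
        if pre_d[kp] <= suf_d[ksuf]:
            max_d, split = float(pre_d[kp]), i + kp  # prefix i..split
            children = ((i, split), (split + 1, j))
        else:
            max_d, split = float(suf_d[ksuf]), i + ksuf + 1  # suffix split..j
            children = ((i, split - 1), (split, j))
        yield i, j, min_d, max_d
        for a, b in children:
            stack.append((a, b, max_d))


def cluster_paraclu(table: CtssTable, sample: str,
                    min_stability: float = DEFAULT_MIN_STABILITY,
                    max_length: int = DEFAULT_MAX_LENGTH,
                    min_total: float = 0.0, mask=None,
                    keep: str = "outermost",
                    keep_nested: bool = False) -> list[TagCluster]:
    """Density-based nested clustering, flattened to non-overlapping clusters.

    Candidates from the recursive segmentation are kept when stable
    (max_density / min_density >= min_stability), short enough and
    sufficiently expressed; surviving candidates form a laminar family and
    are flattened by keeping the outermost (default) or densest members.
    ``keep_nested`` returns the full filtered hierarchy instead.
    """
    if min_stability < 1:
        raise ValueError("min_stability must be >= 1")
    clusters = []
    for chrom, strand, pos, sig in _iter_groups(table, sample, mask):
        cands = []
        for i, j, min_d, max_d in _paraclu_segments(pos, sig):
            total = float(sig[i:j + 1].sum())
            length = int(pos[j] - pos[i] + 1)
            stab = math.inf if min_d == 0 else max_d / min_d
            if stab >= min_stability and length <= max_length and total >= min_total:
                cands.append((i, j, min_d, max_d))
        if keep_nested:
            chosen = sorted(cands, key=lambda c: (c[0], -c[1]))
        else:
            chosen = _flatten(cands, sig, keep)
        for i, j, min_d, max_d in chosen:
            clusters.append(_make_cluster(
                f"{sample}:{chrom}:{pos[i]}:{strand}", chrom, strand, sample,
                pos[i:j + 1], sig[i:j + 1], min_density=min_d, max_density=max_d))
    return clusters


def _flatten(cands, sig, keep: str):
    """Reduce a laminar candidate family to disjoint members."""
    if keep == "outermost":
        chosen = []
        last_end = -1
        for i, j, min_d, max_d in sorted(cands, key=lambda c: (c[0], -c[1])):
            if i > last_end:
                chosen.append((i, j, min_d, max_d))
                last_end = j
        return chosen
    if keep == "densest":
        # prefer high max_density; on ties prefer the larger segment
        chosen = []
        taken = set()
        for i, j, min_d, max_d in sorted(
                cands, key=lambda c: (-c[3], c[0] - c[1])):
            if taken.isdisjoint(range(i, j + 1)):
                chosen.append((i, j, min_d, max_d))
                taken.update(range(i, j + 1))
        return sorted(chosen)
    raise ValueError(f"unknown flattening rule {keep!r}")


# ---------------------------------------------------------------------------
# custom windows


def cluster_custom(table: CtssTable, sample: str,
                   windows: list[GenomicWindow], mask=None) -> list[TagCluster]:
    """Assign CTSSs to predefined windows; windows may overlap.

    A CTSS joins every window that contains it; unstranded ('.') windows
    collect both strands.  Windows without signal are dropped.
    """
    d = table.data if mask is None else table.data.loc[mask]
    d = d[d[sample] > 0]
    clusters = []
    for w_idx, w in enumerate(windows):
        m = (d["chrom"] == w.chrom) & (d["pos"] >= w.start) & (d["pos"] <= w.end)
        if w.strand in ("+", "-"):
            m &= d["strand"] == w.strand
        sub = d.loc[m].sort_values("pos")
        if not len(sub):
            continue
        pos = sub["pos"].to_numpy()
        sig = sub[sample].to_numpy()
        # collapse duplicate positions (both strands in an unstranded window)
        if len(np.unique(pos)) != len(pos):
            agg = sub.groupby("pos")[sample].sum()
            pos, sig = agg.index.to_numpy(), agg.to_numpy()
        strand = w.strand if w.strand in ("+", "-") else "+"
        cl = _make_cluster(w.name or f"{sample}:window{w_idx}", w.chrom,
                           strand, sample, pos, sig)
        cl.strand = w.strand
        clusters.append(cl)
    return clusters


def clusters_to_frame(clusters: list[TagCluster]) -> pd.DataFrame:
    rows = [dataclasses.asdict(c) for c in clusters]
    df = pd.DataFrame(rows)
    if len(df):
        df = df.drop(columns=["iq_positions"])
    return df
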