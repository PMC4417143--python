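"""Promoter width and sequence features around the dominant TSS.

Promoter width is measured as the interquantile width: walking along the
cluster in transcription direction, the positions where the cumulative CAGE
signal first reaches q_low and q_up of the total delimit the central region
holding (q_up - q_low) of the tags.  Unlike the full cluster span this is
robust to sequencing depth, and thresholding it separates sharp promoters
(one dominant TSS) from broad ones (dispersed initiation).

Sequence scans anchored at the dominant TSS are provided for the TATA box
(PWM match in the -35..-22 window, reported as percent of the maximal
score) and for dinucleotide-frequency profiles (e.g. the WW periodicity
downstream of broad promoters that tracks nucleosome positioning).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .cluster import TagCluster

DEFAULT_QUANTILES = (0.1, 0.9)
DEFAULT_SHARP_MAX_WIDTH = 10
TATA_WINDOW = (-35, -22)

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclasses.dataclass
class QuantileAnnotation:
    q_low: float
    q_up: float
    pos_low: int   # 1-based genomic position where cumulative >= q_low
    pos_up: int
    iq_width: int
    shape_class: str = "unassigned"

    def __post_init__(self) -> None:
        if not 0 < self.q_low < self.q_up < 1:
            raise ValueError("need 0 < q_low < q_up < 1")
        if self.iq_width != abs(self.pos_up - self.pos_low) + 1:
            raise ValueError("iq_width inconsistent with quantile positions")


def quantile_positions(pos: np.ndarray, sig: np.ndarray, strand: str,
                       q_low: float = DEFAULT_QUANTILES[0],
                       q_up: float = DEFAULT_QUANTILES[1]) -> QuantileAnnotation:
    """Positions where cumulative signal first reaches q_low / q_up of total.

    The walk is 5'->3' in transcription direction (descending genomic
    coordinate on the minus strand); "reaches" is >=, so a single position
    holding all signal yields width 1 for any quantile pair.
    """
    if not 0 < q_low < q_up < 1:
        raise ValueError("need 0 < q_low < q_up < 1")
    pos = np.asarray(pos)
    sig = np.asarray(sig, dtype=float)
    order = np.argsort(pos)
    if strand == "-":
        order = order[::-1]
    p, s = pos[order], sig[order]
    total = s.sum()
    if total <= 0:
        raise ValueError("quantile positions need positive total signal")
    cum = np.cumsum(s)
    i_low = int(np.searchsorted(cum, q_low * total - 1e-9 * total))
    i_up = int(np.searchsorted(cum, q_up * total - 1e-9 * total))
    plo, pup = int(p[i_low]), int(p[i_up])
    return QuantileAnnotation(q_low=q_low, q_up=q_up, pos_low=plo, pos_up=pup,
                              iq_width=abs(pup - plo) + 1)


def classify_shape(iq_width: int,
                   sharp_max_width: int = DEFAULT_SHARP_MAX_WIDTH) -> str:
    """Sharp iff the interquantile width is at most sharp_max_width bp."""
    if iq_width < 1:
        raise ValueError("iq_width must be >= 1")
    return "sharp" if iq_width <= sharp_max_width else "broad"


def annotate_cluster_shape(cluster: TagCluster, pos, sig,
                           q_low: float = DEFAULT_QUANTILES[0],
                           q_up: float = DEFAULT_QUANTILES[1],
                           sharp_max_width: int = DEFAULT_SHARP_MAX_WIDTH) -> TagCluster:
    """Attach quantile positions, interquantile width and shape class."""
    qa = quantile_positions(pos, sig, cluster.strand, q_low, q_up)
    cluster.iq_positions = {q_low: qa.pos_low, q_up: qa.pos_up}
    cluster.iq_width = qa.iq_width
    cluster.shape_class = classify_shape(qa.iq_width, sharp_max_width)
    return cluster


# ---------------------------------------------------------------------------
# PWM scanning


class Pwm:
    """Position weight matrix with log-odds scoring.

    Built from a count (PFM) matrix: counts plus a total pseudocount of 0.8
    split by background frequency are normalized to probabilities, then
    log2-odds against the background are taken.  JASPAR-format text files
    are parsed with Bio.motifs.
    """

    def __init__(self, counts: np.ndarray, background=None,
                 pseudocount: float = 0.8, name: str = ""):
        counts = np.asarray(counts, dtype=float)  # shape (4, L), rows ACGT
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError("PWM counts must be a 4 x L matrix")
        bg = np.asarray(background if background is not None else [0.25] * 4)
        bg = bg / bg.sum()
        probs = counts + pseudocount * bg[:, None]
        probs = probs / probs.sum(axis=0, keepdims=True)
        self.name = name
        self.probs = probs
        self.logodds = np.log2(probs / bg[:, None])
        self.length = counts.shape[1]
        self.min_score = float(self.logodds.min(axis=0).sum())
        self.max_score = float(self.logodds.max(axis=0).sum())

    @classmethod
    def from_jaspar(cls, path, **kw) -> "Pwm":
        from Bio import motifs
        with open(path) as fh:
            m = motifs.read(fh, "jaspar")
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        return cls(counts, name=m.name or "", **kw)

    def score(self, seq: str) -> float:
        """Log-odds score of one L-length sequence (N scores as background)."""
        if len(seq) != self.length:
            raise ValueError("sequence length != PWM length")
        idx = ["ACGT".find(b) for b in seq.upper()]
        return float(sum(self.logodds[i, j] if i >= 0 else 0.0
                         for j, i in enumerate(idx)))

    def best_match_percent(self, seq: str) -> float:
        """Best sliding-window score as percent of the attainable range."""
        if len(seq) < self.length:
            raise ValueError("sequence shorter than the PWM")
        best = max(self.score(seq[i:i + self.length])
                   for i in range(len(seq) - self.length + 1))
        return 100.0 * (best - self.min_score) / (self.max_score - self.min_score)


def extract_window(genome, chrom: str, anchor: int, strand: str,
                   from_bp: int, to_bp: int) -> str:
    """Transcription-orientation sequence for offsets [from_bp, to_bp]
    relative to a 1-based anchor (offset 0 = anchor base)."""
    if from_bp > to_bp:
        raise ValueError("from_bp > to_bp")
    seq = genome[chrom] if isinstance(genome, dict) else str(genome[chrom][:])
    n = len(seq)
    if strand == "-":
        lo, hi = anchor - to_bp, anchor - from_bp
    else:
        lo, hi = anchor + from_bp, anchor + to_bp
    if lo < 1 or hi > n:
        raise ValueError(
            f"window {chrom}:{lo}-{hi} outside contig bounds (1-{n})")
    sub = seq[lo - 1:hi].upper()
    return _revcomp(sub) if strand == "-" else sub


def scan_pwm_upstream(genome, chrom: str, dominant_pos: int, strand: str,
                      pwm: Pwm, from_bp: int = TATA_WINDOW[0],
                      to_bp: int = TATA_WINDOW[1]) -> float:
    """Best PWM match (percent of maximum) in a window upstream of the
    dominant TSS, scanned in transcription orientation."""
    window = extract_window(genome, chrom, dominant_pos, strand, from_bp, to_bp)
    return pwm.best_match_percent(window)


# ---------------------------------------------------------------------------
# dinucleotide profiles

WW = frozenset({"AA", "AT", "TA", "TT"})
SS = frozenset({"CC", "CG", "GC", "GG"})


def dinucleotide_profile(genome, anchors, dinucleotide_class=WW,
                         flank=(-200, 200)) -> np.ndarray:
    """Per-offset frequency of a dinucleotide class around anchors.

    ``anchors`` are (chrom, pos, strand) triples; offsets run in
    transcription orientation with 0 at the anchor; the dinucleotide at
    offset o spans offsets o and o+1.  Returns frequencies for offsets
    flank[0] .. flank[1] inclusive.
    """
    anchors = list(anchors)
    if not anchors:
        raise ValueError("dinucleotide_profile needs at least one anchor")
    lo, hi = flank
    width = hi - lo + 1
    hits = np.zeros(width)
    cover = np.zeros(width)
    dinucs = frozenset(d.upper() for d in dinucleotide_class)
    for chrom, pos, strand in anchors:
        seq = extract_window(genome, chrom, pos, strand, lo, hi + 1)
        for o in range(width):
            di = seq[o:o + 2]
            if "N" in di:
                continue
            cover[o] += 1
            if di in dinucs:
                hits[o] += 1
    with np.errstate(invalid="ignore"):
        freq = np.where(cover > 0, hits / np.maximum(cover, 1), np.nan)
    return freq
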