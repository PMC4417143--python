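"""Correction of the 5' G-addition bias of the CAGE protocol.

During cDNA preparation the reverse transcriptase often appends a
template-free G to the 5' end of a tag.  After mapping, such tags report a
TSS one base upstream (in transcription direction) of the true start.  Two
corrections are provided:

* ``simple`` — per read: if the first (transcription-strand) base is a G
  that does not match the genome, the added base is certain and the 5' end
  is shifted one base downstream.
* ``systematic`` — per position: reads whose first G mismatches the genome
  are certain additions and are all moved downstream; the addition rate
  rho is estimated from these unambiguous reads (mismatch-G vs non-G
  starts); reads starting on a genomic G are ambiguous, and the expected
  number of added-G reads among them is inferred from rho and the
  already-corrected signal one base downstream, sweeping 3'->5' so each
  genomic-G position sees its corrected downstream neighbour.

Both modes conserve the total tag count exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .ctss import CtssTable, CtssTableError, _genome_base


@dataclasses.dataclass
class GCorrectionStats:
    """Bookkeeping of a systematic G-correction run.

    ``rho_hat`` estimates the per-tag G-addition probability from
    unambiguous reads; ``n_shifted`` counts tags moved downstream.
    """

    rho_hat: float
    n_mismatch_G: int
    n_match_G: int
    n_nonG: int
    n_shifted: int

    def __post_init__(self) -> None:
        if not 0 <= self.rho_hat < 1:
            raise ValueError(f"rho_hat {self.rho_hat} outside [0, 1)")
        if self.n_shifted > self.n_mismatch_G + self.n_match_G:
            raise ValueError("shifted more reads than carry a 5' G")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def correct_simple(read_first_base: str, genome_base_at_5prime: str,
                   pos5: int, strand: str) -> int:
    """Shift a read's 5' position if its first base is a mismatching G.

    The shift is one base in transcription direction: +1 genomic on the plus
    strand, -1 on the minus strand.  'N' in either role never shifts.
    """
    if read_first_base == "G" and genome_base_at_5prime != "G":
        return pos5 + 1 if strand == "+" else pos5 - 1
    return pos5


def correct_systematic(flagged: pd.DataFrame, genome,
                       sample_id: str = "sample_1"):
    """Redistribute G-started tags; returns (CtssTable, GCorrectionStats).

    ``flagged`` columns: chrom, pos, strand, firstG_mismatch, firstG_match,
    non_G (per-position read counts by first-base class).  ``genome`` is a
    pyfaidx.Fasta (or mapping of chrom -> sequence) used to test whether a
    position's transcription-strand base is G.
    """
    req = {"chrom", "pos", "strand", "firstG_mismatch", "firstG_match", "non_G"}
    if not req <= set(flagged.columns):
        raise ValueError(f"flagged table missing columns {req - set(flagged.columns)}")

    n_mm = int(flagged["firstG_mismatch"].sum())
    n_match = int(flagged["firstG_match"].sum())
    n_nonG = int(flagged["non_G"].sum())
    denom = n_mm + n_nonG
    rho = n_mm / denom if denom else 0.0
    if rho >= 1.0:  # degenerate: no unambiguous non-G starts observed
        rho = n_mm / (n_mm + 1.0)

    # corrected per-position totals
    corrected: dict[tuple, float] = {}
    for row in flagged.itertuples(index=False):
        key = (row.chrom, row.strand, int(row.pos))
        base = row.firstG_match + row.non_G
        if base:
            corrected[key] = corrected.get(key, 0.0) + base
        if row.firstG_mismatch:  # certain additions: move downstream
            dkey = _downstream(key)
            corrected[dkey] = corrected.get(dkey, 0.0) + row.firstG_mismatch
    n_shifted = n_mm

    if rho > 0 and n_match:
        ratio = rho / (1.0 - rho)
        # genomic-G positions, swept 3'->5' along each strand so the
        # downstream neighbour is already corrected when we reach a position
        amb = flagged[flagged["firstG_match"] > 0]
        order = []
        for row in amb.itertuples(index=False):
            key = (row.chrom, row.strand, int(row.pos))
            if _is_genomic_G(genome, key):
                order.append((key, int(row.firstG_match)))
        order.sort(key=lambda kv: kv[0][2], reverse=True)  # high pos first
        for key, avail in order:
            if key[1] == "-":
                continue
            n_shifted += _move_ambiguous(corrected, key, avail, ratio)
        # minus strand: 3' end is at LOW genomic coordinates
        for key, avail in sorted(order, key=lambda kv: kv[0][2]):
            if key[1] == "+":
                continue
            n_shifted += _move_ambiguous(corrected, key, avail, ratio)

    keys = sorted(corrected)
    records = [(c, p, s) for (c, s, p) in keys]
    counts = np.array([[corrected[k]] for k in keys], dtype=float) \
        if keys else np.empty((0, 1))
    table = CtssTable.from_records(records, counts, [sample_id])
    stats = GCorrectionStats(rho_hat=rho, n_mismatch_G=n_mm,
                             n_match_G=n_match, n_nonG=n_nonG,
                             n_shifted=int(n_shifted))
    return table, stats


def _downstream(key: tuple) -> tuple:
    chrom, strand, pos = key
    return (chrom, strand, pos + 1 if strand == "+" else pos - 1)


def _is_genomic_G(genome, key: tuple) -> bool:
    chrom, strand, pos = key
    if isinstance(genome, dict):
        seq = genome[chrom]
        if not 1 <= pos <= len(seq):
            raise CtssTableError(f"genome base unavailable at {chrom}:{pos}")
        base = seq[pos - 1].upper()
        if strand == "-":
            base = {"A": "T", "C": "G", "G": "C", "T": "A"}.get(base, "N")
        return base == "G"
    return _genome_base(genome, chrom, pos, strand) == "G"


def _move_ambiguous(corrected: dict, key: tuple, avail: int,
                    ratio: float) -> int:
    dkey = _downstream(key)
    target = ratio * corrected.get(dkey, 0.0)
    moved = min(avail, _round_half_even(target))
    if moved > 0:
        corrected[key] = corrected.get(key, 0.0) - moved
        if corrected[key] <= 0:
            if corrected[key] < -1e-9:
                raise AssertionError("moved more signal than present")
            del corrected[key]
        corrected[dkey] = corrected.get(dkey, 0.0) + moved
    return moved


def _round_half_even(x: float) -> int:
    return int(np.round(x))
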