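"""CTSS tables: single-base TSS signal keyed by (chrom, pos, strand).

A CTSS (CAGE-detected transcription start site) is one genomic base with a
per-sample tag count reflecting how often transcription initiated there.
This module reads and writes the tab-separated CTSS flat-file layout, calls
CTSSs from mapped CAGE tags, and exports genome-browser tracks (strand-split
bedGraph for raw signal, BED12 for clusters with their interquantile span).

All in-memory positions are 1-based inclusive; all exported track formats
use 0-based half-open coordinates.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-")

#: fixed palette for expression-class coloring of BED12 tracks (RGB strings)
CLASS_PALETTE = (
    "228,26,28", "55,126,184", "77,175,74", "152,78,163",
    "255,127,0", "255,217,47", "166,86,40", "247,129,191",
    "153,153,153", "102,194,165", "252,141,98", "141,160,203",
)


class CtssTableError(ValueError):
    pass


@dataclasses.dataclass
class CtssTable:
    """Sparse per-sample CAGE signal at single-base resolution.

    ``data`` has columns ``chrom, pos, strand`` followed by one numeric
    column per sample, sorted by (chrom, strand, pos) with unique keys.
    ``library_sizes`` are the per-sample raw tag totals at load time and are
    carried through normalization unchanged.
    """

    data: pd.DataFrame
    sample_ids: list[str]
    library_sizes: dict[str, int]
    normalized: bool = False

    def __post_init__(self) -> None:
        missing = [s for s in self.sample_ids if s not in self.data.columns]
        if missing:
            raise CtssTableError(f"sample columns missing from data: {missing}")
        if len(self.data):
            if (self.data["pos"] < 1).any():
                raise CtssTableError("positions must be 1-based (>= 1)")
            bad = set(self.data["strand"]) - set(STRANDS)
            if bad:
                raise CtssTableError(f"unknown strand symbol(s): {sorted(bad)}")
            for s in self.sample_ids:
                if (self.data[s] < 0).any():
                    raise CtssTableError(f"negative signal in sample {s!r}")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, int, str]],
        counts: np.ndarray | Sequence[Sequence[float]],
        sample_ids: Sequence[str],
        normalized: bool = False,
        library_sizes: Mapping[str, int] | None = None,
    ) -> "CtssTable":
        """Build a table from (chrom, pos, strand) keys and a counts matrix.

        Duplicate keys are summed.  Library sizes default to the per-sample
        column totals (raw-count semantics).
        """
        recs = list(records)
        counts = np.asarray(counts, dtype=float)
        if counts.ndim == 1:
            counts = counts.reshape(-1, 1)
        df = pd.DataFrame(recs, columns=["chrom", "pos", "strand"])
        for j, s in enumerate(sample_ids):
            df[s] = counts[:, j] if len(recs) else np.empty(0)
        return cls._finalize(df, list(sample_ids), normalized, library_sizes)

    @classmethod
    def empty(cls, sample_ids: Sequence[str]) -> "CtssTable":
        df = pd.DataFrame({"chrom": pd.Series(dtype=str),
                           "pos": pd.Series(dtype=np.int64),
                           "strand": pd.Series(dtype=str)})
        for s in sample_ids:
            df[s] = pd.Series(dtype=float)
        return cls(df, list(sample_ids), {s: 0 for s in sample_ids})

    @classmethod
    def _finalize(cls, df, sample_ids, normalized=False, library_sizes=None):
        if len(df):
            df = (df.groupby(["chrom", "strand", "pos"], as_index=False, sort=True)
                    [sample_ids].sum())
            df = df[["chrom", "pos", "strand"] + sample_ids]
            df["pos"] = df["pos"].astype(np.int64)
        if library_sizes is None:
            library_sizes = {s: int(round(df[s].sum())) if len(df) else 0
                             for s in sample_ids}
        return cls(df.reset_index(drop=True), list(sample_ids),
                   dict(library_sizes), normalized)

    # -- basic queries -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    def totals(self) -> dict[str, float]:
        return {s: float(self.data[s].sum()) for s in self.sample_ids}

    def with_signal(self, matrix: np.ndarray, normalized: bool) -> "CtssTable":
        """Same keys, new per-sample signal (e.g. after normalization)."""
        df = self.data[["chrom", "pos", "strand"]].copy()
        for j, s in enumerate(self.sample_ids):
            df[s] = matrix[:, j]
        return CtssTable(df, list(self.sample_ids), dict(self.library_sizes),
                         normalized)

    def subset(self, chrom: str, strand: str, start: int, end: int) -> pd.DataFrame:
        d = self.data
        m = ((d["chrom"] == chrom) & (d["strand"] == strand)
             & (d["pos"] >= start) & (d["pos"] <= end))
        return d.loc[m]


@dataclasses.dataclass
class GenomicWindow:
    """1-based inclusive genomic interval; strand '.' matches both strands."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"window {self.name or self.chrom}: start > end")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad window strand {self.strand!r}")


# ---------------------------------------------------------------------------
# flat-file I/O


def read_ctss_table(path, dialect: str = "plain",
                    sample_ids: Sequence[str] | None = None) -> CtssTable:
    """Read a tab-separated CTSS table.

    ``plain`` dialect: columns chrom, pos, strand, count_1..count_n.
    ``fantom5`` dialect additionally tolerates '#' header lines and an extra
    leading annotation column (detected from the first data row).
    Duplicate (chrom, pos, strand) keys are summed.
    """
    if dialect not in ("plain", "fantom5"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows: list[tuple] = []
    counts: list[list[float]] = []
    n_samples = None
    offset = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if dialect == "fantom5":
                    continue
                raise CtssTableError(f"line {lineno}: unexpected comment line")
            fields = line.split("\t")
            if n_samples is None:
                offset = _detect_offset(fields, dialect, lineno)
                n_samples = len(fields) - offset - 3
                if n_samples < 1:
                    raise CtssTableError(f"line {lineno}: no count columns")
            if len(fields) != n_samples + offset + 3:
                raise CtssTableError(
                    f"line {lineno}: expected {n_samples + offset + 3} fields, "
                    f"got {len(fields)}")
            chrom = fields[offset]
            try:
                pos = int(fields[offset + 1])
            except ValueError:
                raise CtssTableError(f"line {lineno}: bad position "
                                     f"{fields[offset + 1]!r}") from None
            strand = fields[offset + 2]
            if strand not in STRANDS:
                raise CtssTableError(f"line {lineno}: unknown strand {strand!r}")
            if pos < 1:
                raise CtssTableError(f"line {lineno}: position {pos} < 1")
            try:
                vals = [float(x) for x in fields[offset + 3:]]
            except ValueError:
                raise CtssTableError(f"line {lineno}: non-numeric count") from None
            if any(v < 0 for v in vals):
                raise CtssTableError(f"line {lineno}: negative count")
            rows.append((chrom, pos, strand))
            counts.append(vals)
    if not rows:
        return CtssTable.empty(sample_ids or ["sample_1"])
    if sample_ids is None:
        sample_ids = [f"sample_{i + 1}" for i in range(n_samples)]
    elif len(sample_ids) != n_samples:
        raise CtssTableError(
            f"{len(sample_ids)} sample ids given for {n_samples} count columns")
    return CtssTable.from_records(rows, np.asarray(counts), sample_ids)


def _detect_offset(fields: list[str], dialect: str, lineno: int) -> int:
    if dialect == "plain":
        return 0
    # FANTOM5-like rows may start with an annotation column (e.g. chr1:100..101,+)
    def _int_ok(x):
        try:
            int(x)
            return True
        except ValueError:
            return False
    if len(fields) >= 5 and not _int_ok(fields[1]) and _int_ok(fields[2]):
        return 1
    return 0


def write_ctss_table(table: CtssTable, path) -> None:
    """Write the plain CTSS dialect; raw counts as integers, normalized as %g."""
    with open(path, "w") as fh:
        for row in table.data.itertuples(index=False):
            vals = [getattr(row, s) for s in table.sample_ids]
            if table.normalized:
                txt = "\t".join(f"{v:.6g}" for v in vals)
            else:
                txt = "\t".join(str(int(round(v))) for v in vals)
            fh.write(f"{row.chrom}\t{row.pos}\t{row.strand}\t{txt}\n")


# ---------------------------------------------------------------------------
# CTSS calling from alignments


def ctss_from_alignments(path, genome=None, mapq_min: int = 20,
                         g_mode: str = "none", sample_id: str = "sample_1",
                         return_stats: bool = False):
    """Count alignment 5' ends into a single-sample CtssTable.

    Each primary, mapped alignment with mapping quality >= ``mapq_min``
    contributes one count at its 5' end (plus strand: leftmost aligned base,
    minus strand: rightmost).  ``g_mode`` controls correction of the
    reverse-transcriptase 5' G-addition artifact before counting:
    ``simple`` shifts individual reads whose first base is a G that
    mismatches the genome, ``systematic`` additionally redistributes
    ambiguous genome-G starts with the rate-based estimator in
    :mod:`cageforge.gcorrect`.
    """
    import pysam

    from . import gcorrect

    if g_mode not in ("none", "simple", "systematic"):
        raise ValueError(f"unknown g_mode {g_mode!r}")
    fasta = None
    if g_mode != "none":
        if genome is None:
            raise ValueError(f"g_mode={g_mode!r} requires a genome FASTA")
        import pyfaidx
        fasta = genome if isinstance(genome, pyfaidx.Fasta) else pyfaidx.Fasta(str(genome))

    stats = {"total": 0, "unmapped": 0, "filtered_mapq": 0,
             "secondary": 0, "counted": 0}
    # (chrom, strand, pos) -> count, or class triples for systematic mode
    plain_counts: dict[tuple, int] = {}
    classes: dict[tuple, list] = {}

    with pysam.AlignmentFile(str(path)) as af:
        for aln in af.fetch(until_eof=True):
            stats["total"] += 1
            if aln.is_secondary or aln.is_supplementary:
                stats["secondary"] += 1
                continue
            if aln.is_unmapped:
                stats["unmapped"] += 1
                continue
            if aln.mapping_quality < mapq_min:
                stats["filtered_mapq"] += 1
                continue
            chrom = aln.reference_name
            if aln.is_reverse:
                strand, pos5 = "-", aln.reference_end  # 1-based last base
            else:
                strand, pos5 = "+", aln.reference_start + 1
            if g_mode == "none":
                key = (chrom, strand, pos5)
                plain_counts[key] = plain_counts.get(key, 0) + 1
                stats["counted"] += 1
                continue
            if chrom not in fasta:
                raise CtssTableError(
                    f"contig {chrom!r} present in alignments but absent from genome")
            first = _read_first_base(aln)
            gbase = _genome_base(fasta, chrom, pos5, strand)
            if g_mode == "simple":
                pos5 = gcorrect.correct_simple(first, gbase, pos5, strand)
                key = (chrom, strand, pos5)
                plain_counts[key] = plain_counts.get(key, 0) + 1
            else:
                tri = classes.setdefault((chrom, strand, pos5), [0, 0, 0])
                if first == "G" and gbase != "G":
                    tri[0] += 1
                elif first == "G":
                    tri[1] += 1
                else:
                    tri[2] += 1
            stats["counted"] += 1

    gstats = None
    if g_mode == "systematic":
        flagged = pd.DataFrame(
            [(c, p, s, *tri) for (c, s, p), tri in sorted(classes.items())],
            columns=["chrom", "pos", "strand",
                     "firstG_mismatch", "firstG_match", "non_G"])
        table, gstats = gcorrect.correct_systematic(flagged, fasta,
                                                    sample_id=sample_id)
    else:
        keys = sorted(plain_counts)
        table = CtssTable.from_records(
            [(c, p, s) for (c, s, p) in keys],
            np.array([[plain_counts[k]] for k in keys], dtype=float)
            if keys else np.empty((0, 1)),
            [sample_id])
    if return_stats:
        return table, stats, gstats
    return table


def _read_first_base(aln) -> str:
    seq = aln.query_sequence or ""
    if not seq:
        return "N"
    if aln.is_reverse:
        return _COMP.get(seq[-1].upper(), "N")
    return seq[0].upper()


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _genome_base(fasta, chrom: str, pos: int, strand: str) -> str:
    """Base at 1-based ``pos`` read on the transcription strand."""
    try:
        base = str(fasta[chrom][pos - 1: pos]).upper()
    except (KeyError, IndexError, ValueError):
        raise CtssTableError(f"genome base unavailable at {chrom}:{pos}") from None
    if not base:
        raise CtssTableError(f"genome base unavailable at {chrom}:{pos}")
    return _COMP.get(base, "N") if strand == "-" else base


# ---------------------------------------------------------------------------
# track export


def export_ctss_bedgraph(table: CtssTable, sample: str, out_plus, out_minus,
                         negate_minus: bool = True) -> None:
    """Write strand-split single-base bedGraph tracks for one sample.

    Minus-strand values are negated by default so that browsers mirror the
    two strands around the axis; only nonzero positions are emitted.
    """
    if sample not in table.sample_ids:
        raise CtssTableError(f"unknown sample {sample!r}")
    d = table.data
    for strand, path in (("+", out_plus), ("-", out_minus)):
        sub = d[(d["strand"] == strand) & (d[sample] > 0)]
        sign = -1.0 if (strand == "-" and negate_minus) else 1.0
        with open(path, "w") as fh:
            for row in sub.itertuples(index=False):
                v = sign * getattr(row, sample)
                fh.write(f"{row.chrom}\t{row.pos - 1}\t{row.pos}\t{v:.6g}\n")


def read_bedgraph(path) -> pd.DataFrame:
    """Parse a bedGraph track back to 1-based positions (round-trip helper)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split("\t")
            rows.append((chrom, int(start) + 1, int(end), float(value)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "end", "value"])


def export_clusters_bed12(clusters, path, color_by: Mapping | None = None) -> None:
    """Write clusters as BED12 with the interquantile region as thick span.

    ``color_by`` maps cluster id -> integer expression-class label; classes
    index a fixed palette so browser tracks show promoter classes in color.
    """
    with open(path, "w") as fh:
        for cl in clusters:
            if not cl.iq_positions:
                raise CtssTableError(
                    f"cluster {cl.id} lacks interquantile annotation")
            qlo, qup = min(cl.iq_positions), max(cl.iq_positions)
            plo, pup = cl.iq_positions[qlo], cl.iq_positions[qup]
            lo, up = min(plo, pup), max(plo, pup)
            rgb = "0,0,0"
            if color_by is not None and cl.id in color_by:
                rgb = CLASS_PALETTE[int(color_by[cl.id]) % len(CLASS_PALETTE)]
            fh.write("\t".join(map(str, [
                cl.chrom, cl.start - 1, cl.end, cl.id,
                min(1000, int(round(cl.total_signal))), cl.strand,
                lo - 1, up, rgb, 1, cl.end - cl.start + 1, 0])) + "\n")


def read_bed12(path) -> pd.DataFrame:
    """Parse BED12 back to 1-based spans (round-trip helper)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]) + 1, int(f[2]), f[3], f[5],
                         int(f[6]) + 1, int(f[7]), f[8]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "strand", "thick_start", "thick_end",
                                       "rgb"])
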