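"""Deterministic synthetic CAGE data with serialized ground truth.

The generator emulates the structures the rest of the package measures:
per-TSS tag counts whose reverse cumulative follows a discrete power law,
sharp promoters (one offset carrying >= 80% of the initiation mass) versus
broad flat-topped promoters 30-80 bp wide, controlled TSS shifts applied to
a designated half of the samples, background noise tags, and 5' G addition
at a known rate with genome-aware bookkeeping of whether the added G
matches the genome.  Everything is reproducible from a single seed, fanned
out to fixed per-stage child seeds.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ctss import CtssTable

# fixed child-seed offsets so pipeline stages are independently reproducible
SEED_GENOME, SEED_PROMOTERS, SEED_TAGS, SEED_READS = 11, 23, 37, 53

_BASES = np.array(list("ACGT"))


def _child(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng((int(seed) * 1_000_003 + offset) % (2 ** 31))


# ---------------------------------------------------------------------------
# genome


def generate_genome(seed: int, n_chrom: int = 1, length: int = 100_000,
                    gc: float = 0.5, path=None) -> dict:
    """I.i.d. random genome with expected GC content ``gc``.

    Returns {chrom: sequence}; writes a 60-column FASTA when ``path`` given.
    """
    if not 0 <= gc <= 1:
        raise ValueError("gc must lie in [0, 1]")
    if length < 1000:
        raise ValueError("chromosome length must be >= 1000")
    rng = _child(seed, SEED_GENOME)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = {f"chr{i + 1}": "".join(rng.choice(_BASES, size=length, p=p))
              for i in range(n_chrom)}
    if path is not None:
        write_fasta(genome, path)
    return genome


def write_fasta(genome: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# promoter specifications


@dataclasses.dataclass
class PromoterSpec:
    """Ground-truth description of one simulated promoter."""

    chrom: str
    anchor: int                  # 1-based dominant-TSS position
    strand: str
    shape: str                   # sharp | broad
    width: int
    offsets: np.ndarray          # profile support, anchor-relative offsets
    profile: np.ndarray          # initiation probability per offset
    per_sample_expression: np.ndarray  # expected tags per sample
    shift_offset: int = 0        # bp shift applied to the second half of samples

    def __post_init__(self) -> None:
        if abs(self.profile.sum() - 1.0) > 1e-9:
            raise ValueError("profile must sum to 1")
        if self.shape == "sharp" and self.profile.max() < 0.8:
            raise ValueError("sharp profile must hold >= 0.8 mass at one offset")

    def positions(self, shifted: bool) -> np.ndarray:
        """Genomic positions of the profile support (transcription order)."""
        off = self.offsets + (self.shift_offset if shifted else 0)
        return self.anchor + off if self.strand == "+" else self.anchor - off


def powerlaw_counts(rng: np.random.Generator, n: int, alpha: float) -> np.ndarray:
    """Discrete Pareto: P(X >= v) = v^(-alpha) for integer v >= 1."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    u = rng.random(n)
    return np.floor(u ** (-1.0 / alpha)).astype(np.int64)


def _sharp_profile(rng: np.random.Generator):
    """Geometric decay around the anchor; >= 80% of mass on the anchor."""
    width = int(rng.integers(1, 4))
    offsets = np.arange(width)
    peak = rng.uniform(0.82, 0.95)
    if width == 1:
        return offsets, np.array([1.0]), width
    w = 0.5 ** np.arange(width - 1)
    prof = np.concatenate([[peak], (1 - peak) * w / w.sum()])
    return offsets, prof / prof.sum(), width


def _broad_profile(rng: np.random.Generator):
    """Flat-topped profile, 30-80 bp wide, with a mild dominant position."""
    width = int(rng.integers(30, 81))
    offsets = np.arange(width)
    prof = np.full(width, 1.0)
    taper = min(5, width // 4)
    ramp = np.linspace(0.2, 1.0, taper, endpoint=False)
    prof[:taper] *= ramp
    prof[-taper:] *= ramp[::-1]
    prof[width // 2] *= 2.0  # make the dominant TSS unambiguous
    return offsets - width // 2, prof / prof.sum(), width


def generate_promoterome(seed: int, n_promoters: int,
                         sharp_fraction: float = 0.5, alpha: float = 1.25,
                         n_samples: int = 2, shift_fraction: float = 0.0,
                         shift_offset: int = 0, genome_length: int = 100_000,
                         n_chrom: int = 1, margin: int = 300,
                         min_expression: int = 1) -> list[PromoterSpec]:
    """Draw promoter specs with power-law expression magnitudes.

    Promoter expected counts follow a discrete power law with exponent
    ``alpha`` (so the simulated reverse cumulative is linear on log-log
    axes); ``shift_fraction`` of promoters move their profile by
    ``shift_offset`` bp in the second half of the samples.
    """
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    rng = _child(seed, SEED_PROMOTERS)
    expr = np.maximum(powerlaw_counts(rng, n_promoters, alpha), min_expression)
    n_shift = int(round(shift_fraction * n_promoters))
    shifted = np.zeros(n_promoters, dtype=bool)
    shifted[rng.choice(n_promoters, size=n_shift, replace=False)] = True
    # non-overlapping anchors, at least ~2*margin apart, away from contig ends
    per_chrom = int(np.ceil(n_promoters / n_chrom))
    slots = (genome_length - 2 * margin) // per_chrom if per_chrom else 1
    if slots < 200:
        raise ValueError("genome too short for the requested promoter count")
    specs = []
    for i in range(n_promoters):
        chrom = f"chr{i // per_chrom + 1}"
        anchor = margin + (i % per_chrom) * slots + int(rng.integers(0, slots // 2))
        strand = "+" if rng.random() < 0.5 else "-"
        if rng.random() < sharp_fraction:
            offsets, prof, width = _sharp_profile(rng)
            shape = "sharp"
        else:
            offsets, prof, width = _broad_profile(rng)
            shape = "broad"
        specs.append(PromoterSpec(
            chrom=chrom, anchor=anchor, strand=strand, shape=shape,
            width=width, offsets=offsets, profile=prof,
            per_sample_expression=np.full(n_samples, float(expr[i])),
            shift_offset=int(shift_offset) if shifted[i] else 0))
    return specs


def stage_specific_expression(specs: list[PromoterSpec], seed: int,
                              n_groups: int, high: float = 200.0,
                              low: float = 2.0) -> np.ndarray:
    """Overwrite per-sample expression with stage-specific blocks.

    Promoter i joins group i % n_groups; each group is highly expressed in
    one contiguous block of samples and near-silent elsewhere, emulating a
    developmental time-course.  Returns the group labels.
    """
    rng = _child(seed, SEED_PROMOTERS + 1)
    n_samples = len(specs[0].per_sample_expression)
    groups = np.arange(len(specs)) % n_groups
    block = max(1, n_samples // n_groups)
    for spec, g in zip(specs, groups):
        e = np.full(n_samples, low)
        lo = (g * block) % n_samples
        e[lo:lo + block] = high * rng.uniform(0.8, 1.2)
        spec.per_sample_expression = e
    return groups


# ---------------------------------------------------------------------------
# tag generation


def generate_ctss(specs: list[PromoterSpec], seed: int,
                  depth_per_sample: int, n_samples: int | None = None,
                  noise_rate: float = 0.0, genome: dict | None = None,
                  g_addition_rate: float = 0.0,
                  genome_length: int = 100_000):
    """Sample tags per promoter/sample; returns (CtssTable, truth, flagged).

    Tag counts are multinomial over promoters (probabilities proportional
    to expected expression) and then over each promoter's profile; samples
    in the second half of the panel see shifted profiles where the promoter
    spec says so.  ``noise_rate`` adds uniform background tags.  With a genome
    and ``g_addition_rate`` > 0, each tag is observed one base upstream
    with that probability and the returned ``flagged`` frame carries the
    per-position first-base classes that the G-correction consumes; the
    CtssTable then holds the *observed* (biased) positions.
    """
    if depth_per_sample < 1:
        raise ValueError("depth_per_sample must be >= 1")
    if n_samples is None:
        n_samples = len(specs[0].per_sample_expression) if specs else 1
    rng = _child(seed, SEED_TAGS)
    sample_ids = [f"sample_{j + 1}" for j in range(n_samples)]
    counts: dict[tuple, np.ndarray] = {}
    flagged: dict[tuple, np.ndarray] = {}
    truth_rows = []
    expr = np.array([s.per_sample_expression for s in specs])  # promoters x samples
    for j in range(n_samples):
        shifted_half = j >= n_samples // 2
        n_noise = int(round(noise_rate * depth_per_sample))
        n_promoter_tags = depth_per_sample - n_noise
        if specs:
            p = expr[:, j] / expr[:, j].sum()
            per_prom = rng.multinomial(n_promoter_tags, p)
        else:
            per_prom = np.zeros(0, dtype=int)
        for spec, n_tags in zip(specs, per_prom):
            use_shift = shifted_half and spec.shift_offset != 0
            pos = spec.positions(use_shift)
            tags = rng.multinomial(n_tags, spec.profile)
            for pp, c in zip(pos, tags):
                if c:
                    _add(counts, (spec.chrom, spec.strand, int(pp)), j,
                         n_samples, c)
            truth_rows.append({
                "sample": sample_ids[j], "chrom": spec.chrom,
                "strand": spec.strand, "anchor": spec.anchor,
                "shape": spec.shape, "shifted": bool(use_shift),
                "shift_offset": spec.shift_offset, "n_tags": int(n_tags),
                "dominant_pos": int(pos[int(np.argmax(spec.profile))]),
                "start": int(pos.min()), "end": int(pos.max())})
        if n_noise:
            chroms = sorted({s.chrom for s in specs}) or ["chr1"]
            for _ in range(n_noise):
                key = (chroms[int(rng.integers(len(chroms)))],
                       "+" if rng.random() < 0.5 else "-",
                       int(rng.integers(100, genome_length - 100)) + 1)
                _add(counts, key, j, n_samples, 1)
    if genome is not None and g_addition_rate > 0:
        counts = _apply_g_addition(counts, flagged, genome, g_addition_rate,
                                   rng, n_samples)
    keys = sorted(counts)
    table = CtssTable.from_records(
        [(c, p, s) for (c, s, p) in keys],
        np.array([counts[k] for k in keys], dtype=float)
        if keys else np.empty((0, n_samples)),
        sample_ids)
    truth = pd.DataFrame(truth_rows)
    flagged_df = None
    if flagged:
        fkeys = sorted(flagged)
        flagged_df = pd.DataFrame(
            [(c, p, s, *flagged[(c, s, p)]) for (c, s, p) in fkeys],
            columns=["chrom", "pos", "strand",
                     "firstG_mismatch", "firstG_match", "non_G"])
    return table, truth, flagged_df


def _add(counts, key, j, n_samples, c):
    if key not in counts:
        counts[key] = np.zeros(n_samples)
    counts[key][j] += c


def _tx_base(genome: dict, chrom: str, pos: int, strand: str) -> str:
    base = genome[chrom][pos - 1].upper()
    return {"A": "T", "C": "G", "G": "C", "T": "A"}.get(base, "N") \
        if strand == "-" else base


def _apply_g_addition(counts, flagged, genome, rate, rng, n_samples):
    """Move each tag one base upstream with probability ``rate``.

    The observed first base of a moved tag is the added G; whether it
    matches the genome at the observed position decides its class.
    Unmoved tags start with the genomic base of their true position.
    """
    observed: dict[tuple, np.ndarray] = {}
    for (chrom, strand, pos), per_sample in sorted(counts.items()):
        total = int(per_sample.sum())
        added = rng.binomial(int(per_sample.sum()), rate) if total else 0
        # distribute the added tags over samples proportionally
        moved = rng.multivariate_hypergeometric(per_sample.astype(int), added) \
            if added else np.zeros(n_samples, dtype=int)
        stay = per_sample - moved
        upstream = pos - 1 if strand == "+" else pos + 1
        if stay.sum():
            _addvec(observed, (chrom, strand, pos), stay)
            tri = flagged.setdefault((chrom, strand, pos), np.zeros(3, dtype=int))
            if _tx_base(genome, chrom, pos, strand) == "G":
                tri[1] += int(stay.sum())
            else:
                tri[2] += int(stay.sum())
        if moved.sum():
            _addvec(observed, (chrom, strand, upstream), moved)
            tri = flagged.setdefault((chrom, strand, upstream),
                                     np.zeros(3, dtype=int))
            if _tx_base(genome, chrom, upstream, strand) == "G":
                tri[1] += int(moved.sum())
            else:
                tri[0] += int(moved.sum())
    return observed


def _addvec(counts, key, vec):
    if key not in counts:
        counts[key] = np.zeros(len(vec))
    counts[key] += vec


# ---------------------------------------------------------------------------
# simulated alignments


def write_sam(genome: dict, placements, path, read_length: int = 27,
              mapq: int = 30) -> None:
    """Write simulated CAGE-tag alignments as a coordinate-sorted text SAM.

    ``placements`` are (chrom, pos5, strand, count[, mapq]) tuples; each
    yields ``count`` perfect-match reads whose 5' end is at 1-based
    ``pos5`` (leftmost base on '+', rightmost on '-').
    """
    import pysam

    chroms = list(genome)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": len(genome[c])} for c in chroms]}
    rows = []
    for i, pl in enumerate(placements):
        chrom, pos5, strand, count = pl[:4]
        q = pl[4] if len(pl) > 4 else mapq
        if strand == "+":
            start = pos5  # 1-based leftmost
        else:
            start = pos5 - read_length + 1
        if start < 1 or start + read_length - 1 > len(genome[chrom]):
            raise ValueError(f"placement {pl} outside contig")
        seq = genome[chrom][start - 1:start + read_length - 1].upper()
        for r in range(count):
            rows.append((chrom, start, strand, q, seq, f"read_{i}_{r}"))
    rows.sort(key=lambda r: (chroms.index(r[0]), r[1]))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        hdr = out.header
        for chrom, start, strand, q, seq, name in rows:
            a = pysam.AlignedSegment(hdr)
            a.query_name = name
            a.query_sequence = seq
            a.reference_id = chroms.index(chrom)
            a.reference_start = start - 1
            a.mapping_quality = q
            a.cigarstring = f"{len(seq)}M"
            a.flag = 16 if strand == "-" else 0
            out.write(a)


# ---------------------------------------------------------------------------
# one-call dataset


def simulate_dataset(seed: int, out_dir, n_promoters: int = 200,
                     n_samples: int = 4, depth: int = 50_000,
                     sharp_fraction: float = 0.5, alpha: float = 1.25,
                     shift_fraction: float = 0.0, shift_offset: int = 0,
                     noise_rate: float = 0.02, genome_length: int = 200_000,
                     g_addition_rate: float = 0.0) -> dict:
    """Generate a full synthetic dataset on disk; returns the file manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(seed, 1, genome_length, 0.45,
                             path=out / "genome.fa")
    specs = generate_promoterome(seed, n_promoters, sharp_fraction, alpha,
                                 n_samples, shift_fraction, shift_offset,
                                 genome_length=genome_length)
    table, truth, flagged = generate_ctss(
        specs, seed, depth, n_samples, noise_rate, genome=genome,
        g_addition_rate=g_addition_rate, genome_length=genome_length)
    from .ctss import write_ctss_table
    write_ctss_table(table, out / "ctss.tsv")
    truth.to_csv(out / "truth_promoters.tsv", sep="\t", index=False)
    if flagged is not None:
        flagged.to_csv(out / "truth_g_classes.tsv", sep="\t", index=False)
    manifest = {
        "seed": int(seed), "n_promoters": n_promoters, "n_samples": n_samples,
        "depth": depth, "sharp_fraction": sharp_fraction, "alpha": alpha,
        "shift_fraction": shift_fraction, "shift_offset": shift_offset,
        "noise_rate": noise_rate, "g_addition_rate": g_addition_rate,
        "files": {"genome": "genome.fa", "ctss": "ctss.tsv",
                  "truth": "truth_promoters.tsv"}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
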