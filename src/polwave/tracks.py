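"""Strand-specific single-base 3'-end signal tracks and gene annotations.

PRO-seq coverage is stored at single-base resolution: for every chromosome
and strand, an array holding the number of nascent-RNA 3' ends (the last
base incorporated by Pol II) mapped to that position.  All coordinates are
0-based, half-open, matching the bedGraph convention; GFF3 input is
converted from its 1-based closed convention on read.

Spike-in normalization follows the library-scaling rule
``normalization_factor = spike_mapped_reads / 1e5``; normalized signal is
raw signal divided by that factor, making densities comparable across
libraries that received the same amount of exogenous spike-in material.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

SPIKE_SCALE = 1e5

__all__ = [
    "SignalTrack",
    "Gene",
    "read_bedgraph_pair",
    "write_bedgraph",
    "read_genes",
    "normalization_factor",
    "region_signal",
    "relative_interval",
    "gene_profile",
    "combine_tracks",
]


def normalization_factor(spike_mapped_reads: float) -> float:
    """Spike-in normalization factor: mapped spike-in reads divided by 1e5.

    Normalized signal = raw signal / factor, so a library with twice the
    spike-in recovery (hence twice the sequencing depth per cell) is scaled
    down twofold.
    """
    if spike_mapped_reads <= 0:
        raise ValueError(
            f"cannot normalize: spike_mapped_reads must be > 0, got {spike_mapped_reads}"
        )
    return spike_mapped_reads / SPIKE_SCALE


@dataclass
class SignalTrack:
    """Per-chromosome, per-strand single-base 3'-end counts plus library metadata.

    ``data[chrom][strand]`` is a float array of length ``chrom_sizes[chrom]``
    holding non-negative count magnitudes (minus-strand values are stored as
    magnitudes regardless of the sign convention of the source file).
    """

    chrom_sizes: dict[str, int]
    data: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    spike_mapped_reads: float | None = None
    sample_id: str = ""
    timepoint: float | None = None
    treatment: str = ""

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if chrom not in self.data:
                self.data[chrom] = {
                    "+": np.zeros(size, dtype=float),
                    "-": np.zeros(size, dtype=float),
                }

    @property
    def normalization_factor(self) -> float:
        if self.spike_mapped_reads is None:
            return 1.0
        return normalization_factor(self.spike_mapped_reads)

    def array(self, chrom: str, strand: str) -> np.ndarray:
        if chrom not in self.data:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        return self.data[chrom][strand]

    def total_signal(self) -> float:
        return float(
            sum(arr.sum() for strands in self.data.values() for arr in strands.values())
        )


@dataclass(frozen=True)
class Gene:
    """Stranded transcription unit anchored by its TSS and CPS.

    ``start``/``end`` are genomic (0-based half-open).  The TSS is the
    strand-aware 5' base and the CPS the 3' base: for a minus-strand gene
    the TSS is ``end - 1`` and the CPS is ``start``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+'/'-', got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: zero/negative length ({self.start}..{self.end})")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def cps(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def with_tss(self, tss: int) -> "Gene":
        """Return a copy re-anchored at an observed TSS (CPS unchanged)."""
        if self.strand == "+":
            return Gene(self.gene_id, self.chrom, tss, self.end, "+")
        return Gene(self.gene_id, self.chrom, self.start, tss + 1, "-")


# ---------------------------------------------------------------------------
# bedGraph / annotation I/O


def read_bedgraph_pair(
    plus_path,
    minus_path,
    chrom_sizes: dict[str, int],
    **meta,
) -> SignalTrack:
    """Read a plus/minus bedGraph file pair into a single-base track.

    Intervals are expanded to per-base values.  Minus-strand values may be
    encoded as negative magnitudes (a common dialect); they are stored as
    non-negative magnitudes.  Overlapping intervals within one file are an
    error, as are intervals on unknown chromosomes or outside bounds.
    """
    track = SignalTrack(chrom_sizes=dict(chrom_sizes), **meta)
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        covered: dict[str, np.ndarray] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    fields = line.split()
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns, got {line!r}")
                chrom, s, e, v = fields[0], fields[1], fields[2], fields[3]
                try:
                    start, end, value = int(s), int(e), float(v)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed bedGraph line {line!r}") from exc
                if chrom not in chrom_sizes:
                    raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if not (0 <= start < end <= chrom_sizes[chrom]):
                    raise ValueError(
                        f"{path}:{lineno}: interval {start}..{end} outside {chrom} "
                        f"(size {chrom_sizes[chrom]})"
                    )
                mask = covered.setdefault(chrom, np.zeros(chrom_sizes[chrom], dtype=bool))
                if mask[start:end].any():
                    raise ValueError(f"{path}:{lineno}: overlapping interval on {chrom}")
                mask[start:end] = True
                track.data[chrom][strand][start:end] = abs(value)
    return track


def write_bedgraph(track: SignalTrack, plus_path, minus_path) -> None:
    """Write a track as a plus/minus bedGraph pair.

    Runs of equal non-zero value are collapsed to single intervals; zero
    runs are omitted.  Output is sorted by (chrom, start).
    """
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        with open(path, "w") as fh:
            for chrom in sorted(track.data):
                arr = track.data[chrom][strand]
                if arr.size == 0:
                    continue
                change = np.flatnonzero(np.diff(arr) != 0)
                starts = np.concatenate(([0], change + 1))
                ends = np.concatenate((change + 1, [arr.size]))
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def _gene_from_interval(gene_id, chrom, start, end, strand) -> Gene:
    return Gene(gene_id=gene_id, chrom=chrom, start=start, end=end, strand=strand)


def read_genes(path, fmt: str | None = None) -> list[Gene]:
    """Read gene annotations from BED6 or GFF3 into strand-aware Gene records.

    The format is inferred from the extension unless given.  GFF3
    coordinates (1-based closed) are converted to 0-based half-open.
    Output is stably ordered by (chrom, start, gene_id).
    """
    path = str(path)
    if fmt is None:
        lowered = path.lower()
        if lowered.endswith((".gff", ".gff3")):
            fmt = "gff3"
        else:
            fmt = "bed6"
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fmt == "bed6":
                if len(fields) < 6:
                    raise ValueError(f"{path}:{lineno}: BED6 needs 6 columns, got {len(fields)}")
                chrom, start, end, name, _score, strand = fields[:6]
                start, end = int(start), int(end)
            elif fmt == "gff3":
                if len(fields) < 9:
                    raise ValueError(f"{path}:{lineno}: GFF3 needs 9 columns, got {len(fields)}")
                chrom, _src, _type, start, end, _score, strand, _phase, attrs = fields[:9]
                start, end = int(start) - 1, int(end)  # 1-based closed -> 0-based half-open
                name = None
                for key in ("ID", "gene_id", "Name"):
                    for item in attrs.split(";"):
                        item = item.strip()
                        if item.startswith(key + "="):
                            name = item.split("=", 1)[1]
                            break
                    if name:
                        break
                if name is None:
                    name = f"feature_{lineno}"
            else:
                raise ValueError(f"unknown annotation format {fmt!r}")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: missing/invalid strand {strand!r}")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: zero-length feature {name}")
            genes.append(_gene_from_interval(name, chrom, start, end, strand))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_genes_bed6(genes: list[Gene], path) -> None:
    """Write genes as BED6 (score column 0)."""
    if not genes:
        warnings.warn(f"writing empty gene annotation to {path}")
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Gene-relative signal extraction


def relative_interval(gene: Gene, anchor: str, rel_start: int, rel_end: int) -> tuple[int, int]:
    """Map a gene-strand-relative half-open offset interval to genomic coordinates.

    ``+n`` means n bases downstream of the anchor (TSS or CPS) along the
    gene's strand; the interval is half-open at its downstream edge.  For a
    minus-strand gene downstream runs toward decreasing genomic coordinates.
    """
    if rel_end <= rel_start:
        raise ValueError(f"inverted or empty relative interval {rel_start}..{rel_end}")
    anchor = anchor.lower()
    if anchor == "tss":
        pos = gene.tss
    elif anchor == "cps":
        pos = gene.cps
    else:
        raise ValueError(f"anchor must be 'tss' or 'cps', got {anchor!r}")
    if gene.strand == "+":
        return pos + rel_start, pos + rel_end
    return pos - rel_end + 1, pos - rel_start + 1


def gene_profile(
    track: SignalTrack,
    gene: Gene,
    anchor: str,
    rel_start: int,
    rel_end: int,
    normalized: bool = True,
) -> np.ndarray:
    """Per-base signal over a gene-relative window, oriented 5'->3'.

    Positions falling off the chromosome are returned as NaN so downstream
    aggregation can mask them explicitly.
    """
    gstart, gend = relative_interval(gene, anchor, rel_start, rel_end)
    size = track.chrom_sizes[gene.chrom]
    arr = track.array(gene.chrom, gene.strand)
    out = np.full(gend - gstart, np.nan)
    lo, hi = max(gstart, 0), min(gend, size)
    if lo < hi:
        out[lo - gstart : hi - gstart] = arr[lo:hi]
    if gene.strand == "-":
        out = out[::-1]
    if normalized:
        out = out / track.normalization_factor
    return out


def region_signal(
    track: SignalTrack,
    gene: Gene,
    anchor: str,
    rel_start: int,
    rel_end: int,
    normalized: bool = True,
) -> tuple[float, float]:
    """Sum and per-bp density of signal in a gene-relative window.

    Returns ``(sum, density)`` where density = sum / window width.  Bases
    clipped at chromosome ends are excluded from both sum and width, and a
    warning reports the truncation.
    """
    prof = gene_profile(track, gene, anchor, rel_start, rel_end, normalized=normalized)
    valid = ~np.isnan(prof)
    n_valid = int(valid.sum())
    if n_valid < prof.size:
        warnings.warn(
            f"gene {gene.gene_id}: window {anchor}{rel_start:+d}..{rel_end:+d} truncated "
            f"at chromosome end ({prof.size - n_valid} bp clipped)"
        )
    if n_valid == 0:
        return 0.0, 0.0
    total = float(np.nansum(prof))
    return total, total / n_valid


def combine_tracks(tracks: list[SignalTrack]) -> SignalTrack:
    """Combine replicate libraries by summing raw counts and spike-in reads.

    The combined library's normalization factor is then the sum of spike-in
    reads over 1e5, so combined normalized signal is the depth-weighted
    pool of the replicates.
    """
    if not tracks:
        raise ValueError("no tracks to combine")
    first = tracks[0]
    for t in tracks[1:]:
        if t.chrom_sizes != first.chrom_sizes:
            raise ValueError("cannot combine tracks with differing chromosome sets")
    spike = None
    if all(t.spike_mapped_reads is not None for t in tracks):
        spike = float(sum(t.spike_mapped_reads for t in tracks))
    out = SignalTrack(
        chrom_sizes=dict(first.chrom_sizes),
        spike_mapped_reads=spike,
        sample_id="+".join(t.sample_id for t in tracks if t.sample_id),
        timepoint=first.timepoint,
        treatment=first.treatment,
    )
    for chrom in out.data:
        for strand in ("+", "-"):
            out.data[chrom][strand] = sum(t.data[chrom][strand] for t in tracks)
    return out
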