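"""Genomic formats, coordinate bookkeeping, blacklist subtraction and tag deduplication.

Conventions used throughout the package:

* All coordinates are 0-based, half-open ``[start, end)``.
* Sequencing reads are reduced to *tags*: ``(chrom, pos5, strand)`` where
  ``pos5`` is the genomic position of the 5'-most aligned base.  This is the
  common currency of both ATAC and Pt-exo coverage; Pt-exo semantics require
  5' ends (the exonuclease stop site) and a single convention keeps counting
  uniform.
* Duplicate tags are defined by ``(chrom, pos5, strand)`` identity.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# nucleotide byte codes used for in-memory sequences
BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGTN"):
    _CODE[b] = i
    _CODE[ord(chr(b).lower())] = i
# complement of code i (N -> N)
COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode_sequence(s: str) -> np.ndarray:
    """Encode an A/C/G/T/N string as uint8 codes 0..4."""
    return _CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode("ascii")


class FormatError(ValueError):
    """Raised for malformed genomic input."""


@dataclass
class GenomeAssembly:
    """Ordered map of sequence name -> length, with optional sequence text.

    ``seq`` maps names to uint8 code arrays (0=A,1=C,2=G,3=T,4=N).
    """

    names: list[str]
    sizes: dict[str, int]
    seq: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise FormatError("duplicate sequence names in assembly")
        for name in self.names:
            if self.sizes[name] <= 0:
                raise FormatError(f"non-positive length for sequence {name!r}")
        if self.seq is not None:
            for name, codes in self.seq.items():
                if len(codes) != self.sizes[name]:
                    raise FormatError(
                        f"sequence text length {len(codes)} != declared "
                        f"{self.sizes[name]} for {name!r}"
                    )

    @property
    def has_sequence(self) -> bool:
        return self.seq is not None

    @property
    def total_bp(self) -> int:
        return sum(self.sizes.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if self.seq is None:
            raise ValueError("assembly carries no sequence text")
        return decode_sequence(self.seq[chrom][start:end])

    def gc_content(self) -> float:
        if self.seq is None:
            raise ValueError("assembly carries no sequence text")
        gc = tot = 0
        for codes in self.seq.values():
            gc += int(np.sum((codes == 1) | (codes == 2)))
            tot += int(np.sum(codes != 4))
        return gc / tot

    def write_chrom_sizes(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for name in self.names:
                fh.write(f"{name}\t{self.sizes[name]}\n")

    def write_fasta(self, path: str | os.PathLike, width: int = 60) -> None:
        if self.seq is None:
            raise ValueError("assembly carries no sequence text")
        records = (
            SeqRecord(Seq(decode_sequence(self.seq[n])), id=n, description="")
            for n in self.names
        )
        SeqIO.write(records, str(path), "fasta")


def _as_lines(source) -> list[str]:
    """Accept a path, file-like object, or literal text block."""
    if hasattr(source, "read"):
        return source.read().splitlines()
    s = str(source)
    if s == "" or "\n" in s or "\t" in s:
        return s.splitlines()
    with open(s) as fh:
        return fh.read().splitlines()


def load_assembly(source) -> GenomeAssembly:
    """Load a GenomeAssembly from chrom.sizes text (UCSC dialect) or FASTA.

    ``source`` may be a file path, a file-like object, or a literal
    two-column text block.  FASTA input is detected by a leading ``>``.
    """
    if (
        isinstance(source, (str, os.PathLike))
        and "\n" not in str(source)
        and "\t" not in str(source)
        and os.path.exists(str(source))
    ):
        with open(source) as fh:
            head = fh.read(1)
        if head == ">":
            names, sizes, seq = [], {}, {}
            for rec in SeqIO.parse(str(source), "fasta"):
                if rec.id in sizes:
                    raise FormatError(f"duplicate sequence name {rec.id!r}")
                names.append(rec.id)
                codes = encode_sequence(str(rec.seq))
                sizes[rec.id] = len(codes)
                seq[rec.id] = codes
            return GenomeAssembly(names, sizes, seq)
    names, sizes = [], {}
    for ln in _as_lines(source):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split()
        if len(parts) < 2:
            raise FormatError(f"malformed chrom.sizes line: {ln!r}")
        name, length = parts[0], int(parts[1])
        if name in sizes:
            raise FormatError(f"duplicate sequence name {name!r}")
        names.append(name)
        sizes[name] = length
    return GenomeAssembly(names, sizes)


def packaged_hg19_chrom_sizes() -> GenomeAssembly:
    """The standard UCSC hg19 chrom.sizes table shipped with the package."""
    text = resources.files("ptcore.data").joinpath("hg19.chrom.sizes").read_text()
    return load_assembly(text)


@dataclass
class Interval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in "+-.":
            raise FormatError(f"invalid strand {self.strand!r}")

    def validate(self, assembly: GenomeAssembly) -> None:
        if self.chrom not in assembly.sizes:
            raise FormatError(f"unknown sequence {self.chrom!r}")
        if self.end > assembly.sizes[self.chrom]:
            raise FormatError(
                f"interval {self.chrom}:{self.start}-{self.end} beyond "
                f"sequence end {assembly.sizes[self.chrom]}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def read_intervals(
    source,
    dialect: str = "auto",
    assembly: GenomeAssembly | None = None,
) -> list[Interval]:
    """Read BED3/BED6 intervals (file order preserved, coordinates as-is).

    ``dialect``: one of ``BED3``, ``BED6`` or ``auto`` (per-line by column
    count).  Records referencing sequences absent from ``assembly`` are
    rejected.
    """
    out: list[Interval] = []
    for ln in _as_lines(source):
        ln = ln.rstrip()
        if not ln or ln.startswith(("#", "track", "browser")):
            continue
        f = ln.split("\t")
        if len(f) < 3:
            raise FormatError(f"malformed BED line: {ln!r}")
        n_fields = {"BED3": 3, "BED6": 6}.get(dialect.upper(), len(f))
        if len(f) < n_fields:
            raise FormatError(f"expected {n_fields} BED fields: {ln!r}")
        name = f[3] if n_fields >= 4 and len(f) >= 4 else None
        score = None
        if n_fields >= 5 and len(f) >= 5 and f[4] not in (".", ""):
            score = float(f[4])
        strand = f[5] if n_fields >= 6 and len(f) >= 6 else "."
        iv = Interval(f[0], int(f[1]), int(f[2]), name, score, strand)
        if assembly is not None:
            iv.validate(assembly)
        out.append(iv)
    return out


def write_intervals(intervals: Iterable[Interval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{score}\t{iv.strand}\n"
            )


@dataclass
class GeneModel:
    """A gene with TSS/TTS and exon structure.

    ``start``/``end`` bound the gene span; TSS is ``start`` on ``+`` and
    ``end - 1`` on ``-`` (the first transcribed base), TTS the opposite end.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")
        if not 0 <= self.start < self.end:
            raise FormatError(f"gene {self.gene_id}: invalid span")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise FormatError(f"gene {self.gene_id}: overlapping exons")
        for s, e in exons:
            if s < self.start or e > self.end:
                raise FormatError(f"gene {self.gene_id}: exon outside span")
        self.exons = exons

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


def read_gtf(source, assembly: GenomeAssembly | None = None) -> list[GeneModel]:
    """Minimal GTF reader: gene/exon features keyed by the gene_id attribute."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    for ln in _as_lines(source):
        if not ln or ln.startswith("#"):
            continue
        f = ln.rstrip().split("\t")
        if len(f) < 9:
            raise FormatError(f"malformed GTF line: {ln!r}")
        chrom, _, feature, start, end, _, strand, _, attrs = f[:9]
        gid = None
        for part in attrs.split(";"):
            part = part.strip()
            if part.startswith("gene_id"):
                gid = part.split(None, 1)[1].strip().strip('"')
                break
        if gid is None:
            raise FormatError(f"GTF record without gene_id: {ln!r}")
        rec = genes.setdefault(
            gid, {"chrom": chrom, "strand": strand, "exons": []}
        )
        s, e = int(start) - 1, int(end)  # GTF is 1-based inclusive
        if feature == "gene":
            rec["span"] = (s, e)
        elif feature == "exon":
            rec["exons"].append((s, e))
        if gid not in order:
            order.append(gid)
    out = []
    for gid in order:
        rec = genes[gid]
        exons = sorted(rec["exons"])
        span = rec.get("span")
        if span is None:
            span = (exons[0][0], exons[-1][1])
        gm = GeneModel(gid, rec["chrom"], rec["strand"], span[0], span[1], exons)
        if assembly is not None:
            Interval(gm.chrom, gm.start, gm.end).validate(assembly)
        out.append(gm)
    return out


def write_gtf(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tptcore\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tptcore\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


def read_gene_models_bed12(source, assembly: GenomeAssembly | None = None) -> list[GeneModel]:
    """BED12 gene models (blocks become exons)."""
    out = []
    for ln in _as_lines(source):
        ln = ln.rstrip()
        if not ln or ln.startswith(("#", "track")):
            continue
        f = ln.split("\t")
        if len(f) < 12:
            raise FormatError(f"expected 12 BED fields: {ln!r}")
        chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
        strand = f[5]
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        gm = GeneModel(name, chrom, strand, start, end, exons)
        if assembly is not None:
            Interval(chrom, start, end).validate(assembly)
        out.append(gm)
    return out


class TagSet:
    """Stranded 5'-anchored tags for one sample.

    Tags are stored per chromosome as parallel arrays ``pos`` (int64, the
    5' base) and ``strand`` (int8, 0 for ``+`` / 1 for ``-``), sorted by
    position (ties by strand).  ``library_size`` is the total tag count.
    """

    def __init__(self, sample_id: str, data: dict[str, tuple[np.ndarray, np.ndarray]] | None = None):
        self.sample_id = sample_id
        self.data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if data:
            for chrom, (pos, strand) in data.items():
                self._set(chrom, np.asarray(pos, dtype=np.int64), np.asarray(strand, dtype=np.int8))

    def _set(self, chrom: str, pos: np.ndarray, strand: np.ndarray) -> None:
        order = np.lexsort((strand, pos))
        self.data[chrom] = (pos[order], strand[order])

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    @property
    def library_size(self) -> int:
        return sum(len(p) for p, _ in self.data.values())

    def validate(self, assembly: GenomeAssembly) -> None:
        for chrom, (pos, _) in self.data.items():
            if chrom not in assembly.sizes:
                raise FormatError(f"tags on unknown sequence {chrom!r}")
            if len(pos) and (pos.min() < 0 or pos.max() >= assembly.sizes[chrom]):
                raise FormatError(f"tag position out of bounds on {chrom}")

    def to_bed6(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for chrom in self.data:
                pos, strand = self.data[chrom]
                for p, s in zip(pos, strand):
                    st = "+" if s == 0 else "-"
                    fh.write(f"{chrom}\t{p}\t{p + 1}\t.\t0\t{st}\n")

    @classmethod
    def from_bed6(cls, sample_id: str, source, assembly: GenomeAssembly | None = None) -> "TagSet":
        """Each BED6 record contributes one tag anchored at its 5' end
        (``start`` on ``+``, ``end - 1`` on ``-``)."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in read_intervals(source, "BED6", assembly):
            p = iv.start if iv.strand != "-" else iv.end - 1
            by_chrom.setdefault(iv.chrom, []).append((p, 0 if iv.strand != "-" else 1))
        ts = cls(sample_id)
        for chrom, rows in by_chrom.items():
            arr = np.array(rows, dtype=np.int64)
            ts._set(chrom, arr[:, 0], arr[:, 1].astype(np.int8))
        return ts

    @classmethod
    def from_arrays(cls, sample_id: str, chrom_arrays: dict[str, tuple[np.ndarray, np.ndarray]]) -> "TagSet":
        return cls(sample_id, chrom_arrays)


def merge_intervals(intervals: Sequence[Interval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge overlapping intervals; returns per-chrom sorted (starts, ends)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        merged = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def points_in_merged(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean mask: which points fall inside a merged, sorted interval set."""
    idx = np.searchsorted(starts, pos, side="right") - 1
    inside = idx >= 0
    inside[inside] = pos[inside] < ends[idx[inside]]
    return inside


def subtract_blacklist(tags: TagSet, blacklist: Sequence[Interval]) -> TagSet:
    """Remove tags whose 5' position lies in any blacklist interval."""
    if not blacklist:
        return TagSet(tags.sample_id, dict(tags.data))
    merged = merge_intervals(blacklist)
    out = TagSet(tags.sample_id)
    for chrom, (pos, strand) in tags.data.items():
        if chrom in merged:
            starts, ends = merged[chrom]
            keep = ~points_in_merged(pos, starts, ends)
            pos, strand = pos[keep], strand[keep]
        out._set(chrom, pos.copy(), strand.copy())
    return out


def deduplicate_tags(tags: TagSet) -> TagSet:
    """Keep at most one tag per (chrom, pos5, strand). Idempotent and
    order-independent."""
    out = TagSet(tags.sample_id)
    for chrom, (pos, strand) in tags.data.items():
        key = pos * 2 + strand
        _, idx = np.unique(key, return_index=True)
        out._set(chrom, pos[idx], strand[idx])
    return out


def write_bedgraph(
    windows: pd.DataFrame,
    values: np.ndarray,
    path: str | os.PathLike,
    name: str | None = None,
) -> None:
    """Write per-window values as bedGraph.

    Windows must be sorted by (chrom, start).  Overlapping sliding windows
    are emitted as-is with a header line noting the overlap dialect.
    """
    chrom = windows["chrom"].to_numpy()
    start = windows["start"].to_numpy()
    end = windows["end"].to_numpy()
    if len(windows) > 1:
        order = np.lexsort((start, chrom))
        if not np.array_equal(order, np.arange(len(windows))):
            raise FormatError("windows must be sorted by (chrom, start)")
    same = chrom[1:] == chrom[:-1] if len(windows) > 1 else np.array([], bool)
    overlapping = bool(np.any(start[1:][same] < end[:-1][same]))
    with open(path, "w") as fh:
        track = f'track type=bedGraph name="{name or "ptcore"}"'
        if overlapping:
            track += " # overlapping sliding windows emitted as-is"
        fh.write(track + "\n")
        for c, s, e, v in zip(chrom, start, end, np.asarray(values)):
            fh.write(f"{c}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: str | os.PathLike) -> tuple[pd.DataFrame, np.ndarray]:
    rows, vals = [], []
    with open(path) as fh:
        for ln in fh:
            if ln.startswith(("track", "#")) or not ln.strip():
                continue
            c, s, e, v = ln.split("\t")
            rows.append((c, int(s), int(e)))
            vals.append(float(v))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return df, np.array(vals)
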