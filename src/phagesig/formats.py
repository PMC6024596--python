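"""Sequence primitives and file I/O shared by every pipeline stage.

Conventions used throughout the package:

* all internal coordinates are 0-based, half-open; GFF3 I/O converts
  to/from the 1-based inclusive convention of the format;
* circular genomes are stored linearized with a ``circular`` flag —
  features that wrap the origin carry ``wraps=True`` and are split on
  GFF3 write;
* translation uses the standard genetic code with stop codons rendered
  ``*`` and codons containing ``N`` rendered ``X``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FormatError(ValueError):
    """Raised for malformed FASTA/FASTQ/GFF3 input."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

CDS_STATUSES = ("intact", "disrupted", "absent", "n/a")


@dataclass
class CdsFeature:
    """A protein-coding feature on a genome.

    Coordinates are 0-based half-open on the forward strand of the
    linearized sequence.  ``status`` records the verdict of annotation
    projection onto a recovered genome; de-novo features carry ``n/a``.
    """

    id: str
    start: int
    end: int
    strand: str = "+"
    product: str = ""
    status: str = "n/a"
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/-, got {self.strand!r}")
        if self.status not in CDS_STATUSES:
            raise ValueError(f"unknown CDS status {self.status!r}")
        if not self.wraps and self.start >= self.end:
            raise ValueError(
                f"feature {self.id}: start {self.start} >= end {self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def extract(self, seq: str) -> str:
        """Coding-strand nucleotide sequence of this feature."""
        sub = seq[self.start:self.end]
        return reverse_complement(sub) if self.strand == "-" else sub


@dataclass
class GenomeRecord:
    """A (possibly circular) nucleotide sequence with CDS features."""

    id: str
    seq: str
    circular: bool = False
    features: list[CdsFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id}: empty sequence")
        bad = set(self.seq.upper()) - NUCLEOTIDES
        if bad:
            raise FormatError(
                f"record {self.id}: non-IUPAC characters {sorted(bad)}"
            )
        self.seq = self.seq.upper()
        seen: set[str] = set()
        for f in self.features:
            if f.id in seen:
                raise ValueError(f"duplicate feature id {f.id!r} in {self.id}")
            seen.add(f.id)
            if f.end > len(self.seq) and not f.wraps:
                raise ValueError(
                    f"feature {f.id} end {f.end} beyond sequence "
                    f"length {len(self.seq)}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def feature_by_id(self, fid: str) -> CdsFeature:
        for f in self.features:
            if f.id == fid:
                return f
        raise KeyError(fid)


# ---------------------------------------------------------------------------
# sequence primitives
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> dict[str, str]:
    # built once from Biopython's standard table; stops become '*'
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    return table


def translate(seq: str, frame: int = 0) -> str:
    """Translate ``seq`` in reading frame 0..2; partial codons dropped.

    Codons containing N (or any other ambiguity) yield 'X'.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0..2, got {frame}")
    if not _CODON_TABLE:
        _CODON_TABLE.update(_build_codon_table())
    s = seq.upper()[frame:]
    out = []
    for i in range(0, len(s) - len(s) % 3, 3):
        out.append(_CODON_TABLE.get(s[i:i + 3], "X"))
    return "".join(out)


def six_frame_translate(seq: str) -> dict[int, str]:
    """All six conceptual translations, keyed by BLAST-style frame.

    Frames +1..+3 translate the forward strand at offsets 0..2; frames
    -1..-3 translate the reverse complement at offsets 0..2.
    """
    rc = reverse_complement(seq)
    frames: dict[int, str] = {}
    for f in range(3):
        frames[f + 1] = translate(seq, f)
        frames[-(f + 1)] = translate(rc, f)
    return frames


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read FASTA into GenomeRecords (``circular`` if header says so)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty id")
        circular = "circular=true" in rec.description.lower()
        try:
            records.append(GenomeRecord(rec.id, str(rec.seq), circular=circular))
        except FormatError as e:
            raise FormatError(f"{path}: {e}") from e
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path,
                width: int = 60) -> Path:
    """Write records as FASTA with fixed-width line wrapping."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            desc = " circular=true" if rec.circular else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# FASTQ (paired)
# ---------------------------------------------------------------------------

@dataclass
class ReadPair:
    id: str
    seq1: str
    seq2: str
    qual1: str = ""
    qual2: str = ""


def read_fastq_paired(path1: str | Path,
                      path2: str | Path | None = None) -> Iterator[ReadPair]:
    """Iterate mate pairs from two synchronized files or one interleaved file.

    Mates must appear in order; a name mismatch between mates (after
    stripping /1 and /2 suffixes) raises :class:`FormatError`.
    """
    def base(name: str) -> str:
        return name[:-2] if name.endswith(("/1", "/2")) else name

    if path2 is None:
        it = SeqIO.parse(str(path1), "fastq")
        for r1 in it:
            r2 = next(it, None)
            if r2 is None:
                raise FormatError(f"{path1}: odd number of interleaved reads")
            if base(r1.id) != base(r2.id):
                raise FormatError(
                    f"{path1}: desynchronized mates {r1.id} / {r2.id}")
            yield ReadPair(base(r1.id), str(r1.seq), str(r2.seq),
                           _qual(r1), _qual(r2))
    else:
        it1 = SeqIO.parse(str(path1), "fastq")
        it2 = SeqIO.parse(str(path2), "fastq")
        for r1, r2 in itertools.zip_longest(it1, it2):
            if r1 is None or r2 is None:
                raise FormatError("paired FASTQ files differ in length")
            if base(r1.id) != base(r2.id):
                raise FormatError(
                    f"desynchronized mates {r1.id} / {r2.id}")
            yield ReadPair(base(r1.id), str(r1.seq), str(r2.seq),
                           _qual(r1), _qual(r2))


def _qual(rec: SeqRecord) -> str:
    phred = rec.letter_annotations.get("phred_quality", [])
    return "".join(chr(q + 33) for q in phred)


def write_fastq_paired(pairs: Iterable[ReadPair], path1: str | Path,
                       path2: str | Path | None = None) -> None:
    """Write pairs to two files, or interleaved when ``path2`` is None."""
    def fmt(name: str, mate: int, seq: str, qual: str) -> str:
        if not qual:
            qual = "I" * len(seq)
        return f"@{name}/{mate}\n{seq}\n+\n{qual}\n"

    if path2 is None:
        with open(path1, "w") as fh:
            for p in pairs:
                fh.write(fmt(p.id, 1, p.seq1, p.qual1))
                fh.write(fmt(p.id, 2, p.seq2, p.qual2))
    else:
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for p in pairs:
                f1.write(fmt(p.id, 1, p.seq1, p.qual1))
                f2.write(fmt(p.id, 2, p.seq2, p.qual2))


# ---------------------------------------------------------------------------
# GFF3 (CDS features only — the exchange format for annotations)
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path,
              records: Sequence[GenomeRecord] | None = None
              ) -> dict[str, list[CdsFeature]]:
    """Read CDS lines of a GFF3 file into features per sequence id.

    Coordinates are converted from 1-based inclusive to 0-based
    half-open.  When ``records`` is given, coordinates are validated
    against sequence lengths and the features attached to the records.
    """
    lengths = {r.id: len(r.seq) for r in records} if records else {}
    out: dict[str, list[CdsFeature]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            try:
                start0, end1 = int(start) - 1, int(end)
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from e
            if start0 < 0 or start0 >= end1:
                raise FormatError(f"{path}:{lineno}: invalid interval")
            if seqid in lengths and end1 > lengths[seqid]:
                raise FormatError(
                    f"{path}:{lineno}: end {end1} beyond sequence "
                    f"length {lengths[seqid]}")
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            fid = attr.get("ID", f"cds{lineno}")
            out.setdefault(seqid, []).append(CdsFeature(
                id=fid, start=start0, end=end1, strand=strand,
                product=attr.get("product", ""),
                status=attr.get("status", "n/a")))
    if records:
        for rec in records:
            rec.features = out.get(rec.id, [])
    return out


def write_gff3(features: dict[str, list[CdsFeature]] | Sequence[GenomeRecord],
               path: str | Path) -> Path:
    """Write CDS features as GFF3 (1-based inclusive coordinates).

    Accepts either a mapping seqid -> features or GenomeRecords.  A
    feature wrapping the circular origin is split into its two linear
    parts, both carrying the same ID and a ``wraps=true`` attribute.
    """
    if not isinstance(features, dict):
        mapping = {r.id: (r.features, len(r.seq)) for r in features}
    else:
        mapping = {sid: (fs, None) for sid, fs in features.items()}
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, (fs, seqlen) in mapping.items():
            for f in sorted(fs, key=lambda f: (f.start, f.id)):
                attrs = f"ID={f.id}"
                if f.product:
                    attrs += f";product={f.product}"
                if f.status != "n/a":
                    attrs += f";status={f.status}"
                if f.wraps and seqlen:
                    parts = [(f.start, seqlen), (0, f.end % seqlen)]
                    attrs += ";wraps=true"
                else:
                    parts = [(f.start, f.end)]
                for s0, e1 in parts:
                    fh.write("\t".join([
                        seqid, "phagesig", "CDS", str(s0 + 1), str(e1),
                        ".", f.strand, "0", attrs]) + "\n")
    return path
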