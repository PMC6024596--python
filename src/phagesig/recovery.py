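"""Recovery and QC of complete uncultivated phage genomes from contigs.

The promotion pipeline: keep contigs of >= 20 Kbp, screen them for
translated similarity to the reference gene set (E < 1e-5), map the
sample's own reads back to each candidate to build a per-base depth
profile, and reject any candidate containing a run of >= 100 bp at depth
< 5 reads.  Accepted genomes are rotated/reverse-complemented into the
reference frame, reference annotations are projected onto them with a
per-CDS verdict (intact / disrupted / absent), and pairwise difference
counts and an identity matrix summarize the recovered population.

The internal read mapper is an exact-seed (k=21), ungapped-extension
placer that accepts a mate at its best position when it is >= 90%
identical over its full length — sufficient for depth profiling against
near-identical references, which is all the QC needs.  Whole-genome
pairwise comparisons use banded edit-distance alignment (edlib), which
is exact and fast for the >99%-identical genomes this stage sees.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from .align import ScoringScheme, bitscore, evalue, translated_search
from .formats import (
    CdsFeature,
    GenomeRecord,
    ReadPair,
    reverse_complement,
    translate,
)

_CIG = re.compile(r"(\d+)([=XID])")


def _cigar_runs(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIG.findall(cigar)]


@dataclass
class CoverageProfile:
    """Per-base read depth along one genome."""

    genome_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if self.depth.size else 0.0


@dataclass
class QcReport:
    genome_id: str
    mean_depth: float
    low_regions: list[tuple[int, int]]
    accepted: bool


# ---------------------------------------------------------------------------
# contig triage
# ---------------------------------------------------------------------------

def filter_contigs(contigs: Iterable[GenomeRecord],
                   min_len: int = 20_000) -> list[GenomeRecord]:
    """Length filter: only contigs of at least ``min_len`` nt pass."""
    return [c for c in contigs if len(c.seq) >= min_len]


def screen_contigs(contigs: Sequence[GenomeRecord],
                   reference_genes: Mapping[str, str],
                   scheme: ScoringScheme = ScoringScheme(),
                   evalue_cutoff: float = 1e-5) -> list[GenomeRecord]:
    """Keep contigs with at least one gene hit at E strictly < cutoff."""
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be > 0")
    kept = []
    for contig in contigs:
        for gid, pep in reference_genes.items():
            hit = translated_search(pep, contig, scheme, query_id=gid)
            if hit is not None and hit.evalue < evalue_cutoff:
                kept.append(contig)
                break
    return kept


# ---------------------------------------------------------------------------
# read mapping and depth
# ---------------------------------------------------------------------------

def map_reads(pairs: Iterable[ReadPair], genome: GenomeRecord,
              k: int = 21, min_identity: float = 0.90,
              count_fragments: bool = False) -> CoverageProfile:
    """Place mates by exact k-mer seed + ungapped extension; build depth.

    Each mate is tried on both strands; a seed k-mer from up to three
    read offsets anchors candidate diagonals, the full-length ungapped
    comparison scores each, and the best placement is accepted when its
    identity is at least ``min_identity``.  Circular genomes allow
    placements across the origin.  Depth counts each placed mate
    (read depth); ``count_fragments`` instead increments once per pair
    over the union of its placed mates.
    """
    L = len(genome.seq)
    template = genome.seq + genome.seq[:500] if genome.circular else genome.seq
    index: dict[str, list[int]] = {}
    for i in range(len(template) - k + 1):
        index.setdefault(template[i:i + k], []).append(i)

    diff = np.zeros(L + 1, dtype=np.int64)

    def place(read: str) -> tuple[int, int] | None:
        if k > len(read):
            raise ValueError("seed length exceeds read length")
        best: tuple[int, int] | None = None   # (matches, start)
        for seq in (read, reverse_complement(read)):
            n = len(seq)
            for off in (0, n // 2 - k // 2, n - k):
                if off < 0:
                    continue
                for pos in index.get(seq[off:off + k], ()):
                    start = pos - off
                    if start < 0 or start + n > len(template):
                        continue
                    window = template[start:start + n]
                    matches = sum(a == b for a, b in zip(seq, window))
                    if best is None or matches > best[0] or \
                            (matches == best[0] and start < best[1]):
                        best = (matches, start)
        if best is None:
            return None
        matches, start = best
        n = len(read)
        if matches / n < min_identity:
            return None
        return start, start + n

    for pair in pairs:
        spans = [s for s in (place(pair.seq1), place(pair.seq2))
                 if s is not None]
        if count_fragments and len(spans) == 2:
            a = (min(spans[0][0], spans[1][0]), max(spans[0][1], spans[1][1]))
            spans = [a]
        for s, e in spans:
            if e <= L:
                diff[s] += 1
                diff[e] -= 1
            else:                      # wrapped placement on circular genome
                diff[s] += 1
                diff[L] -= 1
                diff[0] += 1
                diff[e - L] -= 1
    depth = np.cumsum(diff[:-1])
    return CoverageProfile(genome.id, depth)


def low_coverage_regions(profile: CoverageProfile, min_depth: int = 5,
                         min_len: int = 100) -> QcReport:
    """Find maximal runs of depth < min_depth spanning >= min_len bases.

    A genome is accepted exactly when no such run exists — the
    completeness filter for promoting a contig to a finished genome.
    """
    low = profile.depth < min_depth
    regions: list[tuple[int, int]] = []
    if low.any():
        padded = np.concatenate(([False], low, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= min_len:
                regions.append((int(s), int(e)))
    return QcReport(profile.genome_id, profile.mean_depth, regions,
                    accepted=not regions)


def qc_reports_to_tsv(reports: Sequence[QcReport], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("genome_id\tmean_depth\tn_low_regions\taccepted\n")
        for r in reports:
            fh.write(f"{r.genome_id}\t{r.mean_depth:.2f}\t"
                     f"{len(r.low_regions)}\t{r.accepted}\n")
    return path


# ---------------------------------------------------------------------------
# frame adjustment
# ---------------------------------------------------------------------------

def set_frame(genome: GenomeRecord, reference: GenomeRecord,
              scheme: ScoringScheme = ScoringScheme(),
              max_divergence: float = 0.4) -> GenomeRecord:
    """Rotate (and possibly reverse-complement) into the reference frame.

    The reference is located in the doubled candidate sequence on both
    strands; the orientation with the smaller edit distance wins and the
    candidate is rotated so the match starts at position 0.  Idempotent:
    re-framing a framed genome is the identity.  Raises when the best
    orientation's edit distance exceeds ``max_divergence`` of the
    reference length (0.4 separates genuine relatives, <=0.3, from
    unrelated sequence, whose best infix alignment sits near 0.49).
    """
    best = None
    for rc in (False, True):
        seq = reverse_complement(genome.seq) if rc else genome.seq
        doubled = seq + seq
        res = edlib.align(reference.seq, doubled, mode="HW",
                          task="locations")
        if res["editDistance"] < 0:
            continue
        if best is None or res["editDistance"] < best[0]:
            loc = res["locations"][0]
            best = (res["editDistance"], rc, max(loc[0], 0))
    if best is None or best[0] / len(reference.seq) > max_divergence:
        raise ValueError(
            f"{genome.id}: no significant alignment to {reference.id}")
    _, rc, start = best
    seq = reverse_complement(genome.seq) if rc else genome.seq
    rot = start % len(seq)
    framed = seq[rot:] + seq[:rot]
    feats = genome.features if (not rc and rot == 0) else []
    return GenomeRecord(genome.id, framed, circular=genome.circular,
                        features=list(feats))


# ---------------------------------------------------------------------------
# annotation projection
# ---------------------------------------------------------------------------

def project_annotations(reference: GenomeRecord, genome: GenomeRecord,
                        scheme: ScoringScheme = ScoringScheme(),
                        evalue_cutoff: float = 1e-5,
                        large_indel: int = 30) -> list[CdsFeature]:
    """Transfer reference CDS onto a frame-adjusted genome with verdicts.

    Each reference CDS is located in the genome by full-length infix
    alignment; the located copy is scored with the nucleotide scheme and
    called *absent* when its E-value exceeds the cutoff.  A located copy
    is *disrupted* when it carries a net indel not divisible by three
    (frameshift), any single indel of >= ``large_indel`` nt, or a
    premature in-frame stop; otherwise it is *intact*.
    """
    out: list[CdsFeature] = []
    n_total = len(genome.seq)
    for f in reference.features:
        query = reference.seq[f.start:f.end]
        res = edlib.align(query, genome.seq, mode="HW", task="path")
        runs = _cigar_runs(res["cigar"] or "")
        matches = sum(n for n, op in runs if op == "=")
        mismatches = sum(n for n, op in runs if op == "X")
        gap_cols = sum(n for n, op in runs if op in "ID")
        gap_runs = [n for n, op in runs if op in "ID"]
        raw = (scheme.nt_match * matches + scheme.nt_mismatch * mismatches
               - sum(scheme.nt_gap_open + scheme.nt_gap_extend * n
                     for n in gap_runs))
        bits = bitscore(max(raw, 0.0), scheme, nucleotide=True)
        e = evalue(bits, len(query), n_total)
        loc = res["locations"][0]
        s, epos = max(loc[0], 0), loc[1] + 1
        if e > evalue_cutoff:
            out.append(replace(f, status="absent"))
            continue
        status = "intact"
        net = (epos - s) - len(query)
        if net % 3 != 0:
            status = "disrupted"        # frameshift
        elif any(n >= large_indel for n in gap_runs):
            status = "disrupted"        # large indel
        else:
            located = genome.seq[s:epos]
            if f.strand == "-":
                located = reverse_complement(located)
            pep = translate(located)
            if "*" in pep[:-1]:
                status = "disrupted"    # premature stop
        out.append(CdsFeature(id=f.id, start=s, end=epos, strand=f.strand,
                              product=f.product, status=status))
    return out


# ---------------------------------------------------------------------------
# whole-genome comparison
# ---------------------------------------------------------------------------

def _global_columns(a: str, b: str) -> list[tuple[int, str]]:
    res = edlib.align(a, b, mode="NW", task="path")
    return _cigar_runs(res["cigar"])


def pairwise_differences(g1: GenomeRecord, g2: GenomeRecord,
                         return_overhangs: bool = False):
    """Nucleotide differences between two frame-adjusted genomes.

    A global end-free comparison: the count is mismatched columns plus
    gapped columns inside the co-linear core; terminal gap runs
    (overhangs from length differences at either end) are excluded from
    the count and available via ``return_overhangs``.
    """
    runs = _global_columns(g1.seq, g2.seq)
    lead = 0
    while runs and runs[0][1] in "ID":
        lead += runs[0][0]
        runs = runs[1:]
    trail = 0
    while runs and runs[-1][1] in "ID":
        trail += runs[-1][0]
        runs = runs[:-1]
    count = sum(n for n, op in runs if op in "XID")
    if return_overhangs:
        return count, (lead, trail)
    return count


def identity_matrix(genomes: Sequence[GenomeRecord]):
    """Symmetric % identity matrix over global pairwise alignments.

    identity = 100 × identical columns / alignment columns (terminal
    gaps included); the diagonal is 100 by definition.
    """
    import pandas as pd

    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    ids = [g.id for g in genomes]
    mat = np.full((len(genomes), len(genomes)), 100.0)
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            runs = _global_columns(genomes[i].seq, genomes[j].seq)
            total = sum(n for n, _ in runs)
            ident = sum(n for n, op in runs if op == "=")
            mat[i, j] = mat[j, i] = 100.0 * ident / total
    return pd.DataFrame(mat, index=ids, columns=ids)
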