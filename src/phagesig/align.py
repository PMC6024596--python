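"""Local alignment core and hit statistics.

Replaces heuristic database search (blastx/tblastn-style) with exact
affine-gap Smith–Waterman: the corpora in this pipeline are single
genomes and contigs, so the O(nm) dynamic program is affordable and the
scores are fully deterministic.  Raw scores are converted to bitscores
and E-values with fixed Karlin–Altschul constants

    S' = (λ·S − ln K) / ln 2,        E = m·n·2^(−S')

where m·n is simply query length × total subject length (no
length-effect correction).  Defaults are the published gapped-BLOSUM62
constants (λ=0.267, K=0.041) and, for nucleotide searches, λ=0.625,
K=0.41; both are configurable on :class:`ScoringScheme`.

Gap costs follow the BLAST convention: a gap of length k costs
``gap_open + k·gap_extend`` (so the default 11/1 charges 12 for the
first gapped column).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .formats import GenomeRecord, six_frame_translate

LN2 = math.log(2.0)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scores, gap penalties and Karlin–Altschul constants."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    ka_lambda: float = 0.267
    ka_k: float = 0.041
    nt_match: float = 2.0
    nt_mismatch: float = -3.0
    nt_gap_open: float = 5.0
    nt_gap_extend: float = 2.0
    nt_lambda: float = 0.625
    nt_k: float = 0.41

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.ka_lambda <= 0 or not 0 < self.ka_k < 1:
            raise ValueError("need λ > 0 and 0 < K < 1")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=32)
def _protein_aligner(scheme: ScoringScheme) -> PairwiseAligner:
    aligner = PairwiseAligner(mode="local")
    aligner.substitution_matrix = scheme.matrix
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


@lru_cache(maxsize=32)
def _nucleotide_aligner(scheme: ScoringScheme) -> PairwiseAligner:
    aligner = PairwiseAligner(mode="local")
    alphabet = "ACGTN"
    m = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if "N" in (a, b):
                m[a, b] = 0.0
            else:
                m[a, b] = scheme.nt_match if a == b else scheme.nt_mismatch
    aligner.substitution_matrix = m
    aligner.open_gap_score = -(scheme.nt_gap_open + scheme.nt_gap_extend)
    aligner.extend_gap_score = -scheme.nt_gap_extend
    return aligner


@dataclass
class AlignmentHit:
    """One local alignment with BLAST-style statistics.

    Coordinates are 0-based half-open on the query and on the forward
    strand of the subject (for translated searches they are nucleotide
    coordinates).  ``frame`` is BLAST-style (+1..+3 / −1..−3) for
    translated hits and 0 for plain searches.
    """

    query_id: str
    subject_id: str
    raw_score: float
    bitscore: float
    evalue: float
    pct_identity: float
    query_coverage: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    frame: int = 0
    aligned_query: str = ""
    aligned_subject: str = ""
    n_columns: int = 0


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def bitscore(raw_score: float, scheme: ScoringScheme,
             nucleotide: bool = False) -> float:
    """Normalized score S' = (λS − ln K)/ln 2 in bits."""
    if raw_score < 0:
        raise ValueError("raw score must be >= 0")
    lam = scheme.nt_lambda if nucleotide else scheme.ka_lambda
    k = scheme.nt_k if nucleotide else scheme.ka_k
    return (lam * raw_score - math.log(k)) / LN2


def evalue(bits: float, m: int, n: int) -> float:
    """Expected chance hits of >= this bitscore in an m×n search space."""
    return float(m) * float(n) * 2.0 ** (-bits)


# ---------------------------------------------------------------------------
# Smith–Waterman
# ---------------------------------------------------------------------------

def smith_waterman(query: str, subject: str, scheme: ScoringScheme,
                   nucleotide: bool = False,
                   query_id: str = "query",
                   subject_id: str = "subject") -> AlignmentHit | None:
    """Optimal local alignment under affine gaps; None if score <= 0.

    Among co-optimal alignments the aligner's canonical traceback is
    returned, which is deterministic for fixed inputs.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    aligner = (_nucleotide_aligner if nucleotide else _protein_aligner)(scheme)
    alphabet = set(str(aligner.substitution_matrix.alphabet))
    bad = (set(query) | set(subject)) - alphabet
    if bad:
        raise ValueError(f"characters outside scoring alphabet: {sorted(bad)}")
    score = aligner.score(query, subject)
    if score <= 0:
        return None
    aln = aligner.align(query, subject)[0]
    blocks_q, blocks_s = aln.aligned
    q_start, q_end = int(blocks_q[0][0]), int(blocks_q[-1][1])
    s_start, s_end = int(blocks_s[0][0]), int(blocks_s[-1][1])
    identities = 0
    aligned_cols = 0
    for (qa, qb), (sa, sb) in zip(blocks_q, blocks_s):
        aligned_cols += qb - qa
        identities += sum(query[qa + i] == subject[sa + i]
                          for i in range(qb - qa))
    gap_cols = (q_end - q_start - aligned_cols) + (s_end - s_start - aligned_cols)
    n_columns = aligned_cols + gap_cols
    bits = bitscore(score, scheme, nucleotide)
    return AlignmentHit(
        query_id=query_id, subject_id=subject_id, raw_score=float(score),
        bitscore=bits, evalue=evalue(bits, len(query), len(subject)),
        pct_identity=100.0 * identities / n_columns,
        query_coverage=100.0 * (q_end - q_start) / len(query),
        q_start=q_start, q_end=q_end, s_start=s_start, s_end=s_end,
        n_columns=n_columns)


# ---------------------------------------------------------------------------
# translated search (protein query vs six-frame-translated nucleotide)
# ---------------------------------------------------------------------------

def translated_search(protein_query: str,
                      subject: GenomeRecord | str,
                      scheme: ScoringScheme,
                      query_id: str = "query") -> AlignmentHit | None:
    """Best local hit of a protein query over all six subject frames.

    The protein is always the query; subject coordinates are mapped
    back to nucleotide space on the forward strand.  The search space
    for the E-value is query length × subject nucleotide length.
    """
    if isinstance(subject, GenomeRecord):
        nt, sid = subject.seq, subject.id
    else:
        nt, sid = subject, "subject"
    if len(nt) < 3:
        raise ValueError("subject shorter than one codon")
    L = len(nt)
    best: AlignmentHit | None = None
    for frame, peptide in sorted(six_frame_translate(nt).items(),
                                 key=lambda kv: (kv[0] < 0, abs(kv[0]))):
        if not peptide:
            continue
        hit = smith_waterman(protein_query, peptide, scheme,
                             query_id=query_id, subject_id=sid)
        if hit is None:
            continue
        off = abs(frame) - 1
        aa_s, aa_e = hit.s_start, hit.s_end
        if frame > 0:
            hit.s_start, hit.s_end = off + 3 * aa_s, off + 3 * aa_e
        else:
            hit.s_start, hit.s_end = L - (off + 3 * aa_e), L - (off + 3 * aa_s)
        hit.frame = frame
        hit.evalue = evalue(hit.bitscore, len(protein_query), L)
        if best is None or hit.bitscore > best.bitscore:
            best = hit
    return best


def best_hit_per_gene(genes: Mapping[str, str],
                      subjects: Sequence[GenomeRecord],
                      scheme: ScoringScheme,
                      evalue_cutoff: float = 1e-5
                      ) -> dict[str, AlignmentHit]:
    """Per gene, the maximum-bitscore translated hit with E <= cutoff.

    The E-value uses the total subject length of the search set as n, so
    splitting one genome into contigs does not change the statistics.
    Genes without a qualifying hit are simply missing from the result.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be > 0")
    total_n = sum(len(s.seq) for s in subjects)
    out: dict[str, AlignmentHit] = {}
    for gene_id, peptide in genes.items():
        best: AlignmentHit | None = None
        for subj in subjects:
            hit = translated_search(peptide, subj, scheme, query_id=gene_id)
            if hit is None:
                continue
            hit.evalue = evalue(hit.bitscore, len(peptide), total_n)
            if best is None or hit.bitscore > best.bitscore:
                best = hit
        if best is not None and best.evalue <= evalue_cutoff:
            out[gene_id] = best
    return out


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def hits_to_tsv(hits: Iterable[AlignmentHit], path: str | Path) -> Path:
    """BLAST outfmt-6-like hit table (plus a frame column)."""
    path = Path(path)
    cols = ("qid sid pident length qstart qend sstart send "
            "evalue bitscore frame").split()
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for h in hits:
            fh.write("\t".join(str(x) for x in (
                h.query_id, h.subject_id, f"{h.pct_identity:.2f}",
                h.n_columns, h.q_start, h.q_end, h.s_start, h.s_end,
                f"{h.evalue:.3g}", f"{h.bitscore:.1f}", h.frame)) + "\n")
    return path
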