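"""In-silico PCR: primer sites, amplicon prediction, specificity tables.

The binding model is deliberately simple and fully enumerable: a primer
binds wherever it (or, on the minus strand, its reverse complement)
matches the template with at most ``max_mismatches`` mismatches, with
the 3'-terminal three bases required to match exactly — the standard
polymerase-extension constraint.  An amplicon is every (forward site on
+, reverse site on −) combination in productive mutual orientation with
a product no longer than ``max_product``.  Circular templates are
scanned across the origin.

Melting temperatures use the Wallace rule, Tm = 2(A+T) + 4(G+C) °C,
adequate for the short (16–18 nt) genus-typing primers shipped as the
package fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .formats import CdsFeature, GenomeRecord, reverse_complement

REVERSE_ORIENTATIONS = ("five_to_three", "printed_3to5")


@dataclass
class PrimerPair:
    """A PCR primer pair.

    ``reverse_orientation`` says how the stored reverse string is read:
    ``five_to_three`` (default) treats it as a standard 5'→3' primer
    annealing to the plus strand's reverse complement; ``printed_3to5``
    treats it as written 3'→5' and reverses it first.
    """

    id: str
    forward: str
    reverse: str
    max_mismatches: int = 0
    max_product: int = 5_000
    reverse_orientation: str = "five_to_three"

    def __post_init__(self) -> None:
        for name in ("forward", "reverse"):
            seq = getattr(self, name).upper()
            setattr(self, name, seq)
            if not 10 <= len(seq) <= 40:
                raise ValueError(f"{self.id} {name}: length must be 10-40 nt")
            if set(seq) - set("ACGT"):
                raise ValueError(f"{self.id} {name}: non-ACGT characters")
        if self.reverse_orientation not in REVERSE_ORIENTATIONS:
            raise ValueError(
                f"unknown reverse orientation {self.reverse_orientation!r}")

    @property
    def reverse_5to3(self) -> str:
        if self.reverse_orientation == "printed_3to5":
            return self.reverse[::-1]
        return self.reverse


@dataclass
class AmpliconPrediction:
    """One predicted PCR product on the forward strand of a template."""

    template_id: str
    pair_id: str
    start: int
    end: int
    sequence: str
    spanned_features: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# site finding
# ---------------------------------------------------------------------------

def find_sites(primer: str, template: GenomeRecord | str,
               max_mismatches: int = 0) -> list[tuple[int, str]]:
    """All (position, strand) where the primer binds the template.

    ``position`` is the 0-based start of the matched window on the
    forward strand.  On '+' the primer matches the window directly; on
    '-' the window equals the primer's reverse complement.  The three
    3'-terminal primer bases must match exactly.  Circular templates
    are scanned across the origin (positions reported mod length).
    """
    if isinstance(template, GenomeRecord):
        seq, circular = template.seq, template.circular
    else:
        seq, circular = str(template).upper(), False
    primer = primer.upper()
    n = len(primer)
    if n >= len(seq):
        raise ValueError("primer not shorter than template")
    scan = seq + seq[:n - 1] if circular else seq
    L = len(seq)
    arr = np.frombuffer(scan.encode(), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(arr, n)
    sites: list[tuple[int, str]] = []
    for strand, probe, anchor in (
            ("+", primer, slice(n - 3, n)),
            ("-", reverse_complement(primer), slice(0, 3))):
        p = np.frombuffer(probe.encode(), dtype=np.uint8)
        mismatch = win != p
        total = mismatch.sum(axis=1)
        anchored = mismatch[:, anchor].sum(axis=1) == 0
        for pos in np.flatnonzero((total <= max_mismatches) & anchored):
            sites.append((int(pos) % L, strand))
    sites.sort()
    return sites


# ---------------------------------------------------------------------------
# amplicon prediction
# ---------------------------------------------------------------------------

def predict_amplicons(pair: PrimerPair, template: GenomeRecord | str
                      ) -> list[AmpliconPrediction]:
    """Enumerate all products of the pair on the template.

    A product requires a forward-primer site on '+' upstream of a
    reverse-primer site on '−' (5' ends compared), spanning at most
    ``max_product`` nt.  Spanned CDS are computed by interval overlap
    with the template's annotation.
    """
    if isinstance(template, str):
        template = GenomeRecord("template", template)
    fwd_sites = [p for p, s in find_sites(pair.forward, template,
                                          pair.max_mismatches) if s == "+"]
    rev_sites = [p for p, s in find_sites(pair.reverse_5to3, template,
                                          pair.max_mismatches) if s == "-"]
    len_r = len(pair.reverse_5to3)
    L = len(template.seq)
    extended = template.seq + template.seq if template.circular \
        else template.seq
    out: list[AmpliconPrediction] = []
    for f in fwd_sites:
        for r in rev_sites:
            end = r + len_r
            if template.circular and end <= f:
                end += L
            if not f < end - 1:
                continue
            length = end - f
            if length > pair.max_product or length < len(pair.forward) + len_r:
                continue
            seqs = extended[f:end]
            spanned = [feat.id for feat in template.features
                       if feat.start < end and feat.end > f]
            out.append(AmpliconPrediction(
                template_id=template.id, pair_id=pair.id,
                start=f, end=end, sequence=seqs, spanned_features=spanned))
    out.sort(key=lambda a: (a.start, a.end))
    return out


def specificity_table(pairs: Sequence[PrimerPair],
                      genomes: Sequence[GenomeRecord]
                      ) -> tuple[pd.DataFrame, dict]:
    """Which pairs amplify which genomes, with product lengths.

    Returns a boolean pair × genome DataFrame and a dict
    (pair_id, genome_id) → list of product lengths.
    """
    if not pairs or not genomes:
        raise ValueError("need at least one pair and one genome")
    table = pd.DataFrame(False, index=[p.id for p in pairs],
                         columns=[g.id for g in genomes])
    lengths: dict[tuple[str, str], list[int]] = {}
    for p in pairs:
        for g in genomes:
            amps = predict_amplicons(p, g)
            table.loc[p.id, g.id] = bool(amps)
            if amps:
                lengths[(p.id, g.id)] = [a.length for a in amps]
    return table, lengths


def primer_tm(seq: str) -> float:
    """Wallace-rule melting temperature, 2(A+T) + 4(G+C) °C."""
    seq = seq.upper()
    if len(seq) < 2:
        raise ValueError("sequence too short")
    if set(seq) - set("ACGT"):
        raise ValueError("non-ACGT characters")
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    return 2.0 * at + 4.0 * gc


# ---------------------------------------------------------------------------
# primer config I/O
# ---------------------------------------------------------------------------

def read_primer_tsv(path: str | Path | None = None,
                    reverse_orientation: str = "five_to_three"
                    ) -> list[PrimerPair]:
    """Load primer pairs from TSV (columns: pair_id, forward, reverse).

    Without a path, the packaged genus-typing primer set for PB1-like
    phages is loaded.
    """
    if path is None:
        source = resources.files("phagesig").joinpath("data/pb1_primers.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    lines = [l for l in text.splitlines() if l.strip()]
    header = lines[0].split("\t")
    pairs = []
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        pairs.append(PrimerPair(id=row["pair_id"], forward=row["forward"],
                                reverse=row["reverse"],
                                reverse_orientation=reverse_orientation))
    return pairs
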