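"""Informative-gene classification and the genome atlas.

A gene of the reference genome is *informative* for its genus when its
similarity to every genome outside the genus stays below the similarity
to the most distant relative *inside* the genus.  Formally, with
``floor`` the bitscore of the gene against the most distant intragenus
relative and ``best_out`` the best bitscore against any outgroup
genome, the gene is uninformative iff

    best_out >= (1 - ε) · floor

where ε (default 0.05) operationalizes "on par"; ε=0 is the strict
reading.  Optionally a gene must also be detectable in every intragenus
genome to count as informative.

The genome atlas is a genes × samples matrix: each cell is the mean of
% query coverage and % identity of the gene's best hit in the sample's
assembly, and cells with no hit at the E-value cutoff stay missing
(rendered grey) rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentHit, ScoringScheme, best_hit_per_gene, \
    translated_search
from .formats import GenomeRecord, translate


@dataclass(frozen=True)
class SignatureConfig:
    on_par_tolerance: float = 0.05
    evalue_cutoff: float = 1e-5
    require_intragenus_presence: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.on_par_tolerance < 1.0:
            raise ValueError("on_par_tolerance must be in [0, 1)")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")


@dataclass
class InformativityCall:
    gene_id: str
    floor_score: float
    best_outgroup_score: float
    label: str  # "informative" | "uninformative"


def reference_proteins(genome: GenomeRecord) -> dict[str, str]:
    """Translate each annotated CDS; the trailing stop is trimmed."""
    out = {}
    for f in genome.features:
        pep = translate(f.extract(genome.seq))
        out[f.id] = pep[:-1] if pep.endswith("*") else pep
    return out


# ---------------------------------------------------------------------------
# most distant intragenus relative
# ---------------------------------------------------------------------------

def _gene_scores(genes: Mapping[str, str], genome: GenomeRecord,
                 scheme: ScoringScheme
                 ) -> dict[str, tuple[float, float]]:
    """Per gene: (bitscore, E-value) of its best hit; (0, inf) if none."""
    scores: dict[str, tuple[float, float]] = {}
    for gid, pep in genes.items():
        hit = translated_search(pep, genome, scheme, query_id=gid)
        scores[gid] = (hit.bitscore, hit.evalue) if hit else (0.0, np.inf)
    return scores


def most_distant_relative(reference: GenomeRecord,
                          relatives: Sequence[GenomeRecord],
                          scheme: ScoringScheme) -> str:
    """Relative minimizing the mean best-hit bitscore over all genes.

    Genes without a hit contribute 0.  Ties resolve to the
    lexicographically smallest genome id.
    """
    if not relatives:
        raise ValueError("need at least one intragenus relative")
    genes = reference_proteins(reference)
    best_id, best_mean = None, None
    for rel in sorted(relatives, key=lambda g: g.id):
        scores = _gene_scores(genes, rel, scheme)
        mean = float(np.mean([s for s, _ in scores.values()]))
        if best_mean is None or mean < best_mean:
            best_id, best_mean = rel.id, mean
    return best_id


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_informativity(reference: GenomeRecord,
                           intragenus: Sequence[GenomeRecord],
                           outgroups: Sequence[GenomeRecord],
                           cfg: SignatureConfig = SignatureConfig(),
                           scheme: ScoringScheme = ScoringScheme()
                           ) -> list[InformativityCall]:
    """Label every reference gene informative or uninformative.

    ``intragenus`` are the genus genomes other than the reference; the
    floor score comes from the most distant of them.  Floor and outgroup
    scores are plain bitscores of the best hit (0 if none) — no E-value
    gate, so short genes are compared on the same footing as long ones.
    With ``require_intragenus_presence``, a gene must additionally be
    detectable (E <= cutoff) in every *close* intragenus genome — the
    reference's strain cluster, i.e. every genome except the most
    distant relative, which only defines the floor.  Raising ε can only
    move labels toward uninformative (monotone).
    """
    if not intragenus:
        raise ValueError("need at least one intragenus genome")
    genes = reference_proteins(reference)
    if not genes:
        raise ValueError("reference genome has no annotated CDS")

    per_genome: dict[str, dict[str, tuple[float, float]]] = {}
    means: dict[str, float] = {}
    for rel in sorted(intragenus, key=lambda g: g.id):
        scores = _gene_scores(genes, rel, scheme)
        per_genome[rel.id] = scores
        means[rel.id] = float(np.mean([s for s, _ in scores.values()]))
    distant_id = min(means, key=lambda gid: (means[gid], gid))
    floor = {gid: s for gid, (s, _) in per_genome[distant_id].items()}

    out_scores: dict[str, float] = {g: 0.0 for g in genes}
    for og in outgroups:
        for gid, (s, _) in _gene_scores(genes, og, scheme).items():
            out_scores[gid] = max(out_scores[gid], s)

    calls = []
    for gid in genes:
        uninformative = (out_scores[gid]
                         >= (1.0 - cfg.on_par_tolerance) * floor[gid])
        if cfg.require_intragenus_presence and not uninformative:
            present_in_strains = all(
                per_genome[rel_id][gid][1] <= cfg.evalue_cutoff
                for rel_id in per_genome if rel_id != distant_id)
            if not present_in_strains:
                uninformative = True
        calls.append(InformativityCall(
            gene_id=gid, floor_score=floor[gid],
            best_outgroup_score=out_scores[gid],
            label="uninformative" if uninformative else "informative"))
    return calls


def informativity_to_tsv(calls: Sequence[InformativityCall],
                         path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_id\tfloor_score\tbest_outgroup_score\tlabel\n")
        for c in calls:
            fh.write(f"{c.gene_id}\t{c.floor_score:.2f}\t"
                     f"{c.best_outgroup_score:.2f}\t{c.label}\n")
    return path


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

@dataclass
class AtlasMatrix:
    """Genes × samples presence grid; cells in [0,100], NaN = no hit."""

    values: pd.DataFrame                      # index genes, columns samples
    read_counts: dict[str, int]               # per-sample data volume

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        df = self.values.copy()
        df.index.name = "gene_id"
        # full precision so the TSV round-trips losslessly
        df.to_csv(path, sep="\t", na_rep="NA")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path,
                 read_counts: dict[str, int] | None = None) -> "AtlasMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(df, read_counts or {})


def build_atlas(genes: Mapping[str, str],
                samples: Mapping[str, Sequence[GenomeRecord]],
                cfg: SignatureConfig = SignatureConfig(),
                scheme: ScoringScheme = ScoringScheme(),
                read_counts: Mapping[str, int] | None = None) -> AtlasMatrix:
    """Score every informative gene in every sample assembly.

    ``genes`` maps gene id → peptide, in reference-genome order;
    ``samples`` maps sample id → its assembly contigs.  The cell is the
    mean of query coverage and % identity of the single best
    (max-bitscore) hit, or missing when no hit reaches the cutoff.
    """
    if not genes or not samples:
        raise ValueError("need at least one gene and one sample")
    data = {}
    for sample_id, contigs in samples.items():
        hits = best_hit_per_gene(genes, list(contigs), scheme,
                                 cfg.evalue_cutoff)
        col = {gid: (hits[gid].query_coverage + hits[gid].pct_identity) / 2.0
               if gid in hits else np.nan for gid in genes}
        data[sample_id] = col
    df = pd.DataFrame(data, index=list(genes))
    counts = {s: int((read_counts or {}).get(s, 0)) for s in samples}
    return AtlasMatrix(df, counts)


def render_atlas(atlas: AtlasMatrix, path: str | Path,
                 sample_groups: Mapping[str, str] | None = None) -> Path:
    """Heatmap of the atlas: grey = no hit, top bar = per-sample reads.

    Genes keep their (genomic) row order; samples are grouped by the
    supplied category, otherwise kept in input order.  A TSV with the
    exact matrix is written next to the image.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if atlas.values.empty:
        raise ValueError("empty atlas")
    df = atlas.values
    if sample_groups:
        order = sorted(df.columns,
                       key=lambda s: (sample_groups.get(s, ""), s))
        df = df[order]
    path = Path(path)
    fig, (ax_bar, ax_hm) = plt.subplots(
        2, 1, figsize=(max(4, 0.5 * df.shape[1]), max(4, 0.25 * df.shape[0])),
        gridspec_kw={"height_ratios": [1, 6]}, sharex=False)
    counts = [atlas.read_counts.get(s, 0) for s in df.columns]
    ax_bar.bar(range(len(df.columns)), counts, color="0.3")
    ax_bar.set_xlim(-0.5, len(df.columns) - 0.5)
    ax_bar.set_ylabel("reads")
    ax_bar.set_xticks([])
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("0.8")
    im = ax_hm.imshow(np.ma.masked_invalid(df.to_numpy(dtype=float)),
                      aspect="auto", cmap=cmap, vmin=0, vmax=100,
                      interpolation="nearest")
    ax_hm.set_yticks(range(df.shape[0]), labels=list(df.index), fontsize=6)
    ax_hm.set_xticks(range(df.shape[1]), labels=list(df.columns),
                     rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax_hm, label="(coverage + identity) / 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    AtlasMatrix(df, atlas.read_counts).to_tsv(path.with_suffix(".tsv"))
    return path
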