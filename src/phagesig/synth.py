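"""Synthetic phage-genus and virome generator.

Emulates the statistical structure the downstream analysis assumes: a
tight genus of near-identical ~66 Kbp myovirus genomes (>99% pairwise
identity, ~90 CDS) plus one distant intragenus relative, outgroup phages
that share a controllable subset of genes, and paired-end shotgun
viromes with controllable per-genome abundance, per-base error rate and
planted low-coverage windows.

Everything is a pure function of ``(config, seed)``: the same seed
yields byte-identical genomes, reads and truth labels.

The substitution model is deliberately the uniform Jukes–Cantor model —
each mutated site moves to one of the three alternative bases with equal
probability — so that the Jukes–Cantor distances estimated downstream
can be compared against the planted branch lengths.  Sequencing errors
are substitutions only, written with a constant Q30 quality; depth and
identity, not base quality, are what the recovery QC consumes.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats import (
    CdsFeature,
    GenomeRecord,
    ReadPair,
    reverse_complement,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
           if a + b + c not in _STOPS]


@dataclass
class SimConfig:
    """Knobs of the generator; defaults mirror the target study system.

    A reference genome of 90 genes averaging 650 nt with ~80 nt
    intergenic spacers comes out at ~66 Kbp.  The genus holds five close
    relatives (≤5% divergence, i.e. >99% identity for the closest) and
    one distant relative at 25% — the intragenus "floor" for signature
    calling.  Viromes are 2×150 nt paired-end reads at 30× mean depth
    with a 0.5% error rate.
    """

    seed: int = 0
    n_genes: int = 90
    gene_len_mean: float = 650.0
    gene_len_sd: float = 100.0
    intergenic_len: int = 80
    divergence_list: tuple[float, ...] = (0.005, 0.01, 0.02, 0.03, 0.05, 0.25)
    indel_rate: float = 0.0
    n_outgroups: int = 2
    outgroup_shared_genes: tuple[str, ...] = ()
    outgroup_shared_divergence: float = 0.02
    read_len: int = 150
    insert_mean: float = 400.0
    insert_sd: float = 40.0
    error_rate: float = 0.005
    abundance: float = 30.0

    def validate(self) -> None:
        for d in self.divergence_list:
            if not 0.0 <= d < 0.75:
                raise ValueError(f"divergence {d} outside [0, 0.75)")
        if not 0.0 <= self.outgroup_shared_divergence < 0.75:
            raise ValueError("outgroup_shared_divergence outside [0, 0.75)")
        for name in ("indel_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} outside [0, 1]")
        if self.read_len > self.insert_mean:
            raise ValueError("read_len exceeds mean insert size")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


@dataclass
class SimTruth:
    """Ground truth planted by the generator, consumed by tests."""

    planted_informative: set[str] = field(default_factory=set)
    planted_uninformative: set[str] = field(default_factory=set)
    abundances: dict[str, float] = field(default_factory=dict)
    dropouts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    true_tree: str = ""


# ---------------------------------------------------------------------------
# reference genome
# ---------------------------------------------------------------------------

def generate_reference(cfg: SimConfig,
                       record_id: str = "reference"
                       ) -> tuple[GenomeRecord, list[CdsFeature]]:
    """Build a reference genome of non-overlapping, stop-free CDS.

    Each gene starts with ATG, ends with an in-frame stop, contains no
    internal in-frame stop, and is separated from its neighbour by an
    intergenic spacer of 0.5–1.5× the configured length.  Roughly 80% of
    genes sit on the forward strand.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    parts: list[str] = []
    features: list[CdsFeature] = []
    pos = 0
    for g in range(cfg.n_genes):
        spacer_len = int(rng.integers(cfg.intergenic_len // 2,
                                      max(cfg.intergenic_len * 3 // 2, 2)))
        spacer = "".join(
            "ACGT"[b] for b in rng.integers(0, 4, size=spacer_len))
        parts.append(spacer)
        pos += spacer_len
        n_codons = max(30, int(round(rng.normal(
            cfg.gene_len_mean, cfg.gene_len_sd) / 3)))
        body = "".join(_CODONS[i] for i in
                       rng.integers(0, len(_CODONS), size=n_codons - 2))
        stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
        cds = "ATG" + body + stop
        strand = "+" if rng.random() < 0.8 else "-"
        if strand == "-":
            parts.append(reverse_complement(cds))
        else:
            parts.append(cds)
        features.append(CdsFeature(
            id=f"gp{g + 1:02d}", start=pos, end=pos + len(cds),
            strand=strand, product="hypothetical protein", status="intact"))
        pos += len(cds)
    tail = "".join("ACGT"[b] for b in rng.integers(0, 4, size=cfg.intergenic_len))
    parts.append(tail)
    seq = "".join(parts)
    expected = cfg.n_genes * (cfg.gene_len_mean + cfg.intergenic_len)
    if not 0.9 * expected <= len(seq) <= 1.1 * expected + cfg.intergenic_len:
        raise RuntimeError(
            f"packed genome length {len(seq)} outside 10% of {expected:.0f}")
    # phage genomes are circularly permuted; the linearized record keeps
    # a circular flag so read simulation and mapping wrap the origin
    genome = GenomeRecord(record_id, seq, circular=True,
                          features=list(features))
    return genome, features


# ---------------------------------------------------------------------------
# evolution
# ---------------------------------------------------------------------------

def evolve_genome(ref: GenomeRecord, divergence: float,
                  indel_rate: float = 0.0, seed: int = 0,
                  preserve_genes: bool = False, record_id: str | None = None,
                  return_events: bool = False):
    """Mutate a genome by i.i.d. per-site substitutions and rare indels.

    Each site substitutes with probability ``divergence``, moving to one
    of the three alternative bases uniformly.  Indels (1–3 nt) occur at
    ``indel_rate`` per site.  With ``preserve_genes`` set, indels are
    confined to intergenic regions and substitutions that would create
    an in-frame stop inside a CDS are redrawn; feature coordinates are
    shifted across intergenic indels so the annotation stays valid.
    """
    if not 0.0 <= divergence < 0.75:
        raise ValueError(f"divergence {divergence} outside [0, 0.75)")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(ref.seq.encode(), dtype=np.uint8).copy()
    L = arr.size

    sub_sites = np.flatnonzero(rng.random(L) < divergence)
    shifts = rng.integers(1, 4, size=sub_sites.size)
    base_idx = np.searchsorted(_BASES, arr[sub_sites])
    arr[sub_sites] = _BASES[(base_idx + shifts) % 4]

    if preserve_genes and sub_sites.size:
        _repair_stops(arr, ref, sub_sites, rng)

    events = {"n_substitutions": int(sub_sites.size),
              "substitution_sites": sub_sites, "indels": []}

    seq = arr.tobytes().decode()
    features = [replace(f) for f in ref.features]
    if indel_rate > 0:
        n_indels = rng.poisson(indel_rate * L)
        cds_mask = np.zeros(L, dtype=bool)
        for f in ref.features:
            cds_mask[f.start:f.end] = True
        candidates = np.flatnonzero(~cds_mask) if preserve_genes \
            else np.arange(L)
        if candidates.size and n_indels > 0:
            sites = np.sort(rng.choice(candidates,
                                       size=min(n_indels, candidates.size),
                                       replace=False))
            seq, features, indel_events = _apply_indels(
                seq, features, sites, rng)
            events["indels"] = indel_events

    rec = GenomeRecord(record_id or f"{ref.id}_mut", seq,
                       circular=ref.circular, features=features)
    return (rec, events) if return_events else rec


def _repair_stops(arr: np.ndarray, ref: GenomeRecord,
                  sub_sites: np.ndarray, rng: np.random.Generator) -> None:
    """Redraw substitutions that created premature in-frame stops."""
    touched = set(sub_sites.tolist())
    for f in ref.features:
        for start in range(f.start, f.end - 3, 3):
            codon_sites = (range(start, start + 3) if f.strand == "+"
                           else range(f.end - (start - f.start) - 3,
                                      f.end - (start - f.start)))
            codon_sites = list(codon_sites)
            if not any(s in touched for s in codon_sites):
                continue
            for _ in range(8):
                codon = arr[codon_sites[0]:codon_sites[0] + 3].tobytes().decode()
                if f.strand == "-":
                    codon = reverse_complement(codon)
                if codon not in _STOPS:
                    break
                # rotate one mutated site to the next alternative base
                s = next(x for x in codon_sites if x in touched)
                i = int(np.searchsorted(_BASES, arr[s]))
                arr[s] = _BASES[(i + 1 + int(rng.integers(0, 3))) % 4]


def _apply_indels(seq: str, features: list[CdsFeature], sites: np.ndarray,
                  rng: np.random.Generator):
    pieces: list[str] = []
    prev = 0
    offsets: list[tuple[int, int]] = []   # (ref position, cumulative shift)
    shift = 0
    indel_events = []
    for s in sites:
        s = int(s)
        pieces.append(seq[prev:s])
        size = int(rng.integers(1, 4))
        if rng.random() < 0.5:  # insertion
            ins = "".join("ACGT"[b] for b in rng.integers(0, 4, size=size))
            pieces.append(seq[s:s + 1] + ins)
            prev = s + 1
            shift += size
            indel_events.append((s, size))
        else:                   # deletion
            prev = min(s + size, len(seq))
            shift -= prev - s
            indel_events.append((s, -(prev - s)))
        offsets.append((prev, shift))
    pieces.append(seq[prev:])
    new_seq = "".join(pieces)

    positions = [o[0] for o in offsets]
    shifts = [o[1] for o in offsets]

    def remap(p: int) -> int:
        i = bisect_right(positions, p)
        return p + (shifts[i - 1] if i else 0)

    new_features = [replace(f, start=remap(f.start), end=remap(f.end))
                    for f in features]
    return new_seq, new_features, indel_events


# ---------------------------------------------------------------------------
# genus + outgroups
# ---------------------------------------------------------------------------

def generate_genus_and_outgroups(cfg: SimConfig
                                 ) -> tuple[list[GenomeRecord], SimTruth]:
    """Reference, intragenus relatives, and outgroup genomes with truth.

    Outgroups are i.i.d. random sequence except for the designated
    shared genes, which are copies of the reference genes evolved at
    ``outgroup_shared_divergence``.  A shared gene is planted
    uninformative when its divergence in the outgroup does not exceed
    the divergence of the most distant intragenus relative.
    """
    cfg.validate()
    ref, features = generate_reference(cfg)
    genomes = [ref]
    for i, d in enumerate(cfg.divergence_list):
        genomes.append(evolve_genome(
            ref, d, cfg.indel_rate, seed=cfg.seed + 1000 + i,
            preserve_genes=True, record_id=f"relative{i + 1}"))

    rng = np.random.default_rng(cfg.seed + 500)
    shared = [ref.feature_by_id(g) for g in cfg.outgroup_shared_genes]
    for j in range(cfg.n_outgroups):
        og = _make_outgroup(ref, shared, cfg, rng, f"outgroup{j + 1}")
        genomes.append(og)

    max_d = max(cfg.divergence_list) if cfg.divergence_list else 0.0
    all_genes = {f.id for f in features}
    if cfg.outgroup_shared_genes and cfg.outgroup_shared_divergence <= max_d:
        uninformative = set(cfg.outgroup_shared_genes)
    else:
        uninformative = set()
    truth = SimTruth(
        planted_informative=all_genes - uninformative,
        planted_uninformative=uninformative,
        true_tree=_star_newick(cfg))
    return genomes, truth


def _make_outgroup(ref: GenomeRecord, shared: list[CdsFeature],
                   cfg: SimConfig, rng: np.random.Generator,
                   record_id: str) -> GenomeRecord:
    L = len(ref.seq)
    seq = list("ACGT"[b] for b in rng.integers(0, 4, size=L))
    feats = []
    for f in shared:
        gene_seq = f.extract(ref.seq)
        carrier = GenomeRecord("g", gene_seq)
        mut = evolve_genome(carrier, cfg.outgroup_shared_divergence,
                            seed=int(rng.integers(0, 2**31)))
        pos = f.start  # keep genomic position comparable to the reference
        seq[pos:pos + len(mut.seq)] = mut.seq
        feats.append(CdsFeature(id=f.id, start=pos, end=pos + len(mut.seq),
                                strand="+", product=f.product))
    return GenomeRecord(record_id, "".join(seq), features=feats)


def _star_newick(cfg: SimConfig) -> str:
    def jc_len(p: float) -> float:
        return -0.75 * math.log(1 - 4 * p / 3) if p > 0 else 0.0

    tips = ["reference:0.0"] + [
        f"relative{i + 1}:{jc_len(d):.6f}"
        for i, d in enumerate(cfg.divergence_list)]
    return "(" + ",".join(tips) + ");"


def simulate_sequences_on_tree(root_seq: str, tree, seed: int = 0
                               ) -> dict[str, str]:
    """Evolve a sequence down a tree (JC substitutions, no indels).

    ``tree`` is a newick string or an skbio ``TreeNode``; branch lengths
    are Jukes–Cantor distances d, converted to the per-site substitution
    probability p = 3/4·(1 − e^(−4d/3)) on each branch.  Returns the
    leaf-label → sequence mapping.
    """
    import io

    from skbio import TreeNode

    if isinstance(tree, str):
        tree = TreeNode.read(io.StringIO(tree))
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}

    def walk(node, seq: str) -> None:
        for child in node.children:
            d = child.length or 0.0
            p = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
            mut = evolve_genome(GenomeRecord("n", seq), p,
                                seed=int(rng.integers(0, 2**31)))
            if child.is_tip():
                out[child.name] = mut.seq
            else:
                walk(child, mut.seq)

    walk(tree, root_seq)
    return out


# ---------------------------------------------------------------------------
# virome simulation
# ---------------------------------------------------------------------------

def simulate_metagenome(genomes: Sequence[GenomeRecord],
                        abundances: Sequence[float], cfg: SimConfig,
                        dropouts: dict[str, list[tuple[int, int]]] | None = None,
                        truth: SimTruth | None = None,
                        seed: int | None = None) -> list[ReadPair]:
    """Simulate paired-end shotgun reads of a mixed-genome virome.

    Per genome, ``ceil(abundance × L / (2 × read_len))`` pairs are drawn
    from uniformly placed fragments (wrapping the origin for circular
    genomes), giving an expected mean depth equal to the configured
    abundance.  A planted dropout window is emulated by replacing that
    window with unrelated random sequence in the genome the reads are
    drawn from: reads internal to the window then fail to map back to
    the original genome, while reads spanning a window boundary still
    map — the signature of an assembled region unsupported by the
    sample's own reads.
    """
    cfg.validate()
    if len(genomes) != len(abundances):
        raise ValueError("genomes and abundances differ in length")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    dropouts = dropouts or {}
    pairs: list[ReadPair] = []
    for genome, ab in zip(genomes, abundances):
        if ab < 0:
            raise ValueError("abundance must be >= 0")
        if truth is not None:
            truth.abundances[genome.id] = ab
            if genome.id in dropouts:
                truth.dropouts[genome.id] = list(dropouts[genome.id])
        if ab == 0:
            continue
        L = len(genome.seq)
        n_pairs = math.ceil(ab * L / (2 * cfg.read_len))
        source = genome.seq
        for ms, me in dropouts.get(genome.id, []):
            if not 0 <= ms < me <= L:
                raise ValueError(f"dropout ({ms}, {me}) outside genome bounds")
            foreign = "".join("ACGT"[b]
                              for b in rng.integers(0, 4, size=me - ms))
            source = source[:ms] + foreign + source[me:]
        template = source + source[:2000] if genome.circular else source
        for i in range(n_pairs):
            insert = int(np.clip(rng.normal(cfg.insert_mean, cfg.insert_sd),
                                 cfg.read_len, 4 * cfg.insert_mean))
            if genome.circular:
                start = int(rng.integers(0, L))
            else:
                start = int(rng.integers(0, max(L - insert, 1)))
            end = start + insert
            frag = template[start:end]
            if len(frag) < cfg.read_len:
                continue
            r1 = frag[:cfg.read_len]
            r2 = reverse_complement(frag)[:cfg.read_len]
            r1, r2 = (_add_errors(r, cfg.error_rate, rng) for r in (r1, r2))
            pairs.append(ReadPair(f"{genome.id}_{i}", r1, r2,
                                  "?" * len(r1), "?" * len(r2)))
    return pairs


def _add_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return read
    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
    sites = np.flatnonzero(rng.random(arr.size) < rate)
    if sites.size:
        idx = np.searchsorted(_BASES, arr[sites])
        arr[sites] = _BASES[(idx + rng.integers(1, 4, size=sites.size)) % 4]
    return arr.tobytes().decode()


def fragment_to_contigs(genome: GenomeRecord, n_breaks: int,
                        seed: int = 0) -> list[GenomeRecord]:
    """Cut a genome at random positions into contigs that partition it."""
    if n_breaks < 0:
        raise ValueError("n_breaks must be >= 0")
    if n_breaks == 0:
        return [GenomeRecord(f"{genome.id}_c1", genome.seq)]
    rng = np.random.default_rng(seed)
    L = len(genome.seq)
    breaks = sorted(rng.choice(np.arange(1, L), size=min(n_breaks, L - 1),
                               replace=False).tolist())
    bounds = [0] + breaks + [L]
    return [GenomeRecord(f"{genome.id}_c{k + 1}", genome.seq[a:b])
            for k, (a, b) in enumerate(zip(bounds, bounds[1:]))]


# ---------------------------------------------------------------------------
# truth file
# ---------------------------------------------------------------------------

def write_truth(truth: SimTruth, path: str | Path) -> Path:
    """Serialize planted labels, abundances and dropouts as TSV."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("kind\tkey\tvalue\n")
        for g in sorted(truth.planted_informative):
            fh.write(f"informative\t{g}\t1\n")
        for g in sorted(truth.planted_uninformative):
            fh.write(f"uninformative\t{g}\t1\n")
        for gid, ab in sorted(truth.abundances.items()):
            fh.write(f"abundance\t{gid}\t{ab}\n")
        for gid, intervals in sorted(truth.dropouts.items()):
            for s, e in intervals:
                fh.write(f"dropout\t{gid}\t{s}-{e}\n")
        if truth.true_tree:
            fh.write(f"tree\tnewick\t{truth.true_tree}\n")
    return path
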