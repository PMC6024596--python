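"""Contig promotion, read mapping, depth QC, frame adjustment,
annotation projection and whole-genome comparison."""

import numpy as np
import pytest

from phagesig import (
    CoverageProfile,
    GenomeRecord,
    SimConfig,
    evolve_genome,
    filter_contigs,
    identity_matrix,
    low_coverage_regions,
    map_reads,
    pairwise_differences,
    project_annotations,
    reference_proteins,
    reverse_complement,
    screen_contigs,
    set_frame,
    simulate_metagenome,
    translated_search,
)


def random_genome(n, seed, gid="rand"):
    rng = np.random.default_rng(seed)
    return GenomeRecord(gid, "".join("ACGT"[b]
                                     for b in rng.integers(0, 4, size=n)))


class TestFilterAndScreen:
    def test_length_boundary(self):
        short = random_genome(19_999, 1, "short")
        exact = random_genome(20_000, 2, "exact")
        assert filter_contigs([short, exact]) == [exact]
        assert filter_contigs([]) == []

    def test_related_contig_retained_random_discarded(self, small_parts,
                                                      scheme):
        ref, relatives, _, _ = small_parts
        genes = dict(list(reference_proteins(ref).items())[:3])
        decoys = [random_genome(4000, s, f"rand{s}") for s in range(5)]
        kept = screen_contigs([relatives[0]] + decoys, genes, scheme)
        assert [c.id for c in kept] == [relatives[0].id]

    def test_evalue_boundary_is_strict(self, small_parts, scheme):
        ref, relatives, _, _ = small_parts
        gid, pep = next(iter(reference_proteins(ref).items()))
        hit = translated_search(pep, relatives[0], scheme)
        # a cutoff equal to the achieved E-value excludes the hit (<, not <=)
        assert screen_contigs([relatives[0]], {gid: pep}, scheme,
                              evalue_cutoff=hit.evalue) == []
        assert screen_contigs([relatives[0]], {gid: pep}, scheme,
                              evalue_cutoff=hit.evalue * 1.001) != []


class TestMapReads:
    def test_mean_depth_tracks_abundance(self, big_reference, reads_15x):
        _, ref = big_reference
        profile = map_reads(reads_15x, ref)
        assert abs(profile.mean_depth - 15.0) / 15.0 < 0.10

    def test_no_reads_zero_profile(self, big_reference):
        _, ref = big_reference
        profile = map_reads([], ref)
        assert profile.depth.sum() == 0

    def test_unrelated_reads_unplaced(self, big_reference):
        cfg, ref = big_reference
        decoy = random_genome(20_000, 99, "decoy")
        decoy.circular = True
        pairs = simulate_metagenome([decoy], [10.0], cfg, seed=13)
        profile = map_reads(pairs, ref)
        placed = profile.depth.sum() / cfg.read_len
        assert placed / (2 * len(pairs)) < 0.001

    def test_seed_longer_than_read_rejected(self, big_reference):
        _, ref = big_reference
        from phagesig.formats import ReadPair
        with pytest.raises(ValueError):
            map_reads([ReadPair("r", "ACGT", "ACGT")], ref, k=21)


class TestLowCoverageRegions:
    def test_uniform_high_depth_accepted(self):
        rep = low_coverage_regions(
            CoverageProfile("g", np.full(1000, 10)))
        assert rep.accepted and rep.low_regions == []

    def test_planted_zero_window_reported(self):
        depth = np.full(5000, 10)
        depth[2000:2150] = 0
        rep = low_coverage_regions(CoverageProfile("g", depth))
        assert not rep.accepted
        assert rep.low_regions == [(2000, 2150)]

    def test_99bp_run_below_min_len_accepted(self):
        depth = np.full(5000, 10)
        depth[2000:2099] = 4
        rep = low_coverage_regions(CoverageProfile("g", depth))
        assert rep.accepted

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            depth = rng.integers(0, 12, size=2000)
            base = low_coverage_regions(CoverageProfile("g", depth),
                                        min_depth=5, min_len=100)
            stricter_depth = low_coverage_regions(
                CoverageProfile("g", depth), min_depth=6, min_len=100)
            longer_window = low_coverage_regions(
                CoverageProfile("g", depth), min_depth=5, min_len=80)
            if not base.accepted:
                assert not stricter_depth.accepted
                assert not longer_window.accepted


class TestQcLoop:
    def test_fifteen_x_genome_passes(self, big_reference, reads_15x):
        _, ref = big_reference
        rep = low_coverage_regions(map_reads(reads_15x, ref))
        assert rep.accepted

    def test_planted_dropout_rejected_interval_recovered(self,
                                                         big_reference):
        cfg, ref = big_reference
        window = (30_000, 30_150)
        pairs = simulate_metagenome([ref], [115.0], cfg,
                                    dropouts={ref.id: [window]}, seed=21)
        rep = low_coverage_regions(map_reads(pairs, ref))
        assert not rep.accepted
        s, e = rep.low_regions[0][0], rep.low_regions[-1][1]
        assert abs(s - window[0]) <= cfg.read_len
        assert abs(e - window[1]) <= cfg.read_len


class TestSetFrame:
    def test_rotation_recovered(self, big_reference):
        _, ref = big_reference
        rotated = GenomeRecord("rot", ref.seq[1000:] + ref.seq[:1000],
                               circular=True)
        assert set_frame(rotated, ref).seq == ref.seq

    def test_idempotent(self, big_reference):
        _, ref = big_reference
        g = GenomeRecord("rot", ref.seq[500:] + ref.seq[:500], circular=True)
        once = set_frame(g, ref)
        assert set_frame(once, ref).seq == once.seq

    def test_reverse_complement_and_rotation(self, big_reference):
        _, ref = big_reference
        g = GenomeRecord(
            "rcrot", reverse_complement(ref.seq[7000:] + ref.seq[:7000]),
            circular=True)
        assert set_frame(g, ref).seq == ref.seq

    def test_unrelated_genome_rejected(self, big_reference):
        _, ref = big_reference
        with pytest.raises(ValueError):
            set_frame(random_genome(60_000, 3), ref)


class TestProjectAnnotations:
    def test_unmodified_genome_all_intact(self, small_parts):
        ref, _, _, _ = small_parts
        feats = project_annotations(ref, GenomeRecord("copy", ref.seq))
        assert all(f.status == "intact" for f in feats)

    def test_single_deletion_is_frameshift(self, small_parts):
        ref, _, _, _ = small_parts
        target = ref.features[4]
        mid = (target.start + target.end) // 2
        mutant = GenomeRecord("del", ref.seq[:mid] + ref.seq[mid + 1:])
        status = {f.id: f.status for f in project_annotations(ref, mutant)}
        assert status[target.id] == "disrupted"
        assert all(s == "intact" for g, s in status.items()
                   if g != target.id)

    def test_replaced_cds_absent(self, small_parts):
        ref, _, _, _ = small_parts
        target = ref.features[2]
        rng = np.random.default_rng(8)
        junk = "".join("ACGT"[b]
                       for b in rng.integers(0, 4, size=len(target)))
        mutant = GenomeRecord(
            "repl", ref.seq[:target.start] + junk + ref.seq[target.end:])
        status = {f.id: f.status for f in project_annotations(ref, mutant)}
        assert status[target.id] == "absent"

    def test_premature_stop_is_disrupted(self, small_parts):
        ref, _, _, _ = small_parts
        target = next(f for f in ref.features if f.strand == "+")
        # plant TAA one third into the reading frame
        off = target.start + 3 * (len(target) // 9)
        mutant_seq = ref.seq[:off] + "TAA" + ref.seq[off + 3:]
        status = {f.id: f.status
                  for f in project_annotations(
                      ref, GenomeRecord("stop", mutant_seq))}
        assert status[target.id] == "disrupted"


class TestGenomeComparison:
    def test_identical_genomes_zero_differences(self, big_reference):
        _, ref = big_reference
        assert pairwise_differences(ref, GenomeRecord("c", ref.seq)) == 0

    def test_count_equals_planted_substitutions(self, big_reference):
        _, ref = big_reference
        mut, events = evolve_genome(ref, 0.001, seed=9, return_events=True)
        assert pairwise_differences(ref, mut) == events["n_substitutions"]

    def test_symmetry(self, big_reference):
        _, ref = big_reference
        mut = evolve_genome(ref, 0.005, seed=10)
        assert pairwise_differences(ref, mut) == \
            pairwise_differences(mut, ref)

    def test_identity_matrix_tight_genus(self, big_reference):
        _, ref = big_reference
        # two relatives at d<=0.004 from the reference are at most ~0.008
        # apart from each other, keeping every pair above 99% identity
        genus = [ref] + [evolve_genome(ref, 0.004, seed=s,
                                       record_id=f"m{s}")
                         for s in (1, 2)]
        m = identity_matrix(genus)
        off = m.to_numpy()[~np.eye(3, dtype=bool)]
        assert (off > 99.0).all()
        assert np.allclose(m.to_numpy(), m.to_numpy().T, atol=1e-9)
        assert (np.diag(m.to_numpy()) == 100.0).all()
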