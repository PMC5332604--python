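"""Translated-alignment S_G: translation, tiling, normalization, matrix."""

import math

import numpy as np
import pytest

from evgtools.community import CommunitySpec, generate_community, make_circular_artifact
from evgtools.orfs import revcomp
from evgtools.similarity import (
    HSP,
    bitscore_from_raw,
    compute_sg,
    find_hsps,
    raw_similarity,
    read_tabular,
    sg_from_hsp_table,
    sg_matrix,
    six_frame_translate,
    tile_score,
    write_tabular,
)


class TestTranslation:
    def test_genetic_code(self):
        assert six_frame_translate("ATGAAA")[0] == "MK"

    def test_reverse_frames_equal_forward_of_revcomp(self, rng):
        s = "".join(rng.choice(list("ACGT"), size=100))
        fr = six_frame_translate(s)
        rc = six_frame_translate(revcomp(s))
        assert fr[3:] == rc[:3]

    def test_trailing_bases_ignored(self):
        assert six_frame_translate("ATGAA")[0] == "M"
        assert len(six_frame_translate("ATGAA")[1]) == 1  # TGA A -> "*"


def test_karlin_altschul_bitscore():
    # raw 100 with gapped params: (26.7 - ln 0.041) / ln 2
    assert bitscore_from_raw(100, lambda_=0.267, K=0.041) == pytest.approx(
        (26.7 - math.log(0.041)) / math.log(2))
    assert bitscore_from_raw(100, lambda_=0.267, K=0.041) == pytest.approx(43.13, abs=0.01)


def _hsp(q, s, qstart, qend, bitscore):
    return HSP(q, s, 1.0, qend - qstart + 1, 0, 0, qstart, qend, qstart, qend, 1e-30, bitscore)


class TestTiling:
    def test_no_hsps_zero(self):
        assert raw_similarity([], []) == 0.0

    def test_single_symmetric_hsp(self):
        h = _hsp("a", "b", 1, 300, 120.0)
        assert raw_similarity([h], [h]) == 120.0

    def test_greedy_discards_redundant_overlap(self):
        # two disjoint HSPs (80, 40 bits) plus one fully overlapping the
        # first (70 bits): selected total is 120
        hsps = [
            _hsp("a", "b", 1, 300, 80.0),
            _hsp("a", "b", 500, 700, 40.0),
            _hsp("a", "b", 1, 300, 70.0),
        ]
        assert tile_score(hsps) == 120.0

    def test_partial_overlap_below_half_kept(self):
        hsps = [
            _hsp("a", "b", 1, 100, 80.0),
            _hsp("a", "b", 61, 260, 50.0),  # 40/200 = 20% of own span overlaps
        ]
        assert tile_score(hsps) == 130.0
        hsps[1] = _hsp("a", "b", 41, 140, 50.0)  # 60/100 = 60% overlaps
        assert tile_score(hsps) == 80.0


class TestComputeSG:
    def test_identity_endpoint(self):
        assert compute_sg(100.0, 100.0, 100.0) == 1.0

    def test_no_hit_endpoint(self):
        assert compute_sg(0.0, 100.0, 200.0) == 0.0

    def test_min_normalization_arithmetic(self):
        assert compute_sg(30.0, 100.0, 200.0) == pytest.approx(0.30)

    def test_geometric_option(self):
        assert compute_sg(30.0, 100.0, 400.0, normalization="geometric") == pytest.approx(0.15)

    def test_zero_self_score_rejected(self):
        with pytest.raises(ValueError):
            compute_sg(1.0, 0.0, 10.0)


@pytest.fixture(scope="module")
def coding_genome():
    spec = CommunitySpec(n_genera=1, genomes_per_genus=1, genome_length_bp=(20_000, 20_000),
                         within_genus_divergence=0.0, between_genus_divergence=1e-9, seed=21)
    genomes, _ = generate_community(spec)
    return next(iter(genomes.values()))


class TestSearch:
    def test_identical_orfs_align_at_full_identity(self, coding_genome):
        hsps = find_hsps({"a": coding_genome}, {"b": coding_genome}, mode="translated")
        assert hsps
        best = max(hsps, key=lambda h: h.bitscore)
        assert best.identity == 1.0

    def test_unrelated_sequences_find_nothing(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=800))
        b = "".join(rng.choice(list("ACGT"), size=800))
        hsps = find_hsps({"a": a}, {"b": b}, mode="nucleotide", evalue=1e-6)
        assert hsps == []

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            find_hsps({"a": ""}, {"b": "ACGT"})


class TestSGMatrix:
    def test_identical_genomes_all_ones(self, coding_genome):
        sg = sg_matrix({"a": coding_genome, "b": coding_genome, "c": coding_genome})
        assert np.allclose(sg.values, 1.0)

    def test_matrix_properties(self, small_sg):
        sg = small_sg
        assert np.allclose(sg.values, sg.values.T)
        assert np.allclose(np.diag(sg.values), 1.0)
        assert sg.values.min() >= 0.0 and sg.values.max() <= 1.0

    def test_genus_structure_separates_scores(self, small_community, small_sg):
        _, genomes, truth = small_community
        ids = list(genomes)
        within, between = [], []
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                (within if truth.genus_of[a] == truth.genus_of[b] else between).append(
                    small_sg.loc[a, b])
        assert np.mean(within) > np.mean(between)
        assert np.mean(between) < 0.05

    def test_auto_candidates_match_exhaustive(self, small_community):
        _, genomes, _ = small_community
        subset = {k: genomes[k] for k in list(genomes)[:6]}
        full = sg_matrix(subset, candidates="all")
        auto = sg_matrix(subset, candidates="auto")
        # candidate pairs carry the same scores; non-candidates are truly
        # dissimilar pairs whose exhaustive S_G is (near) zero
        diff = (full - auto).abs().values
        assert diff.max() < 0.05

    def test_duplicate_ids_rejected(self, coding_genome):
        with pytest.raises(ValueError):
            sg_matrix({"a": coding_genome})


class TestSGDivergence:
    def test_monotone_decay_with_divergence(self):
        """Mean within-genus S_G decreases with planted divergence."""
        means = []
        for d in (0.01, 0.1, 0.3):
            spec = CommunitySpec(n_genera=1, genomes_per_genus=2,
                                 genome_length_bp=(15_000, 15_000),
                                 within_genus_divergence=d,
                                 between_genus_divergence=0.9, seed=17)
            genomes, _ = generate_community(spec)
            sg = sg_matrix(genomes)
            a, b = list(genomes)
            means.append(sg.loc[a, b])
        assert means[0] > means[1] > means[2]

    def test_rotation_and_reversal_near_invariance(self, coding_genome):
        rotated = coding_genome[7_000:] + coding_genome[:7_000]
        sg = sg_matrix({"a": coding_genome, "rot": rotated, "rc": revcomp(coding_genome)})
        assert sg.loc["a", "rot"] >= 0.95
        assert sg.loc["a", "rc"] >= 0.95


class TestTabular:
    def test_round_trip(self, tmp_path, coding_genome):
        hsps = find_hsps({"a": coding_genome}, {"b": coding_genome}, mode="translated")
        path = tmp_path / "hits.tsv"
        write_tabular(hsps, path)
        back = read_tabular(path)
        assert len(back) == len(hsps)
        assert back[0].query == "a" and back[0].subject == "b"
        assert back[0].bitscore == pytest.approx(hsps[0].bitscore, abs=0.05)
        assert back[0].qstart == hsps[0].qstart

    def test_sg_from_imported_table(self, tmp_path, coding_genome):
        seqs = {"a": coding_genome, "b": coding_genome[:18_000]}
        hsps = find_hsps(seqs, seqs, mode="translated")
        internal = sg_matrix(seqs)
        path = tmp_path / "hits.tsv"
        write_tabular(hsps, path)
        imported = sg_from_hsp_table(read_tabular(path), list(seqs))
        assert imported.loc["a", "b"] == pytest.approx(internal.loc["a", "b"], abs=1e-3)
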