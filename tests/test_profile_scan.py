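"""Profile construction and tandem-repeat detection."""

import math

import numpy as np
import pytest

from s1domains import profile_scan, synthetic_data
from s1domains.seqio import ProteinRecord, encode_sequence


def brute_force_local_score(scores, seq_idx, gap_open, gap_extend, max_gap=5):
    """Best local profile-to-sequence alignment score with at most 2 gap runs.

    Pure enumeration over (start, match run, gap run, ...) segmentations;
    alignments start and end with matched columns.  A gap run of length g
    costs gap_open + (g - 1) * gap_extend.
    """
    n = len(seq_idx)
    L = scores.shape[0]
    best = 0.0

    def match_sum(i, j, m):
        total = 0.0
        for t in range(m):
            total += scores[j + t, seq_idx[i + t]]
        return total

    def gap_cost(g):
        return gap_open + (g - 1) * gap_extend

    for i0 in range(n):
        for j0 in range(L):
            max_m1 = min(n - i0, L - j0)
            for m1 in range(1, max_m1 + 1):
                s1 = match_sum(i0, j0, m1)
                best = max(best, s1)
                i1, j1 = i0 + m1, j0 + m1
                for t1 in ("seq", "prof"):
                    for g1 in range(1, max_gap + 1):
                        i2 = i1 + (g1 if t1 == "seq" else 0)
                        j2 = j1 + (g1 if t1 == "prof" else 0)
                        if i2 >= n or j2 >= L:
                            break
                        base = s1 - gap_cost(g1)
                        for m2 in range(1, min(n - i2, L - j2) + 1):
                            s2 = base + match_sum(i2, j2, m2)
                            best = max(best, s2)
                            i3, j3 = i2 + m2, j2 + m2
                            for t2 in ("seq", "prof"):
                                for g2 in range(1, max_gap + 1):
                                    i4 = i3 + (g2 if t2 == "seq" else 0)
                                    j4 = j3 + (g2 if t2 == "prof" else 0)
                                    if i4 >= n or j4 >= L:
                                        break
                                    base2 = s2 - gap_cost(g2)
                                    for m3 in range(1, min(n - i4, L - j4) + 1):
                                        best = max(
                                            best, base2 + match_sum(i4, j4, m3)
                                        )
    return best


class TestBuildProfile:
    def test_log_odds_formula(self):
        prof = profile_scan.build_profile(["AC"], pseudocount=1.0)
        col = prof.columns[0]
        assert col["A"] == pytest.approx(math.log(10.5))
        assert col["C"] == pytest.approx(math.log(0.5))
        assert col["X"] == 0.0

    def test_gap_dominated_column_dropped(self):
        prof = profile_scan.build_profile(["A-C", "A-C"])
        assert prof.length == 2

    def test_half_gap_column_kept(self):
        prof = profile_scan.build_profile(["AWC", "A-C"])
        assert prof.length == 3

    def test_duplicate_seed_equals_single_seed(self):
        single = profile_scan.build_profile(["ACDEFGHIKL"])
        double = profile_scan.build_profile(["ACDEFGHIKL", "ACDEFGHIKL"])
        assert np.allclose(single.scores, double.scores)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            profile_scan.build_profile(["AC", "ACD"])

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            profile_scan.build_profile([])

    def test_every_column_scores_all_residues(self, family):
        prof = family["profile"]
        for col in prof.columns:
            assert set(col) == set("ACDEFGHIKLMNPQRSTVWYX")


class TestScanSequence:
    def test_self_hit_covers_sequence(self, family):
        seq = family["seed"][0]
        rec = ProteinRecord(id="self", sequence=seq)
        hits = profile_scan.scan_sequence(family["profile"], rec)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (1, len(seq))
        gapless = float(
            sum(family["profile"].scores[j, idx]
                for j, idx in enumerate(encode_sequence(seq)))
        )
        assert hits[0].raw_score == pytest.approx(gapless)
        assert hits[0].norm_score == pytest.approx(gapless / len(seq))

    def test_two_tandem_domains_found(self, family):
        rng = np.random.default_rng(11)
        doms = [
            synthetic_data.mutate_sequence(
                family["ancestor"], 0.3, family["conservation"], rng
            )
            for _ in range(2)
        ]
        rec = ProteinRecord(id="two", sequence=doms[0] + "GSGSGSGSGS" + doms[1])
        hits = profile_scan.scan_sequence(family["profile"], rec)
        assert len(hits) == 2
        assert hits[0].end < hits[1].start  # non-overlapping, N->C order

    def test_random_sequence_yields_no_hit(self, family):
        rng = np.random.default_rng(1234)
        rec = ProteinRecord(id="rand", sequence=synthetic_data.random_sequence(200, rng))
        assert profile_scan.scan_sequence(family["profile"], rec) == []

    def test_hits_never_overlap(self, endosym_truth):
        seed_aln = synthetic_data.seed_alignment_from_truth(endosym_truth, seed=3)
        prof = profile_scan.build_profile(seed_aln)
        scanned = 0
        for rec in endosym_truth.records[:6]:
            hits = profile_scan.scan_sequence(prof, rec)
            scanned += len(hits)
            for h1, h2 in zip(hits, hits[1:]):
                assert h1.end < h2.start
        assert scanned > 0

    def test_lower_cutoff_weakly_increases_hits(self, family):
        rng = np.random.default_rng(5)
        dom = synthetic_data.mutate_sequence(
            family["ancestor"], 0.4, family["conservation"], rng
        )
        rec = ProteinRecord(
            id="p", sequence=dom + "GSGSGS" + dom[::-1] + "AAAA" + dom
        )
        counts = []
        for cutoff in (2.5, 1.5, 1.0, 0.5):
            prof = profile_scan.ScoringProfile(
                scores=family["profile"].scores, cutoff=cutoff
            )
            counts.append(len(profile_scan.scan_sequence(prof, rec)))
        assert counts == sorted(counts)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_best_score_matches_restricted_enumeration(self, seed):
        """DP optimum equals the <=2-gap exhaustive oracle on small inputs."""
        rng = np.random.default_rng(seed)
        anc = synthetic_data.random_sequence(8, rng)
        seed_aln = [synthetic_data.mutate_sequence(anc, 0.15, None, rng) for _ in range(4)]
        prof = profile_scan.build_profile(seed_aln)
        target = synthetic_data.mutate_sequence(anc, 0.2, None, rng)
        seq = synthetic_data.random_sequence(6, rng) + target + synthetic_data.random_sequence(6, rng)
        seq_idx = encode_sequence(seq)
        expected = brute_force_local_score(
            prof.scores, seq_idx, prof.gap_open, prof.gap_extend
        )
        from s1domains.profile_scan import _best_hit

        found = _best_hit(prof, seq_idx, np.zeros(len(seq), dtype=np.bool_))
        got = found[2] if found is not None else 0.0
        assert got == pytest.approx(expected)


class TestCountDomains:
    def test_single_domain(self, family):
        rec = ProteinRecord(id="one", sequence="GSGS" + family["seed"][1] + "GSGS")
        assert profile_scan.count_domains(rec, family["profile"]) == 1

    def test_eight_domain_protein(self, family):
        """An eight-repeat bacterial-style protein is counted exactly."""
        spec = synthetic_data.SyntheticSpec(
            groups=[synthetic_data.GroupSpec(name="Bact8", n_proteins=1, k=8, divergence=0.2)],
            seed=99,
        )
        truth = synthetic_data.generate_family(spec)
        seed_aln = synthetic_data.seed_alignment_from_truth(truth, seed=1)
        prof = profile_scan.build_profile(seed_aln)
        assert profile_scan.count_domains(truth.records[0], prof) == 8

    def test_matches_scan_length(self, family, endosym_truth):
        rec = endosym_truth.records[0]
        assert profile_scan.count_domains(rec, family["profile"]) == len(
            profile_scan.scan_sequence(family["profile"], rec)
        )
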