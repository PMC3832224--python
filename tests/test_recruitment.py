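"""Read recruitment filters, normalization and island calling."""

import numpy as np
import pytest

from conftest import mutate_string, random_dna
from streamline_scan.io_formats import AnnotatedGenome, ReadSet
from streamline_scan.recruitment import (IslandCall, RecruitmentProfile,
                                         call_islands, recruit,
                                         recruit_community)


def _genome(rng, n=20_000, gid="g"):
    return AnnotatedGenome(gid, random_dna(rng, n))


def _adversarial_tail(genome_seq, start, length):
    """Bases that mismatch the genome continuation at every position."""
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
    return "".join(swap[b] for b in genome_seq[start:start + length])


class TestRecruitFilters:
    def test_identical_read_kept_at_100(self, rng):
        g = _genome(rng)
        rs = ReadSet([("r1", g.sequence[500:600])])
        prof = recruit(rs, g)
        assert prof.kept_count == 1
        assert prof.hits[0].identity == 100.0

    def test_49_aligned_bp_excluded_in_abs_len(self, rng):
        g = _genome(rng)
        core = g.sequence[1000:1049]  # 49 exact bp
        tail = _adversarial_tail(g.sequence, 1049, 11)
        rs = ReadSet([("r1", core + tail)])
        prof = recruit(rs, g, mode="abs_len", min_len=50)
        assert prof.kept_count == 0

    def test_50_aligned_bp_kept_in_abs_len(self, rng):
        g = _genome(rng)
        rs = ReadSet([("r1", g.sequence[1000:1050])])
        prof = recruit(rs, g, mode="abs_len", min_len=50)
        assert prof.kept_count == 1

    def test_frac_len_requires_half_the_read(self, rng):
        g = _genome(rng)
        core49 = g.sequence[2000:2049] + _adversarial_tail(g.sequence, 2049, 51)
        core51 = g.sequence[3000:3051] + _adversarial_tail(g.sequence, 3051, 49)
        prof = recruit(ReadSet([("a", core49), ("b", core51)]),
                       g, mode="frac_len", min_len=50)
        assert [h.query_id for h in prof.hits] == ["b"]

    def test_exact_95_identity_kept_9499_dropped(self, rng):
        g = AnnotatedGenome("g", random_dna(rng, 30_000))
        # interior substitutions only: the full-length alignment is optimal
        r95 = mutate_string(g.sequence[100:200], range(10, 100, 20), rng)
        rs = ReadSet([("r95", r95)])
        prof = recruit(rs, g, min_identity=95.0, min_len=50)
        assert prof.kept_count == 1
        assert prof.hits[0].identity == 95.0
        # 9499/10000 matched columns = 94.99% on a long read (501 interior subs)
        r9499 = mutate_string(g.sequence[5000:15000],
                              list(range(9, 10000, 20)) + [9996], rng)
        assert len(r9499) == 10000
        prof = recruit(ReadSet([("x", r9499)]), g, min_identity=95.0, min_len=50)
        assert prof.kept_count == 0

    def test_coverage_sums_to_hit_interval_lengths(self, rng):
        g = _genome(rng)
        reads = [(f"r{i}", g.sequence[i * 150 : i * 150 + 100]) for i in range(30)]
        prof = recruit(ReadSet(reads), g)
        assert prof.coverage.sum() == sum(h.s_end - h.s_start for h in prof.hits)

    def test_normalization_halves_when_database_doubles(self, rng):
        g = _genome(rng)
        real = [(f"r{i}", g.sequence[i * 200 : i * 200 + 100]) for i in range(10)]
        junk = [(f"j{i}", random_dna(rng, 100)) for i in range(10)]
        p1 = recruit(ReadSet(real), g)
        p2 = recruit(ReadSet(real + junk), g)
        assert p1.kept_count == p2.kept_count == 10
        assert p2.normalized_recruitment == pytest.approx(
            p1.normalized_recruitment / 2)

    def test_empty_read_set_rejected(self, rng):
        with pytest.raises(ValueError):
            recruit(ReadSet([]), _genome(rng))


class TestCommunityAssignment:
    def test_tied_read_counted_fractionally(self, rng):
        seq = random_dna(rng, 5_000)
        ga = AnnotatedGenome("A", seq)
        gb = AnnotatedGenome("B", seq)  # identical twins: every hit ties
        rs = ReadSet([("r1", seq[100:200]), ("r2", seq[900:1000])])
        profs = recruit_community(rs, [ga, gb])
        assert profs["A"].kept_count == profs["B"].kept_count == 1.0

    def test_higher_identity_genome_wins(self, rng):
        seq = random_dna(rng, 5_000)
        ga = AnnotatedGenome("A", seq)
        gb = AnnotatedGenome("B", mutate_string(seq, range(0, 5000, 40), rng))
        rs = ReadSet([("r1", seq[1000:1100])])
        profs = recruit_community(rs, [ga, gb])
        assert profs["A"].kept_count == 1.0
        assert profs["B"].kept_count == 0.0


class TestIslandCalling:
    def _profile(self, coverage):
        prof = RecruitmentProfile("g", len(coverage), 1_000_000, "frac_len")
        prof.coverage = np.asarray(coverage, dtype=np.int64)
        return prof

    def test_uniform_coverage_has_no_islands(self):
        prof = self._profile(np.full(200_000, 12))
        assert call_islands(prof) == []

    def test_single_zeroed_stretch_called_once(self):
        cov = np.full(200_000, 12)
        cov[80_000:100_000] = 0
        calls = call_islands(self._profile(cov))
        assert len(calls) == 1
        c = calls[0]
        assert c.label == "GI1"
        assert c.start >= 78_000 and c.end <= 102_000  # within +-2 kb
        overlap = min(c.end, 100_000) - max(c.start, 80_000)
        assert overlap >= 0.8 * 20_000

    def test_islands_labelled_left_to_right_and_disjoint(self):
        cov = np.full(300_000, 15)
        cov[50_000:65_000] = 0
        cov[200_000:230_000] = 0
        calls = call_islands(self._profile(cov))
        assert [c.label for c in calls] == ["GI1", "GI2"]
        assert calls[0].end <= calls[1].start

    def test_short_depression_dropped(self):
        cov = np.full(200_000, 12)
        cov[50_000:53_000] = 0  # 3 kb < min_len 5 kb
        assert call_islands(self._profile(cov)) == []

    def test_all_zero_coverage_warns_not_islands_everywhere(self):
        prof = self._profile(np.zeros(100_000))
        with pytest.warns(UserWarning):
            assert call_islands(prof) == []

    def test_calls_invariant_under_read_order(self, rng):
        g = _genome(rng, 50_000)
        reads = [(f"r{i}", g.sequence[int(p) : int(p) + 100])
                 for i, p in enumerate(rng.integers(0, 49_900, 400))]
        rs1 = ReadSet(reads)
        rs2 = ReadSet(list(reversed(reads)))
        p1 = recruit(rs1, g)
        p2 = recruit(rs2, g)
        assert call_islands(p1) == call_islands(p2)
        assert (p1.coverage == p2.coverage).all()
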