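import numpy as np
import pytest

from poolseq import (
    CandidateIndel,
    ScoringScheme,
    TruthVariant,
    apply_realignment,
    build_alt_reference,
    collect_candidate_indels,
    left_normalize,
    random_reference,
    realign_read,
    simulate_reads_with_indels,
)
from poolseq.cigar import has_gap, reference_length
from poolseq.realign import CoordinateError, score_alignment
from poolseq.simulate import SimulatedRead


def apply_variant(reference: str, pos: int, ref: str, alt: str) -> str:
    """Independent oracle: the haplotype produced by applying a variant."""
    assert reference[pos - 1 : pos - 1 + len(ref)] == ref
    return reference[: pos - 1] + alt + reference[pos - 1 + len(ref) :]


def oracle_score(read: SimulatedRead, reference: str, scoring=ScoringScheme()) -> int:
    """Independent alignment scorer (plain CIGAR walk)."""
    import re

    m = 0
    mm = 0
    rpos, qpos = read.start, 0
    for num, op in re.findall(r"(\d+)([MIDS])", read.cigar):
        n = int(num)
        if op == "M":
            for i in range(n):
                inside = 1 <= rpos + i <= len(reference)
                if inside and reference[rpos + i - 1] == read.sequence[qpos + i]:
                    m += 1
                else:
                    mm += 1
            rpos += n
            qpos += n
        elif op == "I":
            m += n
            qpos += n
        elif op == "D":
            rpos += n
        else:
            qpos += n
    return scoring.match * m + scoring.mismatch * mm


def oracle_best_alt_score(read, alt_refs, scoring=ScoringScheme()):
    """Exhaustive enumeration of every representable gapless placement."""
    L = len(read.sequence)
    end = read.start + max(reference_length(read.cigar), 1) - 1
    best = None
    for ar in alt_refs:
        if end < ar.window_start or read.start > ar.window_end:
            continue
        indel = ar.source_indel
        pre = indel.position - ar.window_start + 1
        ilen = indel.indel_length
        is_ins = not indel.is_deletion
        for off in range(len(ar.sequence) - L + 1):
            if is_ins and pre <= off < pre + ilen:
                continue  # placement starts inside inserted bases
            mm = sum(
                1 for i in range(L) if ar.sequence[off + i] != read.sequence[i]
            )
            sc = scoring.match * (L - mm) + scoring.mismatch * mm
            if best is None or sc > best:
                best = sc
    return best


class TestLeftNormalize:
    def test_homopolymer_deletion_shift_equivalence(self):
        """All shift-equivalent placements of a homopolymer deletion
        normalize to one key; the oracle is haplotype identity."""
        ref = "GGTAAAAAACCGT"
        # delete one A: representable anchored at positions 3..8
        keys = set()
        haplotypes = set()
        for anchor in range(3, 9):
            r = ref[anchor - 1 : anchor + 1]
            a = ref[anchor - 1]
            haplotypes.add(apply_variant(ref, anchor, r, a))
            keys.add(left_normalize(ref, anchor, r, a))
        assert len(haplotypes) == 1
        assert keys == {(3, "TA", "T")}

    def test_dinucleotide_insertion_normalization(self):
        ref = "TTACACACGG"
        # inserting AC is equivalent anywhere in the AC repeat
        keys = {
            left_normalize(ref, p, ref[p - 1], ref[p - 1] + "AC") for p in (2, 4, 6)
        }
        haps = {
            apply_variant(ref, p, ref[p - 1], ref[p - 1] + "AC") for p in (2, 4, 6)
        }
        assert len(haps) == 1
        assert len(keys) == 1
        assert keys.pop()[0] == 2

    def test_distinct_indels_stay_distinct(self):
        ref = "GGTACGTACC"
        k1 = left_normalize(ref, 3, ref[2:4], ref[2])
        k2 = left_normalize(ref, 4, ref[3:5], ref[3])
        assert k1 != k2

    def test_identity_rejected(self):
        with pytest.raises(ValueError):
            left_normalize("ACGT", 2, "C", "C")


class TestCollectCandidates:
    def _read(self, start, cigar, seq, rid="r"):
        return SimulatedRead(rid, "ref", start, seq, tuple([35] * len(seq)),
                             60, cigar)

    def test_no_gapped_reads(self):
        ref = random_reference(100, seed=1)
        reads = [self._read(1, "20M", ref[:20])]
        assert collect_candidate_indels(reads, ref) == []

    def test_shared_deletion_counted_once(self):
        ref = random_reference(100, seed=2)
        # 2bp deletion of ref[30:32] (anchor at 30)
        seq = ref[10:30] + ref[32:52]
        reads = [self._read(11, "20M2D20M", seq, f"r{i}") for i in range(5)]
        cands = collect_candidate_indels(reads, ref, min_support=2)
        assert len(cands) == 1
        c = cands[0]
        assert c.supporting_read_count == 5
        assert len(c.ref_allele) - len(c.alt_allele) == 2

    def test_min_support_filters(self):
        ref = random_reference(100, seed=2)
        seq = ref[10:30] + ref[32:52]
        reads = [self._read(11, "20M2D20M", seq)]
        assert collect_candidate_indels(reads, ref, min_support=2) == []
        assert len(collect_candidate_indels(reads, ref, min_support=1)) == 1

    def test_shifted_encodings_unify(self):
        """Two right/left-shifted CIGAR encodings of the same homopolymer
        deletion collapse to one left-normalized candidate."""
        ref = "GG" + "A" * 8 + random_reference(60, seed=3)
        hap = ref[:4] + ref[5:]  # one A deleted
        seq = hap[:20]
        r1 = self._read(1, "4M1D16M", seq, "r1")   # deletion after 4 bases
        r2 = self._read(1, "7M1D13M", seq, "r2")   # same haplotype, shifted
        cands = collect_candidate_indels([r1, r2], ref, min_support=2)
        assert len(cands) == 1
        assert cands[0].supporting_read_count == 2


class TestAltReference:
    def test_insertion_window_length(self):
        ref = random_reference(200, seed=4)
        ind = CandidateIndel("ref", 100, ref[99], ref[99] + "T", 3)
        ar = build_alt_reference(ref, ind, flank=30)
        assert len(ar.sequence) == (ar.window_end - ar.window_start + 1) + 1

    def test_deletion_window_length(self):
        ref = random_reference(200, seed=4)
        ind = CandidateIndel("ref", 100, ref[99:104], ref[99], 3)
        ar = build_alt_reference(ref, ind, flank=30)
        assert len(ar.sequence) == (ar.window_end - ar.window_start + 1) - 4

    def test_coordinate_map_monotone_and_invertible(self):
        ref = random_reference(200, seed=5)
        ind = CandidateIndel("ref", 100, ref[99:103], ref[99], 3)
        ar = build_alt_reference(ref, ind, flank=20)
        mapped = [ar.offset_to_ref(j) for j in range(len(ar.sequence))]
        vals = [m for m in mapped if m is not None]
        assert vals == sorted(vals)
        assert len(vals) == len(set(vals))
        assert all(ref[m - 1] == ar.sequence[j] for j, m in enumerate(mapped) if m)

    def test_identity_indel_rejected(self):
        with pytest.raises(ValueError):
            CandidateIndel("ref", 10, "A", "A", 2)

    def test_out_of_reference_rejected(self):
        ref = random_reference(50, seed=6)
        with pytest.raises(CoordinateError):
            build_alt_reference(ref, CandidateIndel("ref", 49, "ACGT", "A", 2), flank=10)


def _deletion_scenario(seed, del_len=3, ref_len=300, rate=0.0, coverage=60):
    ref = random_reference(ref_len, seed=seed)
    pos = ref_len // 2
    tv = TruthVariant("ref", pos, ref[pos - 1 : pos + del_len], ref[pos - 1],
                      "deletion", (5,), 0.1)
    reads = simulate_reads_with_indels(
        ref, [tv], coverage=coverage, seed=seed,
        misalignment_rate_near_indels=rate, alt_haplotype_fraction=0.7,
    )
    cands = collect_candidate_indels(reads, ref, min_support=2)
    alt_refs = [build_alt_reference(ref, c, flank=55) for c in cands]
    return ref, reads, alt_refs


class TestRealignRead:
    def test_read_without_window_overlap_unchanged(self):
        ref, reads, alt_refs = _deletion_scenario(seed=31, rate=0.3)
        far = [r for r in reads if not any(
            a.overlaps(r.start, r.start + reference_length(r.cigar) - 1)
            for a in alt_refs)]
        assert far
        for r in far[:10]:
            assert realign_read(r, alt_refs, ref) == r

    def test_misaligned_deletion_read_recovered(self):
        """A gapless forced alignment across a 3bp deletion realigns to a
        mismatch-free gapped alignment; brute force confirms the optimum."""
        ref, reads, alt_refs = _deletion_scenario(seed=32, rate=0.5)
        assert alt_refs, "candidate collection needs surviving gapped reads"
        forced = [r for r in reads if not has_gap(r.cigar)
                  and oracle_score(r, ref) < 55]
        assert forced
        for r in forced:
            new = realign_read(r, alt_refs, ref)
            assert has_gap(new.cigar)
            assert not new.is_original_alignment
            new_score = oracle_score(new, ref)
            assert new_score == 55  # perfect after realignment (error-free reads)
            assert new_score == oracle_best_alt_score(r, alt_refs)

    def test_tie_keeps_original(self):
        """A perfect read inside the flank scores equally on the alternate
        window; the original alignment is kept."""
        ref, reads, alt_refs = _deletion_scenario(seed=33, rate=0.0)
        perfect_overlapping = [
            r for r in reads
            if oracle_score(r, ref) == 55 and any(
                a.overlaps(r.start, r.start + reference_length(r.cigar) - 1)
                for a in alt_refs)
        ]
        assert perfect_overlapping
        for r in perfect_overlapping[:20]:
            assert realign_read(r, alt_refs, ref) == r


class TestApplyRealignment:
    def test_no_candidates_changes_nothing(self):
        ref = random_reference(200, seed=41)
        reads = simulate_reads_with_indels(ref, [], coverage=20, seed=41)
        new, frac = apply_realignment(reads, [], ref)
        assert frac == 0.0
        assert new == list(reads)

    def test_score_monotone_and_idempotent(self):
        ref, reads, alt_refs = _deletion_scenario(seed=42, rate=0.3,
                                                  coverage=80)
        new, frac = apply_realignment(reads, alt_refs, ref)
        assert frac > 0
        for old, upd in zip(reads, new):
            assert oracle_score(upd, ref) >= oracle_score(old, ref)
        again, frac2 = apply_realignment(new, alt_refs, ref)
        assert frac2 == 0.0
        assert again == new

    def test_matches_brute_force_on_random_reads(self):
        """Chosen placements equal exhaustive gapless enumeration
        (small-scale spot check; the full sweep runs elsewhere)."""
        rng = np.random.default_rng(7)
        for seed in (51, 52, 53):
            ref, reads, alt_refs = _deletion_scenario(
                seed=seed, del_len=int(rng.integers(1, 19)), rate=0.5)
            for r in reads[:100]:
                new = realign_read(r, alt_refs, ref)
                orig = oracle_score(r, ref)
                best_alt = oracle_best_alt_score(r, alt_refs)
                expected = orig if best_alt is None else max(orig, best_alt)
                assert oracle_score(new, ref) == expected
                if expected == orig:
                    assert new == r


def test_score_alignment_matches_oracle_on_gapped_reads():
    ref, reads, _ = _deletion_scenario(seed=61, rate=0.2)
    for r in reads[:50]:
        assert score_alignment(r, ref) == oracle_score(r, ref)
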