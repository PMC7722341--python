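"""Built-in detector, best-hit merging and context assignment."""

import numpy as np
import pytest

import nimtscan as ns
from nimtscan.core import GeneModel, GenomicInterval, MtlHit, SequenceRecord, revcomp
from nimtscan.detection import TrnaReference, merge_best_hit
from nimtscan.numtsim import _CLOVERLEAF_DB, _random_structured_trna


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(99)
    seq = _random_structured_trna(_CLOVERLEAF_DB, rng)
    return TrnaReference.from_strings("Tyr", seq, _CLOVERLEAF_DB)


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[k] for k in rng.integers(0, 4, n))


class TestBuiltinScan:
    def test_verbatim_embedding_found_exactly_once(self, reference):
        flank = _random_seq(2500, 1)
        nuclear = SequenceRecord("chr1", flank + reference.model.sequence
                                 + _random_seq(2500, 2))
        hits = ns.builtin_scan(nuclear, [reference])
        assert len(hits) == 1
        h = hits[0]
        assert (h.interval.start, h.interval.end) == (2500, 2500 + len(reference.model))
        assert h.interval.strand == "+" and h.isotype == "Tyr"

    def test_reverse_complement_embedding_found_on_minus_strand(self, reference):
        start = 1800
        embedded = revcomp(reference.model.sequence)
        nuclear = SequenceRecord("chr1", _random_seq(start, 3) + embedded
                                 + _random_seq(2000, 4))
        hits = ns.builtin_scan(nuclear, [reference])
        assert len(hits) == 1
        h = hits[0]
        assert h.interval.strand == "-"
        assert (h.interval.start, h.interval.end) == (start, start + len(embedded))
        # brute-force confirmation: the hit really is the reverse complement
        sub = nuclear.sequence[h.interval.start:h.interval.end]
        assert revcomp(sub) == reference.model.sequence

    def test_loop_mutations_score_above_stem_breaking_mutations(self, reference):
        """Equal substitution counts: structure bonus separates placements."""
        model = reference.model
        loops = [i for i in range(len(model)) if i not in model.pair_table][:5]
        stems = [i for i, j in model.pairs[:5]]

        def mutate(positions):
            s = list(model.sequence)
            for p in positions:
                s[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[p]]
            return "".join(s)

        flank_a, flank_b = _random_seq(800, 5), _random_seq(800, 6)
        hits_loop = ns.builtin_scan(
            SequenceRecord("chr1", flank_a + mutate(loops) + flank_b),
            [reference], min_score=10)
        hits_stem = ns.builtin_scan(
            SequenceRecord("chr1", flank_a + mutate(stems) + flank_b),
            [reference], min_score=10)
        best_loop = max(h.score for h in hits_loop)
        best_stem = max(h.score for h in hits_stem)
        # loop mutant keeps every reference pair -> full structure bonus
        L, lam = len(model), 5.0
        assert best_loop == pytest.approx(L - 2 * 5 + lam)
        assert best_loop > best_stem

    def test_reference_without_plausible_length_rejected(self):
        tiny = TrnaReference.from_strings("Ala", "ACGU", "....")
        with pytest.raises(ValueError, match="length"):
            ns.builtin_scan(SequenceRecord("chr1", _random_seq(500, 7)), [tiny])


def _hit(start, end, score, strand="+", isotype="Tyr"):
    return MtlHit(GenomicInterval("chr1", start, end, strand), isotype,
                  score, "builtin")


class TestMergeBestHit:
    def test_highest_score_survives_overlap(self):
        survivors = merge_best_hit([_hit(100, 170, 33.0), _hit(120, 190, 52.1)])
        assert [h.score for h in survivors] == [52.1]

    def test_non_overlapping_hits_all_survive(self):
        hits = [_hit(0, 50, 10), _hit(60, 110, 20), _hit(200, 250, 5)]
        assert len(merge_best_hit(hits)) == 3

    def test_opposite_strands_do_not_cluster(self):
        hits = [_hit(100, 170, 33.0), _hit(120, 190, 52.1, strand="-")]
        assert len(merge_best_hit(hits)) == 2

    def test_idempotent_and_non_overlapping_output(self):
        rng = np.random.default_rng(0)
        hits = [_hit(int(s), int(s) + int(l), float(rng.integers(1, 100)),
                     strand="+-"[int(rng.integers(2))])
                for s, l in zip(rng.integers(0, 2000, 200),
                                rng.integers(30, 90, 200))]
        once = merge_best_hit(hits)
        assert merge_best_hit(once) == once
        by_strand = {}
        for h in once:
            by_strand.setdefault(h.interval.strand, []).append(h.interval)
        for ivs in by_strand.values():
            ivs.sort(key=lambda iv: iv.start)
            assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))

    def test_survivors_equal_brute_force_cluster_argmax(self):
        """Random overlapping clusters: survivor = per-cluster best."""
        rng = np.random.default_rng(42)
        hits = []
        for c in range(100):
            base = c * 300
            for _ in range(int(rng.integers(1, 6))):
                s = base + int(rng.integers(0, 40))
                hits.append(_hit(s, s + int(rng.integers(50, 120)),
                                 float(rng.random() * 100)))
        survivors = merge_best_hit(hits)
        # oracle: exhaustive single-linkage clustering then argmax
        hits_sorted = sorted(hits, key=lambda h: h.interval.start)
        clusters, cur, cur_end = [], [], -1
        for h in hits_sorted:
            if cur and h.interval.start >= cur_end:
                clusters.append(cur)
                cur, cur_end = [], -1
            cur.append(h)
            cur_end = max(cur_end, h.interval.end)
        clusters.append(cur)
        oracle = sorted((max(c, key=lambda h: h.score) for c in clusters),
                        key=lambda h: h.interval.start)
        assert [h.score for h in survivors] == [h.score for h in oracle]


class TestAssignContext:
    @pytest.fixture()
    def gene(self):
        # 3 exons: [1000,1100) [1500,1600) [2000,2100); introns between
        return GeneModel("G1", "chr1", "+",
                         ((1000, 1100), (1500, 1600), (2000, 2100)))

    def test_hit_inside_intron_is_nimtrna(self, gene):
        (h,) = ns.assign_context([_hit(1620, 1690, 50)], [gene])
        assert h.context == "intronic" and h.host_gene == "G1"
        assert h.antisense_to_host is False

    def test_hit_without_transcript_overlap_is_intergenic(self, gene):
        (h,) = ns.assign_context([_hit(5000, 5070, 50)], [gene])
        assert h.context == "intergenic" and h.host_gene is None

    def test_minus_hit_in_plus_intron_is_antisense(self, gene):
        (h,) = ns.assign_context([_hit(1620, 1690, 50, strand="-")], [gene])
        assert h.context == "intronic" and h.antisense_to_host is True

    def test_exon_overlap_takes_precedence(self, gene):
        (h,) = ns.assign_context([_hit(1080, 1150, 50)], [gene])
        assert h.context == "exonic"

    def test_contexts_partition_the_hit_set(self, gene):
        hits = [_hit(s, s + 70, 10) for s in range(900, 2300, 55)]
        out = ns.assign_context(hits, [gene])
        assert len(out) == len(hits)
        assert all(h.context in ("intronic", "exonic", "intergenic") for h in out)

    def test_overlapping_exons_rejected_at_model_construction(self):
        with pytest.raises(ValueError, match="unsorted|overlap"):
            GeneModel("bad", "chr1", "+", ((100, 200), (150, 300)))
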