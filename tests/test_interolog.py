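"""Interolog prediction: geometry, alignment, conservation and the two routes."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apopath.interolog import (
    AMINO_ACIDS,
    Confidence,
    DomainAssignment,
    DomainStructure,
    InterfaceTemplate,
    Method,
    PredictedInteraction,
    PredictionConfig,
    extract_interface,
    filter_novel,
    global_align,
    global_identity,
    interface_conservation,
    predict_sequence,
    predict_structural,
    residue_contacts,
)

MATCH, MISMATCH, GAP = 1, 0, -1


def make_structure(domain_id, coords):
    coords = np.asarray(coords, dtype=float)
    return DomainStructure(domain_id, tuple(range(1, len(coords) + 1)), coords)


def brute_force_contacts(a, b, cutoff):
    """Independent all-pairs double loop over raw coordinates."""
    out = []
    for i, idx_a in enumerate(a.residue_indices):
        for j, idx_b in enumerate(b.residue_indices):
            d = float(np.sqrt(((a.coords[i] - b.coords[j]) ** 2).sum()))
            if d <= cutoff:
                out.append((idx_a, idx_b, d))
    return out


def enumerate_alignments(seq_a, seq_b):
    """All global alignments of two short sequences (exhaustive recursion)."""
    if not seq_a and not seq_b:
        yield ("", "")
        return
    if seq_a:
        for ta, tb in enumerate_alignments(seq_a[1:], seq_b):
            yield (seq_a[0] + ta, "-" + tb)
    if seq_b:
        for ta, tb in enumerate_alignments(seq_a, seq_b[1:]):
            yield ("-" + ta, seq_b[0] + tb)
    if seq_a and seq_b:
        for ta, tb in enumerate_alignments(seq_a[1:], seq_b[1:]):
            yield (seq_a[0] + ta, seq_b[0] + tb)


def alignment_score(aln_a, aln_b):
    score = 0
    for x, y in zip(aln_a, aln_b):
        if x == "-" or y == "-":
            score += GAP
        elif x == y:
            score += MATCH
        else:
            score += MISMATCH
    return score


def random_seq(rng, n):
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n))


# ---------------------------------------------------------------------------
# residue contacts


class TestResidueContacts:
    def test_single_residue_pairs_straddling_cutoff(self):
        a = make_structure("a", [[0, 0, 0]])
        near = make_structure("b", [[4.9, 0, 0]])
        far = make_structure("c", [[5.1, 0, 0]])
        assert len(residue_contacts(a, near, 5.0)) == 1
        assert residue_contacts(a, far, 5.0) == []

    def test_matches_brute_force_on_random_domains(self, rng):
        for _ in range(5):
            a = make_structure("a", rng.uniform(0, 12, size=(20, 3)))
            b = make_structure("b", rng.uniform(0, 12, size=(20, 3)))
            got = sorted(residue_contacts(a, b, 5.0))
            expected = sorted(brute_force_contacts(a, b, 5.0))
            assert [(i, j) for i, j, _ in got] == [(i, j) for i, j, _ in expected]
            assert np.allclose([d for *_, d in got], [d for *_, d in expected])

    def test_transpose_symmetry_and_cutoff_monotonicity(self, rng):
        a = make_structure("a", rng.uniform(0, 10, size=(15, 3)))
        b = make_structure("b", rng.uniform(0, 10, size=(15, 3)))
        ab = residue_contacts(a, b, 5.0)
        ba = residue_contacts(b, a, 5.0)
        assert sorted((j, i) for i, j, _ in ab) == sorted((i, j) for i, j, _ in ba)
        n_prev = 0
        for cutoff in (2.0, 4.0, 6.0, 10.0):
            n = len(residue_contacts(a, b, cutoff))
            assert n >= n_prev
            n_prev = n

    def test_empty_structure_gives_empty_list(self):
        a = make_structure("a", np.empty((0, 3)))
        b = make_structure("b", [[0, 0, 0]])
        assert residue_contacts(a, b, 5.0) == []


class TestExtractInterface:
    def _pair_with_contacts(self, k):
        # k residue pairs at 4 A, everything else far apart
        a = [[10.0 * i, 0, 0] for i in range(k)] + [[0, 1000, 0]]
        b = [[10.0 * i, 4.0, 0] for i in range(k)] + [[0, -1000, 0]]
        return make_structure("a", a), make_structure("b", b)

    def test_at_least_five_contacts_is_inclusive(self):
        a, b = self._pair_with_contacts(5)
        iface = extract_interface(a, b)
        assert iface is not None
        assert iface[0] == frozenset(range(1, 6))

    def test_four_contacts_is_below_gate(self):
        a, b = self._pair_with_contacts(4)
        assert extract_interface(a, b) is None

    def test_interface_counts_distinct_residues(self):
        # residue 1 of a touches 3 b-residues; residues 2,3 touch one each
        a = make_structure("a", [[0, 0, 0], [0, 3, 0], [0, -3, 0]])
        b = make_structure("b", [[1, 0, 0], [1, 3, 0], [1, -3, 0]])
        contacts = residue_contacts(a, b, 5.0)
        assert len(contacts) >= 5
        iface = extract_interface(a, b)
        assert iface[0] == frozenset(i for i, _, _ in contacts)
        assert iface[1] == frozenset(j for _, j, _ in contacts)


# ---------------------------------------------------------------------------
# alignment and conservation


class TestGlobalIdentity:
    def test_identical_sequences(self):
        assert global_identity("ACDEFGHIK", "ACDEFGHIK") == 1.0

    def test_eight_of_ten_matches(self):
        assert global_identity("AAAAAAAAAA", "AAAAAAAAGG") == pytest.approx(0.8)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_identity("", "ACD")

    def test_alignment_is_valid_and_optimal_vs_biopython(self, rng):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = MATCH
        aligner.mismatch_score = MISMATCH
        aligner.open_gap_score = GAP
        aligner.extend_gap_score = GAP
        for _ in range(20):
            sa, sb = random_seq(rng, 30), random_seq(rng, 25)
            aln_a, aln_b = global_align(sa, sb)
            assert aln_a.replace("-", "") == sa
            assert aln_b.replace("-", "") == sb
            assert alignment_score(aln_a, aln_b) == aligner.score(sa, sb)
            matches = sum(1 for x, y in zip(aln_a, aln_b) if x == y and x != "-")
            assert global_identity(sa, sb) == pytest.approx(matches / len(aln_a))

    def test_identity_among_optimal_alignments_small_exhaustive(self, rng):
        for _ in range(15):
            sa = random_seq(rng, int(rng.integers(1, 5)))
            sb = random_seq(rng, int(rng.integers(1, 5)))
            alignments = list(enumerate_alignments(sa, sb))
            best = max(alignment_score(a, b) for a, b in alignments)
            optimal_identities = {
                sum(1 for x, y in zip(a, b) if x == y and x != "-") / len(a)
                for a, b in alignments
                if alignment_score(a, b) == best
            }
            aln_a, aln_b = global_align(sa, sb)
            assert alignment_score(aln_a, aln_b) == best
            assert global_identity(sa, sb) in optimal_identities

    @settings(derandomize=True, max_examples=50)
    @given(st.text(alphabet=AMINO_ACIDS[:-1], min_size=1, max_size=15))
    def test_self_identity_is_one(self, seq):
        assert global_identity(seq, seq) == 1.0


class TestInterfaceConservation:
    def test_identical_query_fully_conserved(self):
        assert interface_conservation("ACDEFGHIKL", "ACDEFGHIKL", {1, 4, 9}) == 1.0

    def test_three_of_ten_boundary(self):
        template = "ACDEFGHIKL"
        query = "ACD" + "W" * 7  # conserves positions 1-3 only
        assert interface_conservation(query, template, set(range(1, 11))) == pytest.approx(0.30)

    def test_known_mutation_mask(self, rng):
        template = random_seq(rng, 40).replace("W", "A")
        interface = {3, 7, 11, 19, 23, 31, 37}
        mutated_at = {7, 19, 37}
        query = "".join(
            "W" if (i + 1) in mutated_at else c for i, c in enumerate(template)
        )
        expected = sum(1 for p in interface if p not in mutated_at) / len(interface)
        assert interface_conservation(query, template, interface) == pytest.approx(expected)

    def test_non_interface_mutations_do_not_matter(self, rng):
        template = random_seq(rng, 30).replace("W", "A")
        interface = {2, 10, 20}
        query = "".join(
            "W" if (i + 1) not in interface else c for i, c in enumerate(template)
        )
        # alignment still gap-free: same length, score dominated by interface
        assert interface_conservation(query, template, interface) == 1.0

    def test_empty_interface_rejected(self):
        with pytest.raises(ValueError):
            interface_conservation("ACD", "ACD", set())


# ---------------------------------------------------------------------------
# prediction routes


def _template(seq_a, seq_b, iface, tid="t1", fam_a="fa", fam_b="fb"):
    return InterfaceTemplate(
        family_a=fam_a, family_b=fam_b, seq_a=seq_a, seq_b=seq_b,
        interface_a=frozenset(iface), interface_b=frozenset(iface), template_id=tid,
    )


class TestPredictStructural:
    def setup_method(self):
        self.template_seq = "ACDEFGHIKLMNPQRSTVWY"
        self.iface = set(range(1, 11))

    def _query(self, n_conserved):
        # mutate interface positions beyond n_conserved, keep the tail intact
        q = list(self.template_seq)
        for pos in range(n_conserved + 1, 11):
            q[pos - 1] = "Y" if q[pos - 1] != "Y" else "W"
        return "".join(q)

    def test_both_sides_above_threshold_emitted_with_min_score(self):
        tmpl = _template(self.template_seq, self.template_seq, self.iface)
        seqs = {"P": self._query(4), "Q": self._query(6)}
        preds = predict_structural(
            [DomainAssignment("P", "fa"), DomainAssignment("Q", "fb")], [tmpl], seqs
        )
        assert len(preds) == 1
        assert preds[0].score == pytest.approx(0.4)
        assert preds[0].method is Method.STRUCTURE

    def test_exactly_thirty_percent_is_rejected(self):
        tmpl = _template(self.template_seq, self.template_seq, self.iface)
        seqs = {"P": self._query(3), "Q": self._query(8)}
        assert predict_structural(
            [DomainAssignment("P", "fa"), DomainAssignment("Q", "fb")], [tmpl], seqs
        ) == []

    def test_medium_confidence_assignments_never_used(self):
        tmpl = _template(self.template_seq, self.template_seq, self.iface)
        seqs = {"P": self.template_seq, "Q": self.template_seq}
        preds = predict_structural(
            [
                DomainAssignment("P", "fa", Confidence.MEDIUM),
                DomainAssignment("Q", "fb", Confidence.HIGH),
            ],
            [tmpl], seqs,
        )
        assert preds == []

    def test_template_order_does_not_change_output(self):
        t1 = _template(self.template_seq, self.template_seq, self.iface, tid="t1")
        t2 = _template(self.template_seq, self.template_seq, self.iface, tid="t2")
        seqs = {"P": self._query(8), "Q": self._query(8)}
        assigns = [DomainAssignment("P", "fa"), DomainAssignment("Q", "fb")]
        fwd = predict_structural(assigns, [t1, t2], seqs)
        rev = predict_structural(assigns, [t2, t1], seqs)
        assert fwd == rev
        assert fwd[0].template_or_source == "t1"  # tie -> smallest template id

    def test_self_interaction_only_for_self_paired_family(self):
        homo = _template(self.template_seq, self.template_seq, self.iface,
                         tid="homo", fam_a="fa", fam_b="fa")
        seqs = {"P": self.template_seq}
        preds = predict_structural([DomainAssignment("P", "fa")], [homo], seqs)
        assert len(preds) == 1 and preds[0].protein_a == preds[0].protein_b == "P"
        hetero = _template(self.template_seq, self.template_seq, self.iface)
        assert predict_structural(
            [DomainAssignment("P", "fa"), DomainAssignment("P", "fb")], [hetero], seqs
        ) == []


class TestPredictSequence:
    def test_verbatim_pair_scores_one(self):
        seqs = {"P": "ACDEFGHIKL", "Q": "MNPQRSTVWY"}
        known = [("ACDEFGHIKL", "MNPQRSTVWY", "db:1")]
        preds = predict_sequence([("P", "Q")], known, seqs)
        assert len(preds) == 1
        assert preds[0].score == 1.0
        assert preds[0].template_or_source == "db:1"

    def test_identity_exactly_eighty_percent_rejected(self):
        seqs = {"P": "AAAAAAAAGG", "Q": "CCCCCCCCCC"}
        known = [("AAAAAAAAAA", "CCCCCCCCCC", "db:1")]  # P side is exactly 0.8
        assert predict_sequence([("P", "Q")], known, seqs) == []

    def test_swapped_orientation_matches(self):
        seqs = {"P": "MNPQRSTVWY", "Q": "ACDEFGHIKL"}
        known = [("ACDEFGHIKL", "MNPQRSTVWY", "db:1")]
        assert len(predict_sequence([("P", "Q")], known, seqs)) == 1

    def test_matches_brute_force_over_all_matchings(self, rng):
        symbols = [f"P{i}" for i in range(5)]
        seqs = {s: random_seq(rng, 20) for s in symbols}
        known = []
        for k in range(3):
            # reference pairs derived from candidate sequences with few mutations
            base_x = seqs[symbols[k]]
            base_y = seqs[symbols[(k + 2) % 5]]
            known.append((base_x[:-1] + "A", base_y, f"db:{k}"))
        candidates = list(itertools.combinations(symbols, 2))
        preds = predict_sequence(candidates, known, seqs)
        got = {p.pair for p in preds}
        cfg = PredictionConfig()
        expected = set()
        for p, q in candidates:
            for x, y, _ in known:
                for sp, sq in ((x, y), (y, x)):
                    if (
                        global_identity(seqs[p], sp) > cfg.identity_threshold
                        and global_identity(seqs[q], sq) > cfg.identity_threshold
                    ):
                        expected.add(frozenset((p, q)))
        assert got == expected


class TestFilterNovel:
    def _pred(self, a, b):
        return PredictedInteraction(a, b, Method.SEQUENCE, 0.9, "src")

    def test_unordered_pair_matching(self):
        preds = [self._pred("A", "B"), self._pred("C", "D")]
        kept = filter_novel(preds, [("B", "A")])
        assert [(p.protein_a, p.protein_b) for p in kept] == [("C", "D")]
        assert all(p.novel for p in kept)

    def test_empty_known_keeps_everything(self):
        preds = [self._pred("A", "B"), self._pred("C", "D")]
        assert len(filter_novel(preds, [])) == 2

    @settings(derandomize=True, max_examples=30)
    @given(st.data())
    def test_set_difference_and_count_conservation(self, data):
        names = [f"G{i}" for i in range(12)]
        pair = st.tuples(st.sampled_from(names), st.sampled_from(names)).filter(
            lambda p: p[0] != p[1]
        )
        predicted_pairs = data.draw(st.lists(pair, max_size=20, unique_by=frozenset))
        known = data.draw(st.lists(pair, max_size=10))
        preds = [self._pred(a, b) for a, b in predicted_pairs]
        kept = filter_novel(preds, known)
        known_sets = {frozenset(k) for k in known}
        assert {p.pair for p in kept} == {
            frozenset(p) for p in predicted_pairs
        } - known_sets
        assert len(kept) + sum(
            1 for p in predicted_pairs if frozenset(p) in known_sets
        ) == len(predicted_pairs)
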