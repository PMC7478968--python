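"""Alignment, edit extraction/normalization, frame classification,
translation and duplicate-clone collapsing."""

import pytest
from hypothesis import given, strategies as st

from crispre.alleles import (
    AlleleCall,
    CloneObservation,
    Edit,
    FRAME_IN,
    FRAME_P1,
    FRAME_P2,
    FRAME_WT,
    STATUS_FAILED,
    UnalignableCloneError,
    align_clone,
    apply_edits,
    build_aligner,
    call_clone,
    call_experiment,
    classify_allele,
    collapse_identical_clones,
    extract_edits,
    net_frame_shift,
    normalize_edits,
    translate_allele,
)
from crispre.target import CrisprEError, ReferenceTarget, TargetSite, find_target_site
from oracles import brute_force_alignment_score, enumerate_left_shifts

DNA = st.text(alphabet="ACGT", min_size=1)


def _site(ref: ReferenceTarget, cut: int, halfwidth: int = 30) -> TargetSite:
    return TargetSite(
        protospacer="A" * 20,
        pam="AGG",
        strand="+",
        cut_index=cut,
        window_start=max(0, cut - halfwidth),
        window_end=min(len(ref.sequence), cut + halfwidth),
    )


class TestAlignClone:
    def test_three_nt_deletion_recovered_as_one_gap(self):
        ref = ReferenceTarget("r", "ATGGCAGCTTAA", 0, 12)
        aln = align_clone(ref, CloneObservation("c", "ATGGCTTAA"))
        assert aln.clone_gapped.count("-") == 3
        assert aln.ref_gapped.count("-") == 0
        # one contiguous gap run
        runs = [r for r in aln.clone_gapped.split("-") if r]
        assert len(runs) <= 2
        assert aln.score == brute_force_alignment_score(ref.sequence, "ATGGCTTAA")

    def test_identity_case_is_gapless(self):
        ref = ReferenceTarget("r", "ATGGCAGCTTAA", 0, 12)
        aln = align_clone(ref, CloneObservation("c", ref.sequence))
        assert aln.identity == 1.0
        assert "-" not in aln.ref_gapped + aln.clone_gapped

    def test_unrelated_sequence_is_unalignable(self):
        ref = ReferenceTarget("r", "ATGGCAGCTTCGCATTGCAT", 0, 20)
        with pytest.raises(UnalignableCloneError):
            align_clone(ref, CloneObservation("c", "A" * 20))

    def test_length_outlier_is_unalignable(self):
        ref = ReferenceTarget("r", "ATGGCAGCTTCGCATTGCAT", 0, 20)
        with pytest.raises(UnalignableCloneError):
            align_clone(ref, CloneObservation("c", "ATG"))

    @pytest.mark.parametrize("seed", range(6))
    def test_score_matches_brute_force_enumeration(self, seed):
        """Aligner score equals exhaustive enumeration on short strings."""
        import numpy as np

        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 13))))
        b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 13))))
        aligner = build_aligner()
        assert aligner.score(a, b) == brute_force_alignment_score(a, b)


class TestExtractEdits:
    def test_deletion_is_left_normalized(self):
        ref = ReferenceTarget("r", "ATGGCAGCTTAA", 0, 12)
        aln = align_clone(ref, CloneObservation("c", "ATGGCTTAA"))
        edits = extract_edits(aln, ref.sequence)
        assert len(edits) == 1
        (e,) = edits
        assert e.kind == "deletion" and len(e.ref_allele) == 3
        assert e.position == enumerate_left_shifts(ref.sequence, e.position, e.ref_allele)

    def test_gapless_identical_alignment_yields_no_edits(self):
        ref = ReferenceTarget("r", "ATGGCAGCTTAA", 0, 12)
        aln = align_clone(ref, CloneObservation("c", ref.sequence))
        assert extract_edits(aln, ref.sequence) == []

    def test_insertion_plus_substitution_called_separately(self):
        """A +7 insertion with one substitution yields two edits."""
        ref = ReferenceTarget("r", "ATGGTTCAAGCTGGTCATCCTGAATCTGCTAGT", 0, 33)
        edits_in = [
            Edit("insertion", 15, "", "ACCGGTA"),
            Edit("substitution", 20, ref.sequence[20], "A" if ref.sequence[20] != "A" else "C"),
        ]
        clone = apply_edits(ref.sequence, edits_in)
        aln = align_clone(ref, CloneObservation("c", clone))
        edits = extract_edits(aln, ref.sequence)
        kinds = sorted(e.kind for e in edits)
        assert kinds == ["insertion", "substitution"]
        assert net_frame_shift(edits) == 7
        assert sum(1 for e in edits if e.kind == "substitution") == 1

    def test_roundtrip_reconstructs_clone(self):
        ref = ReferenceTarget("r", "ATGGTTCAAGCTGGTCATCCTGAATCTGCTAGT", 0, 33)
        clone = "ATGGTTCAAGCTCATCCTGTATCTGCTAGT"
        aln = align_clone(ref, CloneObservation("c", clone))
        edits = extract_edits(aln, ref.sequence)
        assert apply_edits(ref.sequence, edits) == clone


class TestNormalizeEdits:
    def test_deletion_shifts_to_five_prime_most_placement(self):
        ref = "ATGAAAAAGCT"
        edits = normalize_edits([Edit("deletion", 6, "AA", "")], ref)
        assert edits[0].position == enumerate_left_shifts(ref, 6, "AA")

    def test_insertion_rotates_into_repeat_context(self):
        ref = "ATGCCCGGG"
        (e,) = normalize_edits([Edit("insertion", 6, "", "CC")], ref)
        # CC insertion after CCC is equivalent at any point of the run
        assert e.position == 3
        assert apply_edits(ref, [e]) == apply_edits(ref, [Edit("insertion", 6, "", "CC")])

    def test_normalization_preserves_applied_sequence(self):
        ref = "ATGGCAGCAGCATTGCA"
        raw = [Edit("deletion", 9, "GCA", ""), Edit("substitution", 14, "G", "T")]
        norm = normalize_edits(raw, ref)
        assert apply_edits(ref, norm) == apply_edits(ref, raw)


class TestClassification:
    @pytest.mark.parametrize(
        "net,expected",
        [(12, FRAME_IN), (3, FRAME_IN), (-6, FRAME_IN), (4, FRAME_P1), (7, FRAME_P1),
         (-22, FRAME_P2), (-4, FRAME_P2), (-17, FRAME_P1), (-1, FRAME_P2)],
    )
    def test_residue_classes(self, net, expected):
        if net > 0:
            edits = [Edit("insertion", 5, "", "A" * net)]
        else:
            edits = [Edit("deletion", 5, "G" * (-net), "")]
        assert classify_allele(edits) == expected

    def test_empty_edits_is_wt(self):
        assert classify_allele([]) == FRAME_WT

    def test_substitution_only_is_edited_in_frame(self):
        edits = [Edit("substitution", 5, "A", "G")]
        assert classify_allele(edits) == FRAME_IN
        assert net_frame_shift(edits) == 0

    def test_classification_invariant_to_edit_order(self):
        edits = [Edit("insertion", 3, "", "AT"), Edit("deletion", 8, "GCA", "")]
        assert classify_allele(edits) == classify_allele(list(reversed(edits)))

    def test_multiple_indels_sum_to_net(self):
        edits = [Edit("insertion", 3, "", "AT"), Edit("deletion", 8, "GCA", "")]
        assert net_frame_shift(edits) == -1


class TestTranslation:
    def _ref(self):
        # ORF: ATG GCT GGT CAT CCT GAA TCT GCT AGT TAA
        return ReferenceTarget("r", "TT" + "ATGGCTGGTCATCCTGAATCTGCTAGTTAA" + "TT", 2, 32)

    def test_codon_aligned_inframe_deletion_removes_one_residue(self):
        ref = self._ref()
        site = _site(ref, cut=14, halfwidth=10)
        edits = [Edit("deletion", 11, "CAT", "")]  # removes the His codon
        prot, stop_gain = translate_allele(ref, edits, site)
        ref_prot, _ = translate_allele(ref, [], site)
        assert not stop_gain
        assert len(ref_prot) - len(prot) == 1
        assert "H" not in prot and "H" in ref_prot

    def test_midcodon_inframe_insertion_adds_one_residue(self):
        ref = self._ref()
        site = _site(ref, cut=13, halfwidth=10)
        edits = [Edit("insertion", 13, "", "GGT")]
        prot, stop_gain = translate_allele(ref, edits, site)
        ref_prot, _ = translate_allele(ref, [], site)
        assert len(prot) - len(ref_prot) == 1
        assert not stop_gain

    def test_frameshift_diverges_from_cut_onward(self):
        ref = self._ref()
        site = _site(ref, cut=14, halfwidth=10)
        edits = [Edit("deletion", 14, ref.sequence[14], "")]
        prot, stop_gain = translate_allele(ref, edits, site)
        ref_prot, _ = translate_allele(ref, [], site)
        assert prot[:4] == ref_prot[:4]  # MAGH prefix intact
        assert prot[4:] != ref_prot[4 : 4 + len(prot) - 4]
        assert not stop_gain

    def test_inframe_substitution_creating_stop_is_flagged(self):
        ref = self._ref()
        site = _site(ref, cut=14, halfwidth=10)
        # GAA -> TAA at codon starting offset 15 (ref position 17)
        edits = [Edit("substitution", 17, "G", "T")]
        prot, stop_gain = translate_allele(ref, edits, site)
        assert stop_gain
        assert "*" in prot

    def test_inframe_protein_length_change_is_net_over_three(self):
        ref = self._ref()
        site = _site(ref, cut=14, halfwidth=10)
        for edits in ([Edit("deletion", 11, "CATCCT", "")],
                      [Edit("insertion", 14, "", "GCTAGTGCA")]):
            prot, stop_gain = translate_allele(ref, edits, site)
            ref_prot, _ = translate_allele(ref, [], site)
            if not stop_gain:
                assert abs(len(prot) - len(ref_prot)) * 3 == abs(net_frame_shift(edits))


class TestCollapse:
    def _calls(self, sigs):
        calls = []
        for i, sig in enumerate(sigs):
            if sig is None:
                calls.append(AlleleCall(clone_id=f"c{i}", status=STATUS_FAILED))
                continue
            edits = tuple(sig)
            calls.append(
                AlleleCall(
                    clone_id=f"c{i}",
                    edits=edits,
                    in_window=tuple(True for _ in edits),
                    net_indel=net_frame_shift(edits),
                    frame_class=classify_allele(edits),
                )
            )
        return calls

    def test_identical_pairs_merge_into_single_events(self):
        a = [Edit("insertion", 5, "", "AC")]
        b = [Edit("deletion", 7, "G", "")]
        calls = self._calls([a, a, b, b, [Edit("deletion", 3, "TT", "")]])
        events, summary = collapse_identical_clones(calls)
        assert summary.n_events == 3
        assert summary.n_edited == 5

    def test_all_distinct_clones_stay_distinct(self):
        sigs = [[Edit("insertion", i, "", "A")] for i in range(4)]
        events, summary = collapse_identical_clones(self._calls(sigs))
        assert summary.n_events == summary.n_edited == 4

    def test_three_identical_clones_collapse_to_one_event(self):
        sig = [Edit("deletion", 5, "GT", "")]
        events, summary = collapse_identical_clones(self._calls([sig, sig, sig]))
        assert summary.n_events == 1
        assert events[0].clone_ids == ("c0", "c1", "c2")

    def test_wt_clones_never_merge_with_edited(self):
        calls = self._calls([[], [], [Edit("deletion", 5, "G", "")]])
        events, summary = collapse_identical_clones(calls)
        assert summary.n_wt == 2
        assert summary.n_events == 1

    def test_clone_conservation_invariant(self):
        calls = self._calls([None, [], [Edit("deletion", 5, "G", "")], None])
        _, s = collapse_identical_clones(calls)
        assert s.n_clones == s.n_failed + s.n_wt + s.n_edited == 4


class TestCallClone:
    def test_failed_clone_passes_through(self):
        ref = ReferenceTarget("r", "ATGGCAGCTTAA", 0, 12)
        site = _site(ref, cut=6)
        call = call_clone(ref, site, CloneObservation("c", None))
        assert call.status == STATUS_FAILED
        assert call.frame_class is None

    def test_unalignable_clone_degraded_to_failed(self):
        ref = ReferenceTarget("r", "ATGGCAGCTTCGCATTGCAT", 0, 20)
        site = _site(ref, cut=10)
        call = call_clone(ref, site, CloneObservation("c", "A" * 20))
        assert call.status == STATUS_FAILED

    def test_outside_window_edits_classified_wt_at_target(self):
        seq = "ATGGCTGGTCATCCTGAATCTGCTAGTCCAGGTGCTGGTCATTAA"
        ref = ReferenceTarget("r", seq, 0, len(seq))
        site = _site(ref, cut=35, halfwidth=4)
        clone = apply_edits(seq, [Edit("deletion", 5, seq[5:7], "")])
        call = call_clone(ref, site, CloneObservation("c", clone))
        assert call.frame_class == FRAME_WT
        assert call.edits and not call.edited


@given(
    seq=st.text(alphabet="ACGT", min_size=30, max_size=60),
    del_len=st.integers(min_value=1, max_value=6),
    del_at=st.floats(min_value=0.1, max_value=0.7),
    sub_at=st.floats(min_value=0.75, max_value=0.95),
)
def test_roundtrip_property_apply_align_extract(seq, del_len, del_at, sub_at):
    """Applying the extracted edits always reconstructs the clone."""
    pos = int(del_at * len(seq))
    del_len = min(del_len, len(seq) - pos - 5)
    edits = [Edit("deletion", pos, seq[pos : pos + del_len], "")] if del_len >= 1 else []
    spos = int(sub_at * len(seq))
    if edits and spos <= pos + del_len:
        return  # substitution would overlap the deletion
    old = seq[spos]
    new = {"A": "C", "C": "G", "G": "T", "T": "A"}[old]
    edits.append(Edit("substitution", spos, old, new))
    clone = apply_edits(seq, edits)
    ref = ReferenceTarget("r", seq, 0, len(seq))
    try:
        aln = align_clone(ref, CloneObservation("c", clone))
    except UnalignableCloneError:
        return  # heavily degenerate sequences may fall below the floor
    extracted = extract_edits(aln, seq)
    assert apply_edits(seq, extracted) == clone
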