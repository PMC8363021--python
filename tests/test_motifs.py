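"""Zinc-finger scanner and DBD assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import oracle_fingers, oracle_max_pairing
from nrminer.config import RunConfig
from nrminer.motifs import (
    FingerKind,
    ProteinRecord,
    ValidationError,
    ZincFinger,
    assemble_dbds,
    detect_chc2,
    extract_dbox,
    extract_pbox,
    find_zinc_fingers,
    scan_record,
)

CI_TOY = "CAVCNDYASGYHYGVWSCEGCKGFFRR"
CII_TOY = "CPATNQCTIDKNRRKSCQAC"
CHC2_TOY = "CPATNQHTIDKNRRKSCQAC"


def rec(seq, rid="t"):
    return ProteinRecord(id=rid, species="Syn", sequence=seq)


def as_tuples(fingers):
    return {
        (f.kind.value, f.start, f.end, f.chelator_positions) for f in fingers
    }


class TestFindZincFingers:
    def test_ci_toy(self):
        fingers = find_zinc_fingers(rec(CI_TOY))
        assert as_tuples(fingers) == {("CI", 0, 21, (0, 3, 17, 20))}

    def test_cii_chc2_toy(self):
        fingers = find_zinc_fingers(rec(CHC2_TOY))
        assert as_tuples(fingers) == {("CII_CHC2", 0, 20, (0, 6, 16, 19))}
        assert CHC2_TOY[6] == "H"

    def test_chc2_suppressed_when_disallowed(self):
        assert find_zinc_fingers(rec(CHC2_TOY), allow_chc2=False) == []

    def test_no_chelators(self):
        assert find_zinc_fingers(rec("MAAAKLM")) == []

    def test_invalid_residue_names_position(self):
        with pytest.raises(ValidationError, match="position 3"):
            rec("MAA*KLM")

    def test_x_never_matches_chelator_but_matches_spacer(self):
        seq = list(CI_TOY)
        seq[5] = "X"  # spacer
        assert len(find_zinc_fingers(rec("".join(seq)))) == 1
        seq = list(CI_TOY)
        seq[3] = "X"  # chelator
        assert find_zinc_fingers(rec("".join(seq))) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        alphabet = list("ACDEFGHIKLMNPQRSTVWYX")
        # C/H enriched so finger patterns actually occur
        probs = np.ones(21)
        probs[alphabet.index("C")] = 8
        probs[alphabet.index("H")] = 4
        probs /= probs.sum()
        seq = "".join(rng.choice(alphabet, size=10_000, p=probs))
        fingers = find_zinc_fingers(rec(seq))
        assert as_tuples(fingers) == oracle_fingers(seq)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACH" + "DGKX", min_size=1, max_size=120))
    def test_oracle_equivalence_property(self, seq):
        assert as_tuples(find_zinc_fingers(rec(seq))) == oracle_fingers(seq)

    def test_every_finger_revalidates(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACHDGK"), size=2000))
        for f in find_zinc_fingers(rec(seq)):
            f.validate(seq)

    def test_widened_ci_spacing(self):
        cfg = RunConfig(ci_inner_min=12, ci_inner_max=14)
        seq = "CAAC" + "D" * 12 + "CAAC"
        assert as_tuples(find_zinc_fingers(rec(seq), config=cfg)) == {
            ("CI", 0, 20, (0, 3, 16, 19))
        }
        assert find_zinc_fingers(rec(seq)) == []  # canonical spacing only


class TestAssembleDBDs:
    def test_single_dbd(self):
        seq = CI_TOY + "DGG" + CII_TOY
        hits, partial, arch = scan_record(rec(seq))
        assert arch.label == "single"
        assert len(hits) == 1 and not partial
        hit = hits[0]
        assert (hit.start, hit.end) == (0, 50)
        assert hit.ci.end <= hit.cii.start

    def test_tandem_dbds_are_2dbd(self):
        unit = CI_TOY + "DGG" + CII_TOY
        seq = unit + "M" * 30 + unit
        hits, _, arch = scan_record(rec(seq))
        assert arch.label == "2DBD"
        assert [h.index_in_protein for h in hits] == [0, 1]
        spans = [(h.start, h.end) for h in hits]
        assert spans[0][1] <= spans[1][0]

    def test_unpaired_fingers_reported_as_partial(self):
        hits, partial, arch = scan_record(rec(CI_TOY))
        assert not hits and arch.label == "none"
        assert [f.kind for f in partial] == [FingerKind.CI]

    def test_gap_bounds_respected(self):
        seq = CI_TOY[:21] + "A" * 50 + CII_TOY  # gap 50 > gap_max
        hits, partial, _ = scan_record(rec(seq))
        assert not hits and len(partial) == 2

    @pytest.mark.parametrize("seed", range(20))
    def test_pair_count_matches_exhaustive_oracle(self, seed, config):
        # random synthetic finger layouts, pairing compared against brute force
        rng = np.random.default_rng(seed)
        n_ci, n_cii = rng.integers(0, 4), rng.integers(0, 4)
        cis = sorted(
            (int(s), int(s) + 21) for s in rng.integers(0, 300, size=n_ci)
        )
        ciis = sorted(
            (int(s), int(s) + 20) for s in rng.integers(0, 300, size=n_cii)
        )
        fingers = [
            ZincFinger(FingerKind.CI, s, e, (s, s + 3, s + 17, s + 20))
            for s, e in cis
        ] + [
            ZincFinger(FingerKind.CII_C4, s, e, (s, s + 6, s + 16, s + 19))
            for s, e in ciis
        ]
        seq = _layout_sequence(fingers, 400)
        record = rec(seq)
        hits, _, _ = assemble_dbds(record, sorted(fingers, key=lambda f: f.start))
        assert len(hits) == oracle_max_pairing(
            cis, ciis, config.gap_min, config.gap_max
        )

    def test_no_overlapping_hits(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACHDGK"), size=3000))
        hits, _, _ = scan_record(rec(seq))
        for a, b in zip(hits, hits[1:]):
            assert a.end <= b.start


def _layout_sequence(fingers, length):
    """Materialise a protein carrying exactly the given finger spans."""
    seq = ["A"] * length
    for f in fingers:
        for i, pos in enumerate(f.chelator_positions):
            seq[pos] = "C"
    return "".join(seq)


class TestPBoxDBox:
    def test_pbox_from_ci_toy(self):
        hits, _, _ = scan_record(rec(CI_TOY + "DGG" + CII_TOY))
        pbox = hits[0].pbox
        assert pbox.sequence == "CEGCKGFFRR"
        assert pbox.core6 == "CEGCKG"
        assert not pbox.partial

    def test_dbox_c4_and_chc2(self):
        for cii, chc2 in ((CII_TOY, False), (CHC2_TOY, True)):
            seq = CI_TOY + "DGG" + cii
            hits, _, _ = scan_record(rec(seq))
            assert hits[0].dbox.sequence == "PATNQ"
            assert hits[0].dbox.chc2 is chc2
            assert detect_chc2(hits[0]) is chc2

    def test_truncated_pbox_flagged_partial(self):
        fingers = find_zinc_fingers(rec(CI_TOY[:24]))
        pbox = extract_pbox(CI_TOY[:24], fingers[0])
        assert pbox.partial and len(pbox.sequence) == 7

    def test_extraction_idempotent(self):
        seq = CI_TOY + "DGG" + CII_TOY
        hits, _, _ = scan_record(rec(seq))
        h = hits[0]
        assert extract_pbox(seq, h.ci) == h.pbox
        assert extract_dbox(seq, h.cii) == h.dbox


class TestChc2Panel:
    def test_exactly_k_of_n_flagged(self):
        from nrminer.simulate import ProteinSpec, generate_protein

        flags = [i % 3 == 0 for i in range(30)]
        found = 0
        for i, want in enumerate(flags):
            record, _ = generate_protein(
                ProteinSpec(n_dbds=1, chc2=want), seed=100 + i, record_id=f"p{i}"
            )
            hits, _, _ = scan_record(record)
            assert len(hits) == 1
            found += detect_chc2(hits[0])
        assert found == sum(flags)
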