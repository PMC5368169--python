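"""RING ligand location vs a brute-force oracle, subtype rules, curation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from florascreen import ring
from florascreen.ring import DEFAULT_SPACING
from florascreen.synthetic import MOTIF_RESIDUES, plant_ring_proteome


def oracle_locate(seq, spacing=DEFAULT_SPACING):
    """Exhaustive enumeration of all 8-tuples satisfying the spacing
    bounds; selection rule re-stated independently: smallest first
    position, then largest last position, then smallest tuple."""
    seq = seq.upper()
    candidates = [
        [i for i, ch in enumerate(seq) if ch in allowed]
        for allowed in spacing.allowed
    ]
    matches = []

    def extend(partial):
        k = len(partial)
        if k == 8:
            matches.append(tuple(partial))
            return
        lo, hi = spacing.gaps[k - 1]
        for q in candidates[k]:
            if partial[-1] + lo + 1 <= q <= partial[-1] + hi + 1:
                extend(partial + [q])

    for p1 in candidates[0]:
        extend([p1])
    if not matches:
        return None
    best = min(matches, key=lambda m: (m[0], -m[-1], m))
    return tuple(p + 1 for p in best)


def oracle_classify(residues):
    """Independent rule-table statement of the subtype decision."""
    rest = residues[:3] + residues[5:]
    pos4, pos5 = residues[3], residues[4]
    subst = {"D": "D", "S": "S/T", "T": "S/T", "G": "G"}
    if all(r == "C" for r in rest):
        pair = {("H", "C"): "HC", ("H", "H"): "H2",
                ("C", "H"): "v", ("C", "C"): "C2"}
        if (pos4, pos5) in pair:
            return pair[(pos4, pos5)]
        for r in (pos4, pos5):
            if r in subst:
                return subst[r]
        return "non-canonical"
    for r in residues:
        if r in subst:
            return subst[r]
    return "non-canonical"


def motif_sequence(gaps, residues, filler="A", lead=0, tail=0):
    seq = [filler] * lead
    for i, res in enumerate(residues):
        seq.append(res)
        if i < 7:
            seq.extend(filler * gaps[i])
    seq.extend(filler * tail)
    return "".join(seq)


class TestParseDomainTable:
    @staticmethod
    def write_tsv(path, rows):
        lines = []
        for r in rows:
            base = [r.get("id", "AT1G00010.1"), "md5", "300",
                    r.get("db", "Pfam"), r.get("acc", "PF13639"),
                    "RING finger", str(r.get("start", 10)),
                    str(r.get("end", 60)), "1e-12", "T", "01-01-2020"]
            lines.append("\t".join(base))
        path.write_text("\n".join(lines) + "\n")

    def test_three_rows_parsed(self, tmp_path):
        tsv = tmp_path / "d.tsv"
        self.write_tsv(tsv, [{"id": f"AT1G0000{i}.1"} for i in range(3)])
        anns = ring.parse_domain_table(tsv)
        assert len(anns) == 3
        assert all(a.in_scope for a in anns)

    def test_reversed_span_skipped(self, tmp_path):
        tsv = tmp_path / "d.tsv"
        self.write_tsv(tsv, [{"start": 60, "end": 10}, {"start": 5, "end": 9}])
        anns = ring.parse_domain_table(tsv)
        assert len(anns) == 1
        assert anns[0].start == 5

    def test_short_row_skipped(self, tmp_path):
        tsv = tmp_path / "d.tsv"
        tsv.write_text("AT1G1.1\tonly\tthree\n")
        assert ring.parse_domain_table(tsv) == []

    def test_out_of_scope_databases_flagged_not_dropped(self, tmp_path):
        tsv = tmp_path / "d.tsv"
        self.write_tsv(tsv, [{"db": "Pfam"}, {"db": "PANTHER"},
                             {"db": "SMART"}])
        anns = ring.parse_domain_table(tsv)
        assert len(anns) == 3
        assert [a.in_scope for a in anns] == [True, False, True]
        assert {a.signature_db for a in anns if a.in_scope} <= ring.SIGNATURE_DBS


class TestLocateLigands:
    def test_planted_c3hc4_recovered(self):
        gaps = [2, 12, 2, 2, 2, 10, 2]
        seq = motif_sequence(gaps, MOTIF_RESIDUES["HC"], lead=7, tail=9)
        pos = ring.locate_ring_ligands(seq)
        assert pos == oracle_locate(seq)
        assert [seq[p - 1] for p in pos] == list(MOTIF_RESIDUES["HC"])

    def test_all_alanine_has_no_match(self):
        assert ring.locate_ring_ligands("A" * 120) is None

    def test_leftmost_of_two_candidates_selected(self):
        gaps = [2, 10, 2, 2, 2, 8, 2]
        one = motif_sequence(gaps, MOTIF_RESIDUES["H2"])
        seq = one + "AAAA" + one
        pos = ring.locate_ring_ligands(seq)
        assert pos == oracle_locate(seq)
        assert pos[0] == 1  # starts in the first copy

    def test_span_restricts_search(self):
        gaps = [2, 10, 2, 2, 2, 8, 2]
        one = motif_sequence(gaps, MOTIF_RESIDUES["HC"])
        seq = "A" * 50 + one
        assert ring.locate_ring_ligands(seq, span=(1, 40)) is None
        pos = ring.locate_ring_ligands(seq, span=(45, len(seq)))
        assert pos is not None and pos[0] == 51

    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError):
            ring.locate_ring_ligands("ACDEF", span=(3, 99))

    def test_matches_oracle_on_random_sequences(self):
        # dense C/H sequences so matches and near-misses both occur
        rng = np.random.default_rng(17)
        alphabet = list("CHDSTAGLKV")
        for _ in range(120):
            n = int(rng.integers(40, 200))
            seq = "".join(rng.choice(alphabet, size=n))
            assert ring.locate_ring_ligands(seq) == oracle_locate(seq)


class TestClassify:
    @pytest.mark.parametrize("residues,expected", [
        (("C", "C", "C", "H", "C", "C", "C", "C"), "HC"),
        (("C", "C", "C", "H", "H", "C", "C", "C"), "H2"),
        (("C", "C", "C", "C", "H", "C", "C", "C"), "v"),
        (("C", "C", "C", "C", "C", "C", "C", "C"), "C2"),
        (("C", "C", "C", "D", "C", "C", "C", "C"), "D"),
        (("C", "C", "C", "S", "C", "C", "C", "C"), "S/T"),
        (("C", "C", "C", "T", "C", "C", "C", "C"), "S/T"),
    ])
    def test_canonical_subtypes(self, residues, expected):
        assert ring.classify_ring(residues) == expected

    def test_all_variable_pairs_match_rule_oracle(self):
        for pos4, pos5 in itertools.product("CHDST", repeat=2):
            residues = ("C", "C", "C", pos4, pos5, "C", "C", "C")
            assert ring.classify_ring(residues) == oracle_classify(residues)

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            ring.classify_ring(("C",) * 7)

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(st.tuples(*[st.sampled_from("CHDSTAGW") for _ in range(8)]))
    def test_total_function_on_any_residue_tuple(self, residues):
        label = ring.classify_ring(residues)
        assert label in {"HC", "H2", "v", "C2", "D", "S/T", "G",
                         "non-canonical"}
        assert label == oracle_classify(residues)

    def test_rule_table_is_editable(self, tmp_path):
        custom = tmp_path / "rules.yaml"
        custom.write_text(
            "pair_classes:\n  \"H,C\": MYCLASS\n"
            "substituent_classes: {}\nfallback: other\n")
        rules = ring.load_rule_table(custom)
        assert ring.classify_ring(
            ("C", "C", "C", "H", "C", "C", "C", "C"), rules) == "MYCLASS"


class TestScreenProteome:
    def test_planted_motifs_located_and_classified(self):
        proteins, anns, truth = plant_ring_proteome(n_proteins=24, seed=5)
        hits, signature_only = ring.screen_proteome(proteins, anns)
        planted = truth.details["planted"]
        assert {h.protein_id for h in hits} == {
            pid for pid, t in planted.items() if t is not None}
        for h in hits:
            t = planted[h.protein_id]
            assert list(h.ligand_positions) == t["positions"]
            assert h.ring_class == t["class"]
        assert signature_only == []

    def test_residues_match_sequence_at_positions(self):
        proteins, anns, _ = plant_ring_proteome(n_proteins=8, seed=6)
        hits, _ = ring.screen_proteome(proteins, anns)
        for h in hits:
            seq = proteins[h.protein_id]
            assert all(seq[p - 1] == r for p, r in
                       zip(h.ligand_positions, h.ligand_residues))
            assert all(h.span[0] <= p <= h.span[1]
                       for p in h.ligand_positions)


class TestReconcile:
    def test_identity(self):
        rep = ring.reconcile({"AT1G1", "AT2G2"}, {"AT1G1", "AT2G2"})
        assert rep.matched == {"AT1G1", "AT2G2"}
        assert not rep.dropped and not rep.newly_identified

    def test_isoform_suffix_collapsed(self):
        rep = ring.reconcile({"AT1G1.1", "AT1G1.2"}, {"AT1G1"})
        assert rep.matched == {"AT1G1"}

    def test_census_partition_with_full_evidence(self):
        # 457 matched, 50 new, 31 dropped with the published reason split
        reasons = (["merged"] * 6 + ["no-RING-domain"] * 10
                   + ["absent-from-db"] * 3 + ["pseudogene"] * 3
                   + ["split-new-locus"] * 7 + ["transposable-element"] * 2)
        matched = {f"AT1G{i:05d}" for i in range(457)}
        dropped = {f"AT2G{i:05d}" for i in range(31)}
        new = {f"AT3G{i:05d}" for i in range(50)}
        evidence = dict(zip(sorted(dropped), reasons))
        rep = ring.reconcile(matched | new, matched | dropped, evidence)
        counts = rep.counts
        assert counts["matched"] == 457
        assert counts["newly_identified"] == 50
        assert counts["dropped"] == 31
        assert counts["merged"] == 6
        assert counts["no-RING-domain"] == 10
        assert counts["split-new-locus"] == 7
        # invariant: matched + dropped partition the old set
        assert len(rep.matched) + counts["dropped"] == 457 + 31

    def test_unmatched_without_evidence_is_unresolved(self):
        rep = ring.reconcile({"AT1G1"}, {"AT1G1", "AT9G9"})
        assert rep.unresolved == {"AT9G9"}
        assert rep.counts["dropped"] == 1

    def test_unknown_reason_rejected(self):
        with pytest.raises(ValueError, match="unknown drop reason"):
            ring.reconcile(set(), {"AT1G1"}, {"AT1G1": "vanished"})

    def test_disjoint_sets_with_evidence(self):
        rep = ring.reconcile({"B1"}, {"A1"}, {"A1": "merged"})
        assert rep.newly_identified == {"B1"}
        assert rep.dropped == {"A1": "merged"}
        assert not rep.matched
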