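import pytest

from ehmine import synthetic_data as sd
from ehmine.sequence_io import GeneDatabase, GeneProduct
from ehmine.mining import CandidateEH, textmine, scan_database, merge_candidates
from ehmine.classification import (Reference, ReferenceSet, find_hgxp,
                                   find_dehalogenase_motif, assign_triad_abEH,
                                   assign_triad_LEH, detect_nterm_domain,
                                   classify_family, annotate_leh_selectivity,
                                   annotate_candidate_selectivity,
                                   classify_candidates)


def mutate(seq: str, pos: int, res: str) -> str:
    """Replace the residue at a 1-based position."""
    return seq[:pos - 1] + res + seq[pos:]


class TestHGXP:
    @pytest.mark.parametrize("seq,pos,x,x_class", [
        ("AHGWPA", 2, "W", "aromatic"),
        ("AHGFPA", 2, "F", "aromatic"),
        ("AHGNPA", 2, "N", "hydrophilic"),
        ("AHGVPA", 2, "V", "aliphatic"),
        ("AHGKPA", 2, "K", "other"),
    ])
    def test_x_residue_classification(self, seq, pos, x, x_class):
        (hit,) = find_hgxp(seq)
        assert (hit.position, hit.matched[2], hit.x_class) == (pos, x, x_class)

    def test_no_motif_no_hits(self):
        assert find_hgxp("AAAA") == []

    def test_every_occurrence_reported(self):
        assert [h.position for h in find_hgxp("HGWPAHGNP")] == [1, 6]


class TestDehalogenaseMotif:
    @pytest.mark.parametrize("seq,expected", [
        ("DRAARAAAR", (True, False)),
        ("DWAAAAAAA", (False, True)),
        ("DRAARAAAK", (False, False)),
    ])
    def test_motif_and_post_asp_rules(self, seq, expected):
        assert find_dehalogenase_motif(seq, 1) == expected

    def test_window_past_sequence_end_is_not_a_match(self):
        assert find_dehalogenase_motif("ADRAAR", 2)[0] is False

    def test_non_aspartate_anchor_is_an_error(self):
        with pytest.raises(ValueError):
            find_dehalogenase_motif("ARAARAAAR", 1)


class TestAbEHTriad:
    def test_reference_recovers_itself(self, refs):
        ref = refs.get("refG8a")
        triad = assign_triad_abEH(ref.sequence, refs)
        assert triad.complete and triad.best_reference == "refG8a"
        assert triad.roles["nucleophile"] == (ref.positions["nucleophile"], "D")
        assert triad.roles["base"] == (ref.positions["base"], "H")
        assert triad.roles["tyrosine"] == (ref.positions["tyrosine"], "Y")

    def test_nucleophile_ablation_breaks_completeness(self, refs):
        ref = refs.get("refG8a")
        seq = mutate(ref.sequence, ref.positions["nucleophile"], "A")
        triad = assign_triad_abEH(seq, refs)
        assert not triad.complete
        assert triad.roles["nucleophile"][1] != "D"

    def test_planted_positions_recovered_from_manifest(self, refs):
        seq, entry = sd.make_scaffold("abEH_core", 314)
        triad = assign_triad_abEH(seq, refs)
        assert triad.complete
        for role in ("nucleophile", "base", "tyrosine"):
            assert triad.roles[role][0] == entry["positions"][role]

    def test_acid_variant_b_is_accepted(self, refs):
        for seed in range(30):
            seq, entry = sd.make_scaffold("abEH_core", seed)
            if entry["acid_variant"] == "B":
                break
        triad = assign_triad_abEH(seq, refs)
        assert triad.complete and triad.acid_variant == "B"

    def test_no_abeh_references_is_an_error(self, refs):
        leh_only = ReferenceSet(refs.by_family("LEH"))
        with pytest.raises(ValueError):
            assign_triad_abEH("MKTAY" * 20, leh_only)


class TestLEHTriad:
    def test_reference_recovers_itself(self, refs):
        ref = refs.get("refLEHa1")
        triad = assign_triad_LEH(ref.sequence, refs)
        assert triad.complete
        assert triad.roles["asp1"] == (ref.positions["asp1"], "D")
        assert triad.roles["arg"] == (ref.positions["arg"], "R")
        assert triad.roles["asp2"] == (ref.positions["asp2"], "D")

    def test_arginine_to_lysine_breaks_completeness(self, refs):
        ref = refs.get("refLEHa1")
        seq = mutate(ref.sequence, ref.positions["arg"], "K")
        assert not assign_triad_LEH(seq, refs).complete

    def test_mutated_scaffold_with_protected_triad_stays_complete(self, refs):
        spec = sd.ProteomeSpec(counts={"LEH": 5, "background": 0},
                               mutation_rate=0.05, seed=8)
        db, manifest = sd.make_proteome(spec)
        for gid in sd.planted_ids(manifest, "LEH"):
            assert assign_triad_LEH(db[gid].sequence, refs).complete

    def test_water_positioning_residues_reported_not_required(self, refs):
        ref = refs.get("refLEHa1")
        seq = mutate(ref.sequence, ref.positions["water1"], "A")
        triad = assign_triad_LEH(seq, refs)
        assert triad.complete and triad.roles["water1"][1] == "A"


class TestNtermDomain:
    def test_planted_nterm_product_detected(self, refs, profiles):
        seq, _ = sd.make_scaffold("abEH_Nterm", 99)
        assert detect_nterm_domain(seq, profiles["EH-N"], refs.core_length_median())

    def test_core_product_not_detected(self, refs, profiles):
        seq, _ = sd.make_scaffold("abEH_core", 99)
        assert not detect_nterm_domain(seq, profiles["EH-N"], refs.core_length_median())

    def test_long_sequence_without_domain_hit_not_detected(self, refs, profiles):
        import numpy as np
        rng = np.random.default_rng(3)
        seq = "".join(sd.AA20[i] for i in rng.integers(0, 20, size=460))
        assert not detect_nterm_domain(seq, profiles["EH-N"], refs.core_length_median())


class TestClassifyFamily:
    def _triad(self, complete, nucleophile="D"):
        from ehmine.classification import TriadAssignment
        return TriadAssignment(family="abEH",
                               roles={"nucleophile": (10, nucleophile),
                                      "base": (50, "H"), "tyrosine": (30, "Y")},
                               complete=complete, best_reference="r", identity=80.0)

    def test_decision_tree_order(self):
        from ehmine.classification import TriadAssignment
        leh_ok = TriadAssignment("LEH", {"asp1": (1, "D"), "arg": (2, "R"),
                                         "asp2": (3, "D")}, True, "r", 90.0)
        assert classify_family(leh_ok, self._triad(True), False, False) == "LEH"
        assert classify_family(None, self._triad(True, "A"), False, False) == "rejected"
        assert classify_family(None, self._triad(True), True, False) == "dehalogenase_like"
        assert classify_family(None, self._triad(True), False, True) == "abEH_Nterm"
        assert classify_family(None, self._triad(True), False, False) == "abEH_core"
        assert classify_family(None, self._triad(False), False, False) == "rejected"
        assert classify_family(None, None, False, False) == "rejected"

    def test_no_label_is_both_leh_and_dehalogenase(self):
        # first-match semantics make the labels mutually exclusive
        leh_ok = self._triad(True)
        leh_ok.family = "LEH"
        assert classify_family(leh_ok, self._triad(True), True, False) == "LEH"


@pytest.fixture(scope="module")
def classified(small_proteome, refs, profiles):
    db, manifest = small_proteome
    cands = merge_candidates(textmine(db),
                             scan_database(db, list(profiles.values())), db)
    classify_candidates(cands, db, refs, profiles["EH-N"])
    return db, manifest, cands


@pytest.fixture(scope="module")
def wild_type_leh():
    return sd.make_scaffold("LEH", 4242)[0]


class TestEndToEndClassification:
    def test_noiseless_precision_and_recall_are_perfect(self, classified):
        db, manifest, cands = classified
        truth = {g: e["class"] for g, e in manifest["products"].items()}
        pred = {c.id: c.family for c in cands}
        for fam in ("LEH", "abEH_Nterm", "abEH_core", "dehalogenase_like"):
            planted = {g for g, t in truth.items() if t == fam}
            called = {g for g, p in pred.items() if p == fam}
            assert called == planted

    def test_ablating_nucleophile_flips_to_rejected(self, classified, refs, profiles):
        db, manifest, cands = classified
        gid = sorted(sd.planted_ids(manifest, "abEH_core"))[0]
        entry = manifest["products"][gid]
        seq = mutate(db[gid].sequence, entry["positions"]["nucleophile"], "A")
        db2 = GeneDatabase(products=[GeneProduct(gid, seq, "epoxide hydrolase")])
        cand = CandidateEH(id=gid, annotation_hit=True)
        classify_candidates([cand], db2, refs, profiles["EH-N"])
        assert cand.family == "rejected"

    def test_dehalogenase_decoys_never_label_as_leh(self, classified):
        db, manifest, cands = classified
        decoys = sd.planted_ids(manifest, "dehalogenase_like")
        for c in cands:
            if c.id in decoys:
                assert c.family == "dehalogenase_like"


class TestSelectivity:
    def test_wild_type_ili_raises_no_flags(self, refs, wild_type_leh):
        report = annotate_leh_selectivity(wild_type_leh, refs.releh_reference())
        assert report.residues == {80: "I", 114: "L", 116: "I"}
        assert not report.rr_leaning and not report.ss_leaning

    @pytest.mark.parametrize("pos,res,flag", [
        (80, "V", "rr_leaning"), (114, "F", "rr_leaning"),
        (80, "Y", "ss_leaning"), (116, "V", "ss_leaning"),
    ])
    def test_engineered_variants_flag_their_selectivity(self, refs, wild_type_leh,
                                                        pos, res, flag):
        report = annotate_leh_selectivity(mutate(wild_type_leh, pos, res),
                                          refs.releh_reference())
        assert getattr(report, flag)

    def test_non_leh_candidate_is_an_error(self, refs):
        cand = CandidateEH(id="x", family="abEH_core")
        with pytest.raises(ValueError):
            annotate_candidate_selectivity(cand, "MKTAY" * 30, refs)


class TestReferenceSet:
    def test_annotated_residue_mismatch_is_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            Reference(id="bad", family="LEH", group="g", sequence="MKTAY",
                      positions={"asp1": 1, "arg": 2, "asp2": 3})

    def test_position_outside_sequence_is_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            Reference(id="bad", family="LEH", group="g", sequence="DRD",
                      positions={"asp1": 1, "arg": 2, "asp2": 9})

    def test_default_set_carries_both_families_and_groups(self, refs):
        assert {r.family for r in refs} == {"abEH", "LEH", "dehalogenase"}
        assert {"group5", "group8", "group6", "lehA", "lehB"} <= refs.groups()
        assert refs.releh_reference().positions["sel_80"] == 80
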