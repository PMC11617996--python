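"""Cross-linker chemistry, decoy calibration, site mapping and consensus."""

import itertools
import math

import numpy as np
import pytest

from hdlstruct import crosslinks as X
from hdlstruct.proteins import WATER_MONO, APOA1_HELIX_REPEATS


class TestSpeciesMass:
    @pytest.mark.parametrize(
        "linker, charge, printed",
        [
            ("BS3-H12", 3, 3220.7),
            ("BS3-D12", 3, 3232.8),
            ("DSBU", 4, 3279.73),
            ("DSSO", 4, 3241.67),
        ],
    )
    def test_published_species_masses(self, linker, charge, printed):
        """The K59-K30 link (LLDNWDSVTSTFSKLR x VKSPELQAEAK) reproduces the
        published protonated-species masses."""
        mass = X.crosslinked_species_mass(
            "LLDNWDSVTSTFSKLR", "VKSPELQAEAK", linker, charge)
        assert mass == pytest.approx(printed, abs=0.05)

    def test_symmetric_and_additive(self):
        a, b = "PEPTIDEK", "SAMPLER"
        m1 = X.crosslinked_species_mass(a, b, "DSBU", 0)
        m2 = X.crosslinked_species_mass(b, a, "DSBU", 0)
        assert m1 == m2
        from hdlstruct.proteins import peptide_mass
        assert m1 == pytest.approx(
            peptide_mass(a) + peptide_mass(b) + X.get_linker("DSBU").crosslink_delta)

    def test_charge_adds_protons(self):
        m0 = X.crosslinked_species_mass("AK", "AR", "BS3-H12", 0)
        m3 = X.crosslinked_species_mass("AK", "AR", "BS3-H12", 3)
        assert m3 - m0 == pytest.approx(3 * 1.0072765)
        with pytest.raises(ValueError):
            X.crosslinked_species_mass("AK", "AR", "BS3-H12", -1)


class TestLinkerRegistry:
    def test_monolink_deltas(self):
        assert X.monolink_mass_delta("BS3-H12") == pytest.approx(156.0786,
                                                                 abs=5e-4)
        # chemistry value; the heavy form adds exactly 12 deuteriums
        assert X.monolink_mass_delta("BS3-D12") == pytest.approx(168.1540,
                                                                 abs=2e-3)
        assert X.monolink_mass_delta("DSBU") == pytest.approx(214.0954,
                                                              abs=5e-4)

    def test_unknown_linker(self):
        with pytest.raises(KeyError, match="BS3-H12"):
            X.monolink_mass_delta("BS9")

    def test_hydrolysis_consistency(self):
        for spec in X.LINKERS.values():
            assert spec.monolink_delta - spec.crosslink_delta == pytest.approx(
                WATER_MONO, abs=1e-9)

    def test_heavy_light_delta_is_12_deuteriums(self):
        delta = (X.get_linker("BS3-D12").crosslink_delta
                 - X.get_linker("BS3-H12").crosslink_delta)
        assert delta == pytest.approx(12 * 1.006277, abs=1e-9)
        assert delta == pytest.approx(12.07533, abs=1e-4)


class TestIsotopeDoublet:
    def test_published_pair_validates(self):
        assert X.validate_isotope_doublet(3220.709, 3232.784)

    def test_off_pairs_rejected(self):
        assert not X.validate_isotope_doublet(3220.7, 3232.7)
        assert not X.validate_isotope_doublet(1000.0, 1000.0)
        with pytest.raises(ValueError):
            X.validate_isotope_doublet(-1.0, 5.0)


def candidate(score, protein_a="APOA1", protein_b="APOA2"):
    return X.CrosslinkCandidate(
        peptide_a="AKPALEDLR", site_offset_a=2, protein_a=protein_a,
        peptide_b="VKSPELQAEAK", site_offset_b=2, protein_b=protein_b,
        score=score)


class TestCalibrateThreshold:
    def test_spec_example(self):
        cands = [candidate(2.9, protein_a="DUMMY1"),
                 candidate(2.5, protein_b="DUMMY2"),
                 candidate(3.2), candidate(3.5)]
        threshold, accepted = X.calibrate_threshold(cands, {"DUMMY1", "DUMMY2"})
        assert threshold == 3.2
        assert len(accepted) == 2

    def test_no_decoys_accepts_everything(self):
        cands = [candidate(s) for s in (1.0, 2.0, 3.0)]
        threshold, accepted = X.calibrate_threshold(cands, {"DUMMY1"})
        assert threshold == 1.0
        assert len(accepted) == 3

    def test_all_decoys_accepts_nothing(self):
        cands = [candidate(s, protein_a="DUMMY1") for s in (1.0, 2.0)]
        with pytest.warns(UserWarning, match="decoy budget"):
            threshold, accepted = X.calibrate_threshold(cands, {"DUMMY1"})
        assert math.isinf(threshold)
        assert accepted == []

    def test_minimality_against_brute_force(self):
        """Any threshold strictly below the calibrated one admits more
        decoys than the budget (random candidate sets, several budgets)."""
        rng = np.random.default_rng(17)
        for trial in range(50):
            n = int(rng.integers(3, 40))
            cands = [
                candidate(float(np.round(rng.uniform(0, 5), 2)),
                          protein_a="DUMMY1" if rng.random() < 0.4 else "APOA1")
                for _ in range(n)
            ]
            budget = int(rng.integers(0, 3))
            import warnings as _warnings
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", UserWarning)
                threshold, accepted = X.calibrate_threshold(cands, {"DUMMY1"},
                                                            budget)
            scores = sorted({c.score for c in cands})

            def decoys_at(t):
                return sum(1 for c in cands
                           if c.score >= t and c.involves({"DUMMY1"}))

            if math.isinf(threshold):
                assert all(decoys_at(t) > budget for t in scores)
                continue
            assert decoys_at(threshold) <= budget
            for t in scores:
                if t < threshold:
                    assert decoys_at(t) > budget
            assert all(c.score >= threshold and not c.involves({"DUMMY1"})
                       for c in accepted)


class TestResiduePairs:
    def test_mapping_via_locate_and_map(self, registry):
        cand = X.CrosslinkCandidate(
            peptide_a="LEALKENGGAR", site_offset_a=5, protein_a="APOA1",
            peptide_b="VKSPELQAEAK", site_offset_b=2, protein_b="APOA2")
        pair = X.to_residue_pair(cand, registry)
        assert (pair.protein_a, pair.residue_a) == ("APOA1", 182)
        assert (pair.protein_b, pair.residue_b) == ("APOA2", 30)

    def test_ambiguous_offsets_expand(self, registry):
        cand = X.CrosslinkCandidate(
            peptide_a="AKPALEDLR", site_offset_a=2, protein_a="APOA1",
            peptide_b="VKSPELQAEAK", site_offset_b=2, protein_b="APOA2",
            alt_offsets_b=(3, 11))
        pair = X.to_residue_pair(cand, registry)
        assert pair.residue_b == 30 and pair.alternatives_b == (31, 39)
        assert len(pair.expand()) == 3

    def test_unknown_protein_errors(self, registry):
        cand = candidate(1.0, protein_a="NOT_A_PROTEIN")
        with pytest.raises(KeyError, match="NOT_A_PROTEIN"):
            X.to_residue_pair(cand, registry)

    def test_canonical_ordering(self):
        pair = X.make_pair("APOA2", 30, "APOA1", 59)
        assert (pair.protein_a, pair.residue_a) == ("APOA1", 59)


def brute_force_consensus(pair_sets, min_evidence, tol):
    """Oracle: explicit double loop over all concrete pair combinations,
    then connected-component merging of within-tolerance survivors."""
    concrete = [(eid, cp) for eid, pairs in pair_sets
                for p in pairs for cp in p.expand()]

    def match(p, q):
        return (p.protein_a == q.protein_a and p.protein_b == q.protein_b
                and abs(p.residue_a - q.residue_a) <= tol
                and abs(p.residue_b - q.residue_b) <= tol)

    survivors = []
    for _, cp in concrete:
        ids = {eid for eid, other in concrete if match(cp, other)}
        if len(ids) >= min_evidence:
            survivors.append(cp)
    key = lambda p: (p.protein_a, p.residue_a, p.protein_b, p.residue_b)
    survivors = sorted(set(survivors), key=key)
    # connected components by breadth-first search over match edges
    unvisited = list(survivors)
    reps = set()
    while unvisited:
        queue = [unvisited.pop(0)]
        component = []
        while queue:
            p = queue.pop()
            component.append(p)
            linked = [q for q in unvisited if match(p, q)]
            for q in linked:
                unvisited.remove(q)
            queue.extend(linked)
        reps.add(key(min(component, key=key)))
    return reps


@pytest.fixture(scope="module")
def table_sets():
    t1 = X.table_residue_pairs(X.load_published_bs3_table())
    t2 = X.table_residue_pairs(X.load_published_cleavable_table())
    return [("bs3", t1), ("cleavable", t2)]


class TestConsensus:
    def test_published_tables_strict_intersection(self, table_sets):
        entries = X.consensus(table_sets, min_evidence=2, site_tolerance=0)
        got = {(e.pair.residue_a, e.pair.residue_b) for e in entries}
        assert got == {(59, 30), (182, 46), (208, 30), (208, 39)}
        for e in entries:
            assert set(e.evidence_ids) == {"bs3", "cleavable"}

    def test_published_tables_one_residue_tolerance(self, table_sets):
        entries = X.consensus(table_sets, min_evidence=2, site_tolerance=1)
        got = {(e.pair.residue_a, e.pair.residue_b) for e in entries}
        assert got == {(59, 30), (182, 39), (182, 46), (208, 30), (208, 39)}

    def test_single_evidence_set_gives_nothing(self, table_sets):
        assert X.consensus(table_sets[:1], min_evidence=2) == []

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(23)
        for trial in range(30):
            n_sets = int(rng.integers(1, 4))
            pair_sets = []
            for i in range(n_sets):
                pairs = [
                    X.make_pair("A", int(rng.integers(1, 40)),
                                "B", int(rng.integers(1, 40)))
                    for _ in range(int(rng.integers(0, 30)))
                ]
                pair_sets.append((f"e{i}", pairs))
            for tol, min_ev in [(0, 2), (1, 2), (2, 1)]:
                got = {
                    (e.pair.protein_a, e.pair.residue_a,
                     e.pair.protein_b, e.pair.residue_b)
                    for e in X.consensus(pair_sets, min_ev, tol)
                }
                assert got == brute_force_consensus(pair_sets, min_ev, tol)


class TestAnnotation:
    def test_helix_labels_on_pairs(self):
        anns = {"APOA1": APOA1_HELIX_REPEATS}
        pairs = [X.make_pair("APOA1", 59, "APOA2", 30),
                 X.make_pair("APOA1", 182, "APOA2", 39),
                 X.make_pair("APOA1", 226, "APOA2", 30)]
        labelled = X.annotate_pairs(pairs, anns)
        assert [(a, b) for _, a, b in labelled] == [
            ("H1", "unassigned"), ("H7", "unassigned"), ("H10", "unassigned")]


class TestTableTranscriptions:
    def test_expanded_link_counts(self):
        assert X.count_expanded_links(X.load_published_bs3_table()) == 8
        assert X.count_expanded_links(X.load_published_cleavable_table()) == 9

    def test_candidate_csv_round_trip(self, tmp_path):
        cands = [X.CrosslinkCandidate(
            peptide_a="AKPALEDLR", site_offset_a=2, protein_a="APOA1",
            peptide_b="VKSPELQAEAK", site_offset_b=2, protein_b="APOA2",
            engine="sim-xl", experiment_id="e1", score=3.5,
            observed_species_mass=3162.7, charge=3, alt_offsets_b=(3, 11))]
        path = tmp_path / "cands.csv"
        X.write_candidates(cands, path)
        back = X.read_candidates(path)
        assert back == cands

    def test_plink_scores_invert(self):
        assert X.adapt_score("plink", 1e-3) > X.adapt_score("plink", 1e-1)
        with pytest.raises(KeyError, match="plink"):
            X.adapt_score("mystery-engine", 1.0)
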