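"""Common-family filtering, anchor selection, window search and conserved
module detection."""

import numpy as np
import pytest

import crmscan as c
import oracles


def hit(start, family, width=10, matrix=None, strand="+", msim=0.9, csim=1.0):
    return c.TFBSHit(
        start=start,
        matrix=matrix or f"{family}_1",
        strand=strand,
        family=family,
        width=width,
        position_rel_tss=start - 4500,
        core_similarity=csim,
        matrix_similarity=msim,
    )


class TestCommonFamilies:
    def test_intersection_semantics(self):
        hits = {f"sp{i}": [hit(100, "NEUR"), hit(300, "HNF1")] for i in range(7)}
        hits["sp7"] = [hit(100, "NEUR")]  # HNF1 missing in one of 8 species
        assert c.common_families(hits) == {"NEUR"}

    def test_shared_families_returned(self):
        hits = {
            "a": [hit(1, "NEUR"), hit(30, "HNF1"), hit(60, "DEC1")],
            "b": [hit(5, "HNF1"), hit(90, "NEUR")],
        }
        assert c.common_families(hits) == {"NEUR", "HNF1"}

    def test_empty_species_gives_empty_result(self):
        assert c.common_families({"a": [hit(1, "NEUR")], "b": []}) == set()

    def test_single_species_warns(self):
        with pytest.warns(UserWarning):
            c.common_families({"a": [hit(1, "NEUR")]})

    def test_planted_sets_recover_exactly_true_families(
        self, library, thresholds
    ):
        for seed in (1, 5, 9):
            regs, truth = c.simulate_ortholog_promoters(library, c.PlantSpec(seed=seed))
            hits = {
                r.species: c.scan_sequence(library, r.sequence, thresholds=thresholds)
                for r in regs
            }
            assert c.common_families(hits) >= set(c.TRUE_FAMILY_NAMES)
            # decoys are forced non-universal, so none can be common
            decoys = set(library.families) - set(c.TRUE_FAMILY_NAMES)
            planted_decoys = {
                s.family for s in truth.sites if s.family in decoys
            }
            for fam in planted_decoys:
                present_in = {
                    sp for sp, hh in hits.items()
                    if any(h.family == fam for h in hh)
                }
                if fam in c.common_families(hits):
                    # only possible via chance background hits in every species
                    assert present_in == set(hits)


class TestSelectAnchors:
    def test_single_hit_returned(self):
        h = hit(100, "NEUR")
        assert c.select_anchors([h, hit(40, "HNF1")]) == [h]

    def test_ranked_by_matrix_similarity(self):
        lo, hi = hit(10, "NEUR", msim=0.88), hit(900, "NEUR", msim=0.93)
        assert c.select_anchors([lo, hi])[0] is hi

    def test_tss_proximity_breaks_exact_ties(self):
        far = hit(1500, "NEUR")  # rel TSS -3000
        near = hit(3300, "NEUR")  # rel TSS -1200
        assert c.select_anchors([far, near])[0] is near

    def test_no_anchor_family_gives_empty(self):
        assert c.select_anchors([hit(3, "HNF1")]) == []

    def test_ties_at_cut_are_kept(self):
        same = [hit(1000 + i, "NEUR", msim=0.9) for i in range(4)]
        # identical (msim, csim) but different |rel TSS| -> strict top_k
        assert len(c.select_anchors(same, top_k=3)) == 3
        equal = [
            hit(4500 - 100, "NEUR", msim=0.9),
            hit(4500 + 100, "NEUR", msim=0.9, strand="-"),
        ]
        out = c.select_anchors(equal + [hit(4500 - 2000, "NEUR", msim=0.95)], top_k=2)
        assert len(out) == 3  # both |100| ties kept at the cut


class TestFindModuleWindow:
    def test_all_families_within_span(self):
        anchor = hit(1000, "NEUR")
        hits = [anchor] + [
            hit(1000 + 120 * (i + 1), fam)
            for i, fam in enumerate(["HNF1", "HNF6", "BRNF", "PDX1", "LEFF"])
        ]
        w = c.find_module_window(hits, anchor, set(c.TRUE_FAMILY_NAMES), max_span=1000)
        assert w.families == set(c.TRUE_FAMILY_NAMES)
        assert w.span <= 700

    def test_distant_family_excluded(self):
        anchor = hit(1000, "NEUR")
        near = hit(1200, "HNF1")
        far = hit(2800, "HNF6")  # 1500+ away from everything else
        w = c.find_module_window([anchor, near, far], anchor,
                                 {"NEUR", "HNF1", "HNF6"}, max_span=1000)
        assert w.families == {"NEUR", "HNF1"}

    def test_degenerate_anchor_only(self):
        anchor = hit(2000, "NEUR")
        w = c.find_module_window([anchor], anchor, {"NEUR"})
        assert (w.start, w.end) == (anchor.start, anchor.end)
        assert w.families == {"NEUR"}

    def test_anchor_must_be_in_hits(self):
        with pytest.raises(ValueError):
            c.find_module_window([hit(1, "HNF1")], hit(5, "NEUR"), {"NEUR"})

    def test_agrees_with_hit_bounded_enumeration_oracle(self):
        rng = np.random.default_rng(23)
        fams = ["NEUR", "HNF1", "HNF6", "BRNF"]
        for _ in range(25):
            hits = [
                hit(int(rng.integers(0, 4000)), fams[int(rng.integers(len(fams)))],
                    width=int(rng.integers(8, 15)))
                for _ in range(int(rng.integers(5, 20)))
            ]
            anchors = [h for h in hits if h.family == "NEUR"]
            if not anchors:
                continue
            anchor = anchors[0]
            got = c.find_module_window(hits, anchor, set(fams), max_span=1000)
            tup = [(h.start, h.end, h.family, i) for i, h in enumerate(hits)]
            anchor_ids = {i for i, h in enumerate(hits)
                          if (h.start, h.matrix, h.strand)
                          == (anchor.start, anchor.matrix, anchor.strand)}
            want = oracles.exhaustive_best_window(tup, anchor_ids, set(fams), 1000)
            assert (got is None) == (want is None)
            if got is not None:
                assert got.families == set(want[0])
                assert got.span == want[1]
                assert got.start == want[2]


class TestDetectConservedModule:
    def test_planted_module_recovered_exactly(self, planted_set):
        regs, truth, hits = planted_set
        module = c.detect_conserved_module(hits)
        assert module is not None
        assert set(module.families) == set(c.TRUE_FAMILY_NAMES)
        assert set(module.windows) == {r.species for r in regs}
        for sp, w in module.windows.items():
            assert w.span <= 1000
            ws, we = truth.windows[sp]
            assert w.start < we and ws < w.end  # window overlaps the plant

    def test_family_set_subset_of_common_and_contains_anchor(self, planted_set):
        _, _, hits = planted_set
        module = c.detect_conserved_module(hits)
        assert set(module.families) <= c.common_families(hits)
        assert "NEUR" in module.families

    def test_no_anchor_control_yields_none(self, library, thresholds):
        regs, _ = c.simulate_control_promoters(library, c.PlantSpec(seed=31), "no_anchor")
        hits = {
            r.species: c.scan_sequence(library, r.sequence, thresholds=thresholds)
            for r in regs
        }
        assert c.detect_conserved_module(hits) is None

    def test_scattered_control_yields_none_or_partial(self, library, thresholds):
        regs, _ = c.simulate_control_promoters(library, c.PlantSpec(seed=32), "scattered")
        hits = {
            r.species: c.scan_sequence(library, r.sequence, thresholds=thresholds)
            for r in regs
        }
        module = c.detect_conserved_module(hits)
        assert module is None or len(module.families) < 6

    def test_shrinking_span_never_enlarges_family_set(self, planted_set):
        _, _, hits = planted_set
        prev = None
        for span in (1000, 700, 400, 200):
            module = c.detect_conserved_module(hits, max_span=span)
            fams = set(module.families) if module else set()
            if prev is not None:
                assert fams <= prev or len(fams) <= len(prev)
            prev = fams

    def test_agrees_with_exhaustive_subset_enumeration(self):
        rng = np.random.default_rng(41)
        fams = ["NEUR", "HNF1", "HNF6", "BRNF", "PDX1"]
        for trial in range(15):
            hits_by_species = {}
            for sp in ("a", "b", "c"):
                hits_by_species[sp] = [
                    hit(int(rng.integers(0, 4500)), fams[int(rng.integers(len(fams)))],
                        width=10)
                    for _ in range(int(rng.integers(4, 25)))
                ]
            got = c.detect_conserved_module(
                hits_by_species, max_span=800, min_families=1, top_k_anchors=1000
            )
            tup = {
                sp: [(h.start, h.end, h.family) for h in hh]
                for sp, hh in hits_by_species.items()
            }
            want = oracles.exhaustive_module_families(tup, "NEUR", 800)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert set(got.families) == set(want)

    def test_min_families_threshold(self):
        hits = {
            "a": [hit(100, "NEUR")],
            "b": [hit(200, "NEUR")],
        }
        assert c.detect_conserved_module(hits, min_families=2) is None
        single = c.detect_conserved_module(hits, min_families=1)
        assert single is not None and single.families == ("NEUR",)


class TestCompareParalogs:
    def _module(self, species):
        windows = {
            sp: c.ModuleWindow(
                species=sp, start=1000, end=1600,
                anchor=hit(1000, "NEUR"), members=[hit(1000, "NEUR"), hit(1400, "HNF1")],
            )
            for sp in species
        }
        return c.RegulatoryModule(
            gene_id="g", families=("HNF1", "NEUR"), anchor_family="NEUR",
            windows=windows,
        )

    def test_presence_absence_rows(self):
        species = ["sp01", "sp02"]
        table = c.compare_paralogs(species, self._module(species), None)
        assert list(table.index) == species
        assert table["a"].all() and not table["b"].any()

    def test_both_present_and_both_absent(self):
        species = ["sp01"]
        both = c.compare_paralogs(species, self._module(species), self._module(species))
        assert both.loc["sp01"].tolist() == [True, True]
        neither = c.compare_paralogs(species, None, None)
        assert neither.loc["sp01"].tolist() == [False, False]

    def test_species_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            c.compare_paralogs(["spX"], self._module(["sp01"]), None)
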