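"""Five-level classification: name-set categories, pair/unit rules, profiles."""

from __future__ import annotations

import random

import pytest

from herblink.io import Collection
from herblink.normalize import MatchParams
from herblink.similarity import (
    NameCache,
    Thresholds,
    classify_pair,
    classify_unit,
    compare_collections,
    name_set_similarity,
)
from herblink.synthetic import SyntheticConfig, generate_pair
from conftest import make_collection


# ---------------------------------------------------------------------------
# Independent brute-force oracle: a flat re-derivation of the rules used to
# cross-check the incremental best-tracking in classify_unit.
# ---------------------------------------------------------------------------


def oracle_unit(members, target, thresholds, cache):
    verdicts = []  # (specimen_no, level, branch, coverage)
    name_holders, species_holders = set(), set()
    for q in members:
        q_bin = cache.binomial(q.determination)
        for cand in target:
            sim = name_set_similarity(cache.names(q), cache.names(cand),
                                      thresholds)
            species = bool(q_bin) and cache.binomial(cand.determination) == q_bin
            shared = sim.category in ("exact", "largely", "partly")
            if shared:
                name_holders.add(cand.specimen_no)
            if species:
                species_holders.add(cand.specimen_no)
            if species and sim.category == "exact":
                lv, br = 100, "A"
            elif species and sim.category == "largely":
                lv, br = 75, "B"
            elif species and sim.category == "partly":
                lv, br = 50, "C"
            elif shared:
                lv, br = 25, "D1"
            elif species:
                lv, br = 25, "D2"
            else:
                lv, br = 0, "E"
            verdicts.append((lv, sim.query_coverage, -cand.specimen_no, br))
    lv, cov, negno, br = max(verdicts)
    counterpart = -negno
    if lv < 50 and name_holders and species_holders and \
            len(name_holders | species_holders) > 1:
        return 25, "D3", None
    if br == "E":
        counterpart = None
    return lv, br, counterpart


# ---------------------------------------------------------------------------
# name_set_similarity
# ---------------------------------------------------------------------------


class TestNameSetSimilarity:
    def test_barbarea_largely(self, barbarea_names):
        q, c = barbarea_names
        sim = name_set_similarity(q, c)
        assert sim.category == "largely"
        assert sim.query_coverage == pytest.approx(3 / 4)
        assert sim.exact_coverage == pytest.approx(2 / 4)

    def test_identical_single_name_exact(self, N):
        sim = name_set_similarity([N("Potamogeton")], [N("Potamogeton")])
        assert sim.category == "exact"
        assert sim.query_coverage == 1.0 and sim.candidate_coverage == 1.0

    def test_disjoint_different(self, N):
        sim = name_set_similarity([N("Adarca")], [N("Potamogeton")])
        assert sim.category == "different" and sim.query_coverage == 0.0

    def test_marker_only_set(self, N):
        sim = name_set_similarity([N("alius")], [N("Potamogeton")])
        assert sim.category == "different"
        assert "marker-only" in sim.reason

    def test_variant_only_match_still_exact_category(self, N):
        # orthographic variants still count as "exactly the same name"
        sim = name_set_similarity([N("Lupha")], [N("Luppa")])
        assert sim.category == "exact" and sim.exact_coverage == 1.0

    def test_all_partial_matches_categorize_partly(self, N):
        # full coverage but only stem-strength evidence is not "largely"
        sim = name_set_similarity([N("Erisimi")], [N("Erysimum")])
        assert sim.category == "partly"
        assert sim.query_coverage == 1.0

    def test_roughly_stem_signal(self, N):
        sim = name_set_similarity([N("Tragonum")], [N("Tragana")])
        assert sim.category == "roughly"

    def test_extra_candidate_name_downgrades_exact(self, N):
        sim = name_set_similarity(
            [N("Colocasia")], [N("Colocasia"), N("Arum Aegyptiacum")])
        assert sim.category == "largely"
        assert sim.candidate_coverage == pytest.approx(1 / 2)

    def test_monotone_theta(self, barbarea_names):
        q, c = barbarea_names
        order = {"different": 0, "roughly": 0, "partly": 1, "largely": 2,
                 "exact": 3}
        cats = [
            name_set_similarity(q, c, Thresholds(theta_largely=t)).category
            for t in (0.9, 0.75, 2 / 3, 0.5, 0.25)
        ]
        ranks = [order[c] for c in cats]
        assert ranks == sorted(ranks)  # lowering theta never downgrades


# ---------------------------------------------------------------------------
# classify_pair
# ---------------------------------------------------------------------------


def _sp(no, names, det, cid="X"):
    from herblink.io import Specimen
    return Specimen(cid, no, tuple(names), det)


class TestClassifyPair:
    @pytest.mark.parametrize("q_names, q_det, c_names, c_det, level, branch", [
        (["Terebinthus"], "Pistacia terebinthus",
         ["Terebinthus"], "Pistacia terebinthus", 100, "A"),
        (["Potamogeton"], "Potamogeton natans",
         ["Potamogeton"], "Potamogeton natans", 100, "A"),
        (["Robertina", "Adarca", "Sideritis"], "Barbarea vulgaris",
         ["Robertina", "Cardamine"], "Barbarea vulgaris", 50, "C"),
        (["Bellis"], "Bellis perennis",
         ["Bellis"], "Globularia bisnagarica", 25, "D1"),
        (["Lupha"], "Colocasia esculenta",
         ["Aron verum"], "Colocasia esculenta", 25, "D2"),
        (["Lupha"], "Colocasia esculenta",
         ["Potamogeton"], "Potamogeton natans", 0, "E"),
    ])
    def test_rules(self, q_names, q_det, c_names, c_det, level, branch):
        lv, br, _ = classify_pair(_sp(1, q_names, q_det), _sp(2, c_names, c_det))
        assert (lv, br) == (level, branch)

    def test_barbarea_pair_is_large_similarity(self, barbarea_names):
        from conftest import BARBAREA_QUERY, BARBAREA_TARGET
        lv, br, sim = classify_pair(
            _sp(1, BARBAREA_QUERY, "Barbarea vulgaris"),
            _sp(2, BARBAREA_TARGET, "Barbarea vulgaris"))
        assert (lv, br) == (75, "B")

    def test_undetermined_query_is_species_nonmatch(self):
        lv, br, _ = classify_pair(_sp(1, ["Aron"], ""),
                                  _sp(2, ["Aron"], "Arum maculatum"))
        assert (lv, br) == (25, "D1")


# ---------------------------------------------------------------------------
# classify_unit
# ---------------------------------------------------------------------------


class TestClassifyUnit:
    def test_best_among_decoys(self):
        target = make_collection("T", [
            (i, [f"Decoynamea {i}"], f"Genus species{i}") for i in range(1, 11)
        ] + [(11, ["Terebinthus"], "Pistacia terebinthus")])
        q = _sp(1, ["Terebinthus"], "Pistacia terebinthus", "Q")
        out = classify_unit(q, target)
        assert out.level == 100 and out.best_counterpart == 11

    def test_cross_assignment_d3(self):
        target = make_collection("T", [
            (1, ["Bellis"], "Globularia bisnagarica"),
            (2, ["Consolida minor"], "Bellis perennis"),
        ])
        q = _sp(1, ["Bellis"], "Bellis perennis", "Q")
        out = classify_unit(q, target)
        assert (out.level, out.branch) == (25, "D3")
        assert out.best_counterpart is None

    def test_same_specimen_holding_both_is_not_d3(self):
        target = make_collection("T", [
            (1, ["Bellis"], "Bellis perennis"),
        ])
        q = _sp(1, ["Bellis"], "Bellis perennis", "Q")
        out = classify_unit(q, target)
        assert (out.level, out.branch) == (100, "A")

    def test_self_match(self, toy_pair):
        query, _ = toy_pair
        for sp in query:
            assert classify_unit(sp, query).level == 100

    def test_empty_target_rejected(self):
        q = _sp(1, ["Aron"], "Arum maculatum", "Q")
        with pytest.raises(ValueError, match="empty target"):
            classify_unit(q, Collection(id="T", specimens=[]))

    def test_tie_breaks_on_lower_specimen_no(self):
        target = make_collection("T", [
            (5, ["Aron"], "Arum maculatum"),
            (2, ["Aron"], "Arum maculatum"),
        ])
        q = _sp(1, ["Aron"], "Arum maculatum", "Q")
        assert classify_unit(q, target).best_counterpart == 2

    def test_order_invariance(self, toy_pair):
        query, target = toy_pair
        reversed_target = Collection(
            id="T", specimens=list(reversed(target.specimens)))
        for sp in query:
            a = classify_unit(sp, target)
            b = classify_unit(sp, reversed_target)
            assert (a.level, a.branch, a.best_counterpart) == \
                   (b.level, b.branch, b.best_counterpart)

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        cache = NameCache()
        thresholds = Thresholds()
        rnd = random.Random(42)
        for rep in range(15):
            cfg = SyntheticConfig(
                n_species=14, n_query=rnd.randint(2, 8),
                n_target=rnd.randint(2, 14), rho_common_origin=rnd.random(),
                p_shared_species=rnd.random(), p_mutation=0.2 * rnd.random(),
                p_extra_name=0.3, p_cross_assign=0.4, p_duplicate=0.3,
                seed=900 + rep)
            query, target, _ = generate_pair(cfg)
            for sp in query:
                got = classify_unit(sp, target, thresholds, cache)
                lv, br, cp = oracle_unit([sp], target, thresholds, cache)
                assert (got.level, got.branch, got.best_counterpart) == (lv, br, cp)


# ---------------------------------------------------------------------------
# compare_collections
# ---------------------------------------------------------------------------


class TestCompareCollections:
    def test_toy_profile(self, toy_pair):
        query, target = toy_pair
        profile, assignments = compare_collections(query, target,
                                                   unit_mode="specimen")
        assert profile.as_dict() == {100: 1, 75: 0, 50: 1, 25: 0, 0: 1}
        assert profile.n_units == len(assignments) == 3

    def test_identity_all_exact(self, toy_pair):
        query, _ = toy_pair
        profile, _ = compare_collections(query, query, unit_mode="specimen")
        assert profile.as_dict()[100] == len(query)

    def test_combined_mode_upgrades(self, toy_pair):
        query, target = toy_pair
        # second target improves only the Barbarea unit (50 -> 75)
        target2 = make_collection("T2", [
            (1, ["Robertina", "Adarca", "Cardamine"], "Barbarea vulgaris"),
        ])
        single, _ = compare_collections(query, target, unit_mode="specimen")
        combined, _ = compare_collections(query, [target, target2],
                                          unit_mode="specimen")
        assert single.as_dict() == {100: 1, 75: 0, 50: 1, 25: 0, 0: 1}
        assert combined.as_dict() == {100: 1, 75: 1, 50: 0, 25: 0, 0: 1}
        assert combined.config_echo["combined"] is True

    def test_combined_dominance(self):
        cfg = SyntheticConfig(n_species=20, n_query=10, n_target=15,
                              p_mutation=0.1, seed=3)
        query, target, _ = generate_pair(cfg)
        cfg2 = SyntheticConfig(n_species=20, n_query=10, n_target=15,
                               rho_common_origin=0.3, seed=4)
        _, target2, _ = generate_pair(cfg2)
        target2 = Collection(id="T2", specimens=[
            type(s)(collection_id="T2", specimen_no=s.specimen_no,
                    original_names=s.original_names,
                    determination=s.determination) for s in target2])
        _, single = compare_collections(query, target, unit_mode="specimen")
        _, combined = compare_collections(query, [target, target2],
                                          unit_mode="specimen")
        by_unit = {a.unit_id: a.level for a in single}
        for a in combined:
            assert a.level >= by_unit[a.unit_id]

    def test_taxon_mode_groups_determinations(self):
        query = make_collection("Q", [
            (1, ["Aron"], "Arum maculatum"),
            (2, ["Aron verum"], "Arum maculatum"),   # duplicate taxon
            (3, ["Lupha"], ""),                      # undetermined: own unit
        ], unit_mode="taxon")
        target = make_collection("T", [(1, ["Aron"], "Arum maculatum")])
        profile, assignments = compare_collections(query, target)
        assert profile.n_units == 2
        levels = {a.unit_id: a.level for a in assignments}
        assert levels["arum maculatum"] == 100  # best duplicate wins

    def test_taxon_mode_without_determinations_rejected(self):
        query = make_collection("Q", [(1, ["Aron"], "")])
        target = make_collection("T", [(1, ["Aron"], "Arum maculatum")])
        with pytest.raises(ValueError, match="determination"):
            compare_collections(query, target, unit_mode="taxon")

    def test_conservation(self, toy_pair):
        query, target = toy_pair
        profile, assignments = compare_collections(query, target,
                                                   unit_mode="specimen")
        assert sum(profile.counts.values()) == profile.n_units == len(assignments)
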