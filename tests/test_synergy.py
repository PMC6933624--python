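"""Per-target synergy-set search and network assembly."""

import itertools

import numpy as np
import pytest

from mirna_synergy.config import RunConfig
from mirna_synergy.datatypes import MIRNA, MRNA, BindingNetwork
from mirna_synergy.preprocess import log2_zscore
from mirna_synergy.synergy import (CandidateSet, EffectScorer, SynergySet,
                                   build_network, candidate_sets,
                                   compare_networks, find_max_synergy_set,
                                   sequence_level_pairs)
from mirna_synergy.synthetic import make_bundle


def scoring_setup(seed, p=4, q=2, n=2000, density=0.6):
    """Bundle -> (z-scored data, pre-z averages, binding) for effect scoring."""
    b = make_bundle(p, q, n, 0.0, seed=seed, density=density)
    data, means = log2_zscore(b.expression_nonneg)
    return b, data, means.to_dict()


class TestCandidateSets:
    def test_filtering_rules(self):
        net = BindingNetwork({("m1", "G1"), ("m2", "G1"), ("m3", "G2"),
                              ("m4", "G3")})
        cands = candidate_sets(net, ["m1", "m2", "m3"], ["G1", "G2", "G4"])
        by_target = {c.target_id: c.miRNAs for c in cands}
        # G3 not selected, G4 has no binding, m4 not selected
        assert by_target == {"G1": {"m1", "m2"}, "G2": {"m3"}}

    def test_shared_regulators(self):
        net = BindingNetwork({(m, g) for m in ("a", "b", "c")
                              for g in ("G1", "G2")})
        cands = candidate_sets(net, ["a", "b", "c"], ["G1", "G2"])
        assert len(cands) == 2
        assert all(c.miRNAs == {"a", "b", "c"} for c in cands)


class TestFindMaxSynergySet:
    def test_exhaustive_matches_brute_force(self):
        config = RunConfig(subset_cap=10)
        for seed in (0, 1, 2):
            b, data, averages = scoring_setup(seed)
            cands = candidate_sets(b.binding, b.model.mirnas, b.model.mrnas)
            for cand in cands:
                scorer = EffectScorer(cand, data, averages, config)
                got = find_max_synergy_set(cand, data, averages, config,
                                           scorer=scorer)
                # independent brute force over every non-empty subset
                best = None
                members = sorted(cand.miRNAs)
                for r in range(1, len(members) + 1):
                    for combo in itertools.combinations(members, r):
                        d = scorer.delta(frozenset(combo))
                        key = (-d, len(combo), combo)
                        if best is None or key < best[0]:
                            best = (key, combo, d)
                _, combo, d = best
                if d <= 0:
                    assert got is None
                else:
                    assert got.miRNAs == list(combo)
                    assert got.delta == pytest.approx(d)

    def test_greedy_never_beats_exhaustive(self):
        for seed in range(5):
            b, data, averages = scoring_setup(seed + 10)
            cands = candidate_sets(b.binding, b.model.mirnas, b.model.mrnas)
            for cand in cands:
                if len(cand.miRNAs) < 2:
                    continue
                cfg_ex = RunConfig(subset_cap=10)
                cfg_gr = RunConfig(subset_cap=1)
                scorer = EffectScorer(cand, data, averages, cfg_ex)
                ex = find_max_synergy_set(cand, data, averages, cfg_ex,
                                          scorer=scorer)
                gr = find_max_synergy_set(cand, data, averages, cfg_gr,
                                          scorer=scorer)
                if gr is not None:
                    assert ex is not None
                    assert gr.search_mode == "greedy"
                    assert ex.delta >= gr.delta - 1e-12

    def test_all_nonpositive_gives_none(self):
        # activating regulation: knocking the miRNA off lowers the target,
        # so every subset has delta <= 0 and no synergy set is reported
        from conftest import make_expr
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        y = 1.5 * x + rng.normal(size=500)
        data = make_expr(np.vstack([x, y]), ids=["m1", "G1"],
                         classes=[MIRNA, MRNA])
        cand = CandidateSet("G1", {"m1"})
        got = find_max_synergy_set(cand, data, {"m1": 3.0}, RunConfig())
        assert got is None

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError):
            find_max_synergy_set(CandidateSet("G1", set()), None, {},
                                 RunConfig())


class TestBuildNetwork:
    def test_pairs_from_one_set(self):
        net = build_network([SynergySet("G1", ["a", "b", "c"], 1.0, "exhaustive")])
        assert set(net.edges) == {("a", "b"), ("a", "c"), ("b", "c")}
        assert all(s == {"G1"} for s in net.edges.values())

    def test_support_merged_across_targets(self):
        net = build_network([
            SynergySet("G1", ["a", "b"], 1.0, "exhaustive"),
            SynergySet("G2", ["a", "b"], 0.5, "exhaustive")])
        assert set(net.edges) == {("a", "b")}
        assert net.edges[("a", "b")] == {"G1", "G2"}

    def test_singletons_contribute_nothing(self):
        net = build_network([SynergySet("G1", ["a"], 1.0, "exhaustive")])
        assert not net.edges and not net.nodes


class TestSequenceLevelPairs:
    def test_shared_target_pair(self):
        net = BindingNetwork({("a", "G"), ("b", "G")})
        assert sequence_level_pairs(net) == {("a", "b")}

    def test_star_gives_all_pairs(self):
        net = BindingNetwork({(m, "G") for m in "abcd"})
        assert len(sequence_level_pairs(net)) == 6

    def test_disjoint_targets_give_none(self):
        net = BindingNetwork({("a", "G1"), ("b", "G2")})
        assert sequence_level_pairs(net) == set()


class TestCompareNetworks:
    def test_identical_and_disjoint(self):
        from mirna_synergy.synergy import SynergyNetwork
        net = SynergyNetwork(nodes={"a", "b"}, edges={("a", "b"): {"G"}})
        same = compare_networks({("a", "b")}, net)
        assert not same.sequence_only and not same.expression_only
        disj = compare_networks({("c", "d")}, net)
        assert not disj.both

    def test_mismatch_only_shared_targets_appear_sequence_only(self):
        # with sequence-level-only binding edges injected, pairs supported
        # only by those edges cannot be expression-level synergy edges
        b, data, averages = scoring_setup(3, p=5, q=3, n=1500)
        bundle = make_bundle(5, 3, 1500, mismatch_fraction=1.0, seed=3,
                             density=0.6)
        data, means = log2_zscore(bundle.expression_nonneg)
        averages = means.to_dict()
        config = RunConfig()
        cands = candidate_sets(bundle.binding, bundle.model.mirnas,
                               bundle.model.mrnas)
        sets = [s for c in cands
                if (s := find_max_synergy_set(c, data, averages, config))]
        net = build_network(sets)
        seq = sequence_level_pairs(bundle.binding)
        cmp = compare_networks(seq, net)
        assert cmp.sequence_only | cmp.both == seq
        assert len(cmp.both) + len(cmp.sequence_only) == len(seq)


def test_network_edges_have_binding_support():
    """Both miRNAs of every edge share >= 1 binding target (soundness)."""
    for seed in (0, 4):
        bundle, data, averages = scoring_setup(seed, p=5, q=3)
        config = RunConfig()
        cands = candidate_sets(bundle.binding, bundle.model.mirnas,
                               bundle.model.mrnas)
        sets = [s for c in cands
                if (s := find_max_synergy_set(c, data, averages, config))]
        net = build_network(sets)
        for (a, b), support in net.edges.items():
            shared = bundle.binding.targets_of(a) & bundle.binding.targets_of(b)
            assert shared >= support


def test_strong_joint_repressors_recovered_as_edge():
    """Two miRNAs strongly repressing one mRNA are recovered together in the
    synergy set (hence as a network edge) in >= 80% of seeds."""
    from mirna_synergy.datatypes import ExpressionMatrix
    from mirna_synergy.synthetic import SemModel, sample_sem
    import pandas as pd

    hits = 0
    seeds = 20
    for seed in range(seeds):
        rng = np.random.default_rng(seed)
        w1, w2 = -rng.uniform(0.8, 1.5), -rng.uniform(0.8, 1.5)
        model = SemModel(["m1", "m2", "G"],
                         {"m1": MIRNA, "m2": MIRNA, "G": MRNA},
                         {("m1", "G"): w1, ("m2", "G"): w2},
                         intercepts={"m1": 3.0, "m2": 3.0, "G": 8.0})
        expr = sample_sem(model, 5000, seed=seed + 500)
        X = expr.values.to_numpy()
        shift = float(np.ceil(max(0.0, -X.min())) + 1.0)
        nonneg = ExpressionMatrix(
            pd.DataFrame(np.exp2(X + shift) - 1.0, index=expr.values.index,
                         columns=expr.values.columns),
            expr.entity_class.copy())
        data, means = log2_zscore(nonneg)
        cand = CandidateSet("G", {"m1", "m2"})
        got = find_max_synergy_set(cand, data, means.to_dict(), RunConfig())
        if got is not None and got.miRNAs == ["m1", "m2"]:
            hits += 1
    assert hits >= 0.8 * seeds, f"recovered {hits}/{seeds}"
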