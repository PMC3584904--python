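"""Leave-cluster-out protocol, top-hit labelling and ROC analysis."""

import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from gofp.align import LocalAlignmentTrace
from gofp.annotation import ChainRecord, DomainRecord
from gofp.benchmark import (
    GO_PROFILE,
    ConfusionCounts,
    LabeledTopHit,
    calibrate_flat,
    exclude_cluster,
    flat_database,
    flat_search,
    label_top_hit,
    roc,
    run_benchmark,
    verify_domain,
)
from gofp.library import LibraryParams, build_library
from gofp.search import Hit
from gofp.world import WorldParams, generate_world


def _labeled(score, correct, field="function_correct"):
    kw = dict(function_correct=False, fold_correct=False,
              domain_verified=True)
    kw[field] = correct
    tr = LocalAlignmentTrace(0, 1, [0], score)
    hit = Hit("q", "fA", "GO:1", tr, score, 10 ** (-score))
    return LabeledTopHit(test_chain_id="c", method=GO_PROFILE, hit=hit,
                         roc_score=score, **kw)


class TestExcludeCluster:
    def test_absent_cluster_is_identity(self, small_world):
        d, c = exclude_cluster(small_world.domains, small_world.chains, "nope")
        assert len(d) == len(small_world.domains)
        assert len(c) == len(small_world.chains)

    def test_cluster_members_fully_removed(self, small_world):
        cl = small_world.chains[0].cluster_id
        d, c = exclude_cluster(small_world.domains, small_world.chains, cl)
        assert all(ch.cluster_id != cl for ch in c)
        kept_chains = {ch.chain_id for ch in c}
        assert all(dom.chain_id in kept_chains for dom in d)

    def test_exclusion_can_empty_an_entry(self, tiny_dag):
        # 3 unrelated domains, all in one cluster: removing the cluster
        # leaves nothing, so the (fold, term) entry vanishes on rebuild
        rng = np.random.default_rng(0)
        from gofp.alphabet import decode
        doms, chains = [], []
        for i in range(3):
            seq = decode(rng.integers(0, 20, size=60).astype(np.int8))
            doms.append(DomainRecord(f"d{i}", f"c{i}", "fA", seq,
                                     domain_go_ids={"GO:0004721"}))
            chains.append(ChainRecord(f"c{i}", [f"d{i}"],
                                      {"GO:0004721"}, cluster_id="shared"))
        params = LibraryParams(calibration_n_random=100, calibration_length=60)
        full = build_library(doms, chains, tiny_dag, params)
        assert len(full) == 1
        d2, c2 = exclude_cluster(doms, chains, "shared")
        rebuilt = build_library(d2, c2, tiny_dag, params)
        assert len(rebuilt) == 0


class TestFlatSearch:
    def test_self_match_is_top_hit(self, small_world, small_library):
        lib, params = small_library
        flat = flat_database(lib, small_world.domains_by_id())
        ev = calibrate_flat(params, 90, seed=1, n_random=120)
        dom = flat[0]
        hits = flat_search("q", dom.sequence, flat, params, ev, max_evalue=math.inf)
        assert hits[0].fold_id == dom.fold_id
        assert hits[0].all_go_ids() == frozenset(dom.domain_go_ids)

    def test_empty_database_gives_empty_list(self, small_library):
        lib, params = small_library
        ev = calibrate_flat(params, 90, seed=1, n_random=120)
        assert flat_search("q", "ACDEF", [], params, ev) == []

    def test_flat_db_holds_exactly_the_profile_members(self, small_world, small_library):
        lib, _ = small_library
        flat = flat_database(lib, small_world.domains_by_id())
        member_ids = {m for e in lib.entries for m in e.member_ids}
        assert {d.domain_id for d in flat} == member_ids


class TestVerifyDomain:
    def _chain_with_domains(self, seqs):
        doms = {
            f"d{i}": DomainRecord(f"d{i}", "ch", f"f{i}", s)
            for i, s in enumerate(seqs)
        }
        chain = ChainRecord("ch", list(doms), {"GO:1"}, cluster_id="cl")
        return chain, doms

    def _hit(self, start, end):
        tr = LocalAlignmentTrace(start, end, [None] * (end - start), 50.0)
        return Hit("ch", "fA", "GO:1", tr, 50.0, 1e-6)

    def test_exact_segment_identifies_its_domain(self):
        rng = np.random.default_rng(3)
        from gofp.alphabet import decode
        s1 = decode(rng.integers(0, 20, size=60).astype(np.int8))
        s2 = decode(rng.integers(0, 20, size=60).astype(np.int8))
        chain, doms = self._chain_with_domains([s1, s2])
        hit = self._hit(60, 120)  # exactly domain 2's span
        assert verify_domain(hit, chain, doms, rng_seed=1) == "d1"

    def test_symmetric_straddle_is_ambiguous(self):
        rng = np.random.default_rng(4)
        from gofp.alphabet import decode
        s = decode(rng.integers(0, 20, size=60).astype(np.int8))
        # both domains identical: any segment matches both equally
        chain, doms = self._chain_with_domains([s, s])
        hit = self._hit(30, 90)
        assert verify_domain(hit, chain, doms, rng_seed=1) is None

    def test_single_domain_chain_verifies_when_above_floor(self):
        rng = np.random.default_rng(5)
        from gofp.alphabet import decode
        s = decode(rng.integers(0, 20, size=80).astype(np.int8))
        chain, doms = self._chain_with_domains([s])
        hit = self._hit(10, 70)
        assert verify_domain(hit, chain, doms, rng_seed=1) == "d0"

    def test_missing_domain_decomposition_is_an_error(self):
        chain = ChainRecord("ch", ["dX"], {"GO:1"}, cluster_id="cl")
        hit = self._hit(0, 5)
        with pytest.raises(ValueError, match="decomposition"):
            verify_domain(hit, chain, {}, rng_seed=1)


class TestLabelSemantics:
    def _setup(self, tiny_dag):
        rng = np.random.default_rng(6)
        from gofp.alphabet import decode
        seq = decode(rng.integers(0, 20, size=80).astype(np.int8))
        dom = DomainRecord("d0", "ch", "fA", seq,
                           domain_go_ids={"GO:0004721"})
        chain = ChainRecord("ch", ["d0"], {"GO:0004721"}, cluster_id="cl")
        tr = LocalAlignmentTrace(5, 75, [None] * 70, 60.0)
        return chain, {"d0": dom}, tr

    def test_exact_term_and_fold_match_is_correct(self, tiny_dag):
        chain, doms, tr = self._setup(tiny_dag)
        hit = Hit("ch", "fA", "GO:0004721", tr, 60.0, 1e-8)
        rec = label_top_hit(hit, chain, doms, tiny_dag, min_eval_depth=2,
                            rng_seed=1)
        assert rec.function_correct and rec.fold_correct

    def test_more_specific_child_term_counts_as_failure(self, tiny_dag):
        """A prediction more specific than the annotation (child term) is a
        failure under exact-term evaluation."""
        chain, doms, tr = self._setup(tiny_dag)
        hit = Hit("ch", "fA", "GO:0004725", tr, 60.0, 1e-8)  # child of truth
        rec = label_top_hit(hit, chain, doms, tiny_dag, min_eval_depth=2,
                            rng_seed=1)
        assert rec.domain_verified
        assert not rec.function_correct

    def test_correct_term_in_wrong_domain_is_failure(self, tiny_dag):
        rng = np.random.default_rng(7)
        from gofp.alphabet import decode
        s1 = decode(rng.integers(0, 20, size=60).astype(np.int8))
        s2 = decode(rng.integers(0, 20, size=60).astype(np.int8))
        d1 = DomainRecord("d1", "ch", "fA", s1, domain_go_ids={"GO:0004721"})
        d2 = DomainRecord("d2", "ch", "fB", s2, domain_go_ids={"GO:0016787"})
        chain = ChainRecord("ch", ["d1", "d2"],
                            {"GO:0004721", "GO:0016787"}, cluster_id="cl")
        # hit aligned on d2's span but claiming d1's term and fold
        tr = LocalAlignmentTrace(60, 120, [None] * 60, 50.0)
        hit = Hit("ch", "fA", "GO:0004721", tr, 50.0, 1e-8)
        rec = label_top_hit(hit, chain, {"d1": d1, "d2": d2}, tiny_dag,
                            min_eval_depth=2, rng_seed=1)
        assert rec.verified_domain_id == "d2"
        assert not rec.function_correct and not rec.fold_correct

    def test_shallow_hit_excluded_from_evaluation(self, tiny_dag):
        chain, doms, tr = self._setup(tiny_dag)
        hit = Hit("ch", "fA", "GO:0003824", tr, 60.0, 1e-8)  # depth 1
        assert label_top_hit(hit, chain, doms, tiny_dag, min_eval_depth=2,
                             rng_seed=1) is None

    def test_function_correct_implies_domain_verified(self):
        with pytest.raises(ValueError):
            LabeledTopHit("c", GO_PROFILE, None, function_correct=True,
                          fold_correct=False, domain_verified=False)


class TestRoc:
    def test_methods_formula_point(self):
        c = ConfusionCounts(tp=3, fn=1, fp=2, tn=4)
        assert c.tpr == pytest.approx(0.75)
        assert c.fpr == pytest.approx(1 / 3)

    def test_perfect_separation_gives_unit_auc(self):
        labeled = [_labeled(s, True) for s in (9, 8, 7)] + [
            _labeled(s, False) for s in (3, 2, 1)
        ]
        assert roc(labeled).auc == 1.0

    def test_reversed_labels_mirror_auc(self):
        rng = np.random.default_rng(1)
        labeled = [
            _labeled(float(rng.normal(ok, 1.0)), ok)
            for ok in rng.random(200) < 0.5
        ]
        fwd = roc(labeled).auc
        flipped = [
            _labeled(l.roc_score, not l.function_correct) for l in labeled
        ]
        assert roc(flipped).auc == pytest.approx(1.0 - fwd, abs=1e-12)

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(17)
        labeled = [
            _labeled(float(rng.random()), bool(rng.random() < 0.5))
            for _ in range(2000)
        ]
        assert 0.45 <= roc(labeled).auc <= 0.55

    def test_monotone_score_transform_preserves_curve(self):
        rng = np.random.default_rng(2)
        labeled = [
            _labeled(float(rng.normal(ok, 1.0)), ok)
            for ok in rng.random(100) < 0.4
        ]
        base = roc(labeled)
        squashed = [
            _labeled(math.tanh(l.roc_score / 10), l.function_correct)
            for l in labeled
        ]
        again = roc(squashed)
        assert again.points == base.points
        assert again.auc == pytest.approx(base.auc)

    def test_matches_sklearn_auc(self):
        rng = np.random.default_rng(3)
        labels = rng.random(300) < 0.3
        scores = rng.normal(labels.astype(float), 1.2)
        labeled = [_labeled(float(s), bool(y)) for s, y in zip(scores, labels)]
        assert roc(labeled).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-9
        )

    def test_degenerate_classes_error(self):
        with pytest.raises(ValueError, match="no negative"):
            roc([_labeled(1.0, True)])
        with pytest.raises(ValueError, match="no positive"):
            roc([_labeled(1.0, False)])

    def test_curve_shape_invariants(self):
        rng = np.random.default_rng(4)
        labeled = [
            _labeled(float(rng.normal()), bool(rng.random() < 0.5))
            for _ in range(50)
        ]
        curve = roc(labeled)
        assert curve.points[0] == (0.0, 0.0)
        assert curve.points[-1] == (1.0, 1.0)
        fprs = [p[0] for p in curve.points]
        assert fprs == sorted(fprs)


class TestRunBenchmark:
    def test_no_test_chains_is_an_error(self, small_world):
        w = small_world
        with pytest.raises(ValueError, match="test chains"):
            run_benchmark([], w.domains, w.chains, w.dag)

    def test_leave_cluster_out_hygiene(self, small_world):
        """After exclusion no profile member and no flat sequence shares
        the test chain's cluster."""
        w = small_world
        params = LibraryParams(calibration_n_random=100, calibration_length=60)
        chain = w.chains[0]
        d2, c2 = exclude_cluster(w.domains, w.chains, chain.cluster_id)
        lib = build_library(d2, c2, w.dag, params, seed=1)
        excluded_domains = {
            d.domain_id for d in w.domains if d.domain_id not in
            {x.domain_id for x in d2}
        }
        for e in lib.entries:
            assert not (set(e.member_ids) & excluded_domains)
        flat = flat_database(lib, {d.domain_id: d for d in d2})
        assert not ({d.domain_id for d in flat} & excluded_domains)

    def test_end_to_end_small_benchmark_is_deterministic(self, small_world):
        w = small_world
        params = LibraryParams(calibration_n_random=100, calibration_length=60)
        tc = w.chains[:6]
        r1 = run_benchmark(tc, w.domains, w.chains, w.dag, params, seed=3,
                           depths=(2,), aligner=w.structural_aligner())
        r2 = run_benchmark(tc, w.domains, w.chains, w.dag, params, seed=3,
                           depths=(2,), aligner=w.structural_aligner())
        for key in r1.labeled:
            a = [(l.test_chain_id, l.function_correct, l.roc_score)
                 for l in r1.labeled[key]]
            b = [(l.test_chain_id, l.function_correct, l.roc_score)
                 for l in r2.labeled[key]]
            assert a == b
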