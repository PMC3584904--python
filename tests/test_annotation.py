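"""Chain-to-domain annotation transfer via minimal fold covers."""

import numpy as np
import pytest

from gofp.annotation import (
    ChainRecord,
    DomainRecord,
    assign_domain_annotations,
    minimal_fold_set,
)
from gofp.world import WorldParams, generate_world, make_fragment_artifact

from oracles import brute_force_hitting_set


class TestMinimalFoldSet:
    def test_forced_single(self):
        assert minimal_fold_set([{"A"}]) == {"A"}

    def test_common_fold_wins(self):
        assert minimal_fold_set([{"A", "B"}, {"A", "C"}, {"A"}]) == {"A"}

    def test_lexicographic_tie_break(self):
        # minimum size is 2; {A,B} is lexicographically first of the optima
        assert minimal_fold_set([{"A", "B"}, {"B", "C"}, {"A", "C"}]) == {"A", "B"}

    def test_errors(self):
        with pytest.raises(ValueError, match="no evidence"):
            minimal_fold_set([])
        with pytest.raises(ValueError, match="empty fold set"):
            minimal_fold_set([{"A"}, set()])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n_folds = int(rng.integers(1, 11))
            n_chains = int(rng.integers(1, 13))
            folds = [f"F{i}" for i in range(n_folds)]
            sets = []
            for _ in range(n_chains):
                k = int(rng.integers(1, n_folds + 1))
                sets.append(set(rng.choice(folds, size=k, replace=False)))
            got = minimal_fold_set(sets)
            oracle = brute_force_hitting_set(sets)
            assert len(got) == len(oracle)
            assert got == oracle

    def test_removing_evidence_never_grows_cover(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            folds = [f"F{i}" for i in range(6)]
            sets = [
                set(rng.choice(folds, size=int(rng.integers(1, 5)), replace=False))
                for _ in range(int(rng.integers(2, 8)))
            ]
            full = minimal_fold_set(sets)
            reduced = minimal_fold_set(sets[:-1])
            assert len(reduced) <= len(full)


def _single_chain(cid, domains, terms, flags=()):
    return ChainRecord(
        chain_id=cid,
        domain_ids=[d.domain_id for d in domains],
        chain_go_ids=set(terms),
        cluster_id=cid,
        flags=set(flags),
    )


def _dom(did, cid, fold):
    return DomainRecord(domain_id=did, chain_id=cid, fold_id=fold, sequence="ACDEF")


class TestAssignDomainAnnotations:
    def test_unique_minimal_cover(self, tiny_dag):
        t = "GO:0016787"
        d1 = _dom("d1", "c1", "A")
        d2a = _dom("d2a", "c2", "A")
        d2b = _dom("d2b", "c2", "B")
        chains = [
            _single_chain("c1", [d1], [t]),
            _single_chain("c2", [d2a, d2b], [t]),
        ]
        assign_domain_annotations(chains, [d1, d2a, d2b], tiny_dag)
        assert t in d1.domain_go_ids and t in d2a.domain_go_ids
        assert d2b.domain_go_ids == set()

    def test_annotations_accumulate_across_terms(self, tiny_dag):
        t1, t2 = "GO:0016787", "GO:0004721"
        da = _dom("da", "c1", "A")
        db = _dom("db", "c1", "B")
        da2 = _dom("da2", "c2", "A")
        db2 = _dom("db2", "c3", "B")
        chains = [
            _single_chain("c1", [da, db], [t1, t2]),
            _single_chain("c2", [da2], [t1]),
            _single_chain("c3", [db2], [t2]),
        ]
        assign_domain_annotations(chains, [da, db, da2, db2], tiny_dag)
        assert da.domain_go_ids == {t1}
        assert db.domain_go_ids == {t2}

    def test_single_domain_chains_inherit_chain_terms(self, tiny_dag):
        d = _dom("d1", "c1", "A")
        chains = [_single_chain("c1", [d], ["GO:0016787", "GO:0004725"])]
        assign_domain_annotations(chains, [d], tiny_dag)
        assert d.domain_go_ids == {"GO:0016787", "GO:0004725"}

    def test_flagged_chains_are_not_evidence(self, tiny_dag):
        d = _dom("d1", "c1", "A")
        chains = [_single_chain("c1", [d], ["GO:0016787"], flags=["mutant"])]
        assign_domain_annotations(chains, [d], tiny_dag)
        assert d.domain_go_ids == set()

    def test_unknown_term_skipped(self, tiny_dag):
        d = _dom("d1", "c1", "A")
        chains = [_single_chain("c1", [d], ["GO:7777777"])]
        assign_domain_annotations(chains, [d], tiny_dag)
        assert d.domain_go_ids == set()

    def test_cover_property_every_evidence_chain_is_explained(self, tiny_dag):
        rng = np.random.default_rng(5)
        term = "GO:0016787"
        domains, chains = [], []
        for c in range(10):
            k = int(rng.integers(1, 4))
            doms = [
                _dom(f"d{c}_{i}", f"c{c}", f"F{int(rng.integers(0, 5))}")
                for i in range(k)
            ]
            domains.extend(doms)
            chains.append(_single_chain(f"c{c}", doms, [term]))
        assign_domain_annotations(chains, domains, tiny_dag)
        by_id = {d.domain_id: d for d in domains}
        for c in chains:
            assert any(term in by_id[d].domain_go_ids for d in c.domain_ids)


class TestFragmentConfound:
    def test_fragments_force_a_spurious_fold_into_the_cover(self):
        """Isolated fragment chains annotated with the whole protein's
        function drag their (non-functional) fold into the cover — the
        documented failure mode of cover-based annotation transfer."""
        w = generate_world(WorldParams(
            n_folds=2, n_functions=2, domains_per_cell=4, clusters_per_cell=4,
            fold_core_length=60, seed=3, multidomain_fraction=0.0,
        ))
        # a term whose genuine evidence lives exclusively in fold f.1
        from gofp.ontology import GoDag, GoTerm
        go = "GO:1999998"
        terms = dict(w.dag.terms)
        terms[go] = GoTerm(go, "fold-1-only activity", (w.dag.root_id,))
        w.dag = GoDag(terms, w.dag.root_id)
        dbi = w.domains_by_id()
        f1_chains = [c for c in w.chains
                     if dbi[c.domain_ids[0]].fold_id == "f.1"][:3]
        for c in f1_chains:
            c.chain_go_ids.add(go)
        companion = "f.2"
        before_sets = [
            {dbi[d].fold_id for d in c.domain_ids}
            for c in w.chains if go in c.chain_go_ids
        ]
        cover_before = minimal_fold_set(before_sets)
        assert cover_before == {"f.1"}
        make_fragment_artifact(w, ("f.1", go), n_fragments=3,
                               companion_fold=companion)
        dbi = w.domains_by_id()
        after_sets = [
            {dbi[d].fold_id for d in c.domain_ids}
            for c in w.chains if go in c.chain_go_ids
        ]
        cover_after = minimal_fold_set(after_sets)
        assert companion in cover_after
        # and the spurious fold also equals what the exhaustive solver finds
        assert cover_after == brute_force_hitting_set(after_sets)
        # downstream: fragment domains now wrongly receive the term
        assign_domain_annotations(w.chains, w.domains, w.dag)
        frag = [d for d in w.domains if d.domain_id.startswith("frag_")][0]
        assert go in frag.domain_go_ids
        assert go not in w.truth[frag.domain_id].go_ids
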