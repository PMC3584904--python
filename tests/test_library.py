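"""Profile-library construction: filtering, redundancy, masters, pile-up."""

import numpy as np
import pytest

from gofp.align import PairwiseAlignment, global_align, percent_identity
from gofp.annotation import ChainRecord, DomainRecord
from gofp.library import (
    LibraryParams,
    build_library,
    build_matrix,
    load_library,
    pileup,
    reduce_redundancy,
    save_library,
    select_master,
)
from gofp.world import WorldParams, generate_world


def _dom(did, fold="fA", seq="ACDEFGHIKL", chain=None, go=("GO:0004721",),
         multi=False):
    return DomainRecord(
        domain_id=did, chain_id=chain or f"ch_{did}", fold_id=fold,
        sequence=seq, is_multidomain_entry=multi, domain_go_ids=set(go),
    )


def _chain(dom, flags=()):
    return ChainRecord(
        chain_id=dom.chain_id, domain_ids=[dom.domain_id],
        chain_go_ids=set(dom.domain_go_ids), cluster_id=dom.chain_id,
        flags=set(flags),
    )


class TestBuildMatrix:
    def test_multi_term_domain_joins_multiple_cells(self, tiny_dag):
        d = _dom("d1", go=("GO:0004721", "GO:0004725"))
        cells = build_matrix([d], [_chain(d)], tiny_dag, LibraryParams())
        assert set(cells) == {("fA", "GO:0004721"), ("fA", "GO:0004725")}

    def test_flagged_chain_domains_excluded(self, tiny_dag):
        d = _dom("d1")
        cells = build_matrix([d], [_chain(d, flags=["mutant"])], tiny_dag,
                             LibraryParams())
        assert cells == {}

    def test_multidomain_entry_excluded(self, tiny_dag):
        d = _dom("d1", multi=True)
        assert build_matrix([d], [_chain(d)], tiny_dag, LibraryParams()) == {}

    def test_shallow_terms_dropped(self, tiny_dag):
        # GO:0003824 is at depth 1 < default min depth 3
        d = _dom("d1", go=("GO:0003824",))
        assert build_matrix([d], [_chain(d)], tiny_dag, LibraryParams()) == {}


class TestReduceRedundancy:
    def test_identical_pair_keeps_lexicographically_first(self):
        a, b = _dom("a"), _dom("b")
        assert [d.domain_id for d in reduce_redundancy([a, b], 40.0)] == ["a"]

    def test_unrelated_sequences_both_survive(self):
        a = _dom("a", seq="ACDEFGHIKLMNPQRSTVWY")
        b = _dom("b", seq="WYVTSRQPNMLKIHGFEDCA")
        kept = reduce_redundancy([a, b], 40.0)
        assert {d.domain_id for d in kept} == {"a", "b"}
        aln = global_align(a.sequence, b.sequence)
        assert percent_identity(aln) < 40.0

    def test_single_domain_is_its_own_representative(self):
        a = _dom("a")
        assert reduce_redundancy([a], 40.0) == [a]

    def test_survivors_are_mutually_below_cutoff(self, small_world):
        cell = [d for d in small_world.domains if d.domain_id.startswith("d_0_0_")]
        kept = reduce_redundancy(cell, 40.0)
        for i, x in enumerate(kept):
            for y in kept[i + 1:]:
                aln = global_align(x.sequence, y.sequence)
                assert percent_identity(aln) < 40.0


class TestSelectMaster:
    def test_closest_to_mean_length(self):
        doms = [_dom("a", seq="A" * 50), _dom("b", seq="C" * 60),
                _dom("c", seq="D" * 100)]
        assert select_master(doms).domain_id == "b"

    def test_tie_prefers_shorter(self):
        doms = [_dom("a", seq="A" * 50), _dom("b", seq="C" * 90)]
        assert select_master(doms).domain_id == "a"

    def test_single(self):
        d = _dom("a")
        assert select_master([d]) is d


class TestPileup:
    def test_identical_domain_gives_identical_row(self):
        m = _dom("m", seq="ACD")
        aln = global_align("ACD", "ACD", id_a="m", id_b="x")
        msa = pileup(m, [aln])
        assert msa.rows == ["ACD", "ACD"]
        assert msa.discarded_insertions == {"x": 0}

    def test_insertion_relative_to_master_is_discarded_and_counted(self):
        m = _dom("m", seq="ACD")
        binary = PairwiseAlignment("m", "x", "A--CD", "AWYCD", 0.0)
        msa = pileup(m, [binary])
        assert msa.rows[1] == "ACD"
        assert msa.discarded_insertions == {"x": 2}

    def test_unmatched_master_position_projects_a_gap(self):
        m = _dom("m", seq="ACD")
        binary = PairwiseAlignment("m", "x", "ACD", "AC-", 0.0)
        msa = pileup(m, [binary])
        assert msa.rows[1] == "AC-"

    def test_alignment_not_involving_master_is_an_error(self):
        m = _dom("m", seq="ACD")
        binary = PairwiseAlignment("y", "x", "ACD", "ACD", 0.0)
        with pytest.raises(ValueError, match="does not involve"):
            pileup(m, [binary])

    def test_gap_stripped_rows_preserve_residue_order(self, small_library):
        lib, _ = small_library
        for entry in lib.entries:
            assert entry.alignment.master_row == next(
                r for i, r in zip(entry.alignment.row_ids, entry.alignment.rows)
                if i == entry.master_id
            )


class TestBuildLibrary:
    def test_cell_below_minimum_is_dropped_with_provenance(self, tiny_dag):
        a, b = _dom("a"), _dom("b")  # identical: 1 NR survivor < 3
        lib = build_library([a, b], [_chain(a), _chain(b)], tiny_dag,
                            LibraryParams(calibration_n_random=100))
        assert len(lib) == 0
        prov = lib.provenance["cells"]["fA|GO:0004721"]
        assert prov["initial"] == 2 and prov["after_nr"] == 1 and prov["kept"] == 0

    def test_empty_domain_list_gives_valid_empty_library(self, tiny_dag):
        lib = build_library([], [], tiny_dag, LibraryParams())
        assert len(lib) == 0

    def test_synthetic_cells_build_entries(self, small_library):
        lib, params = small_library
        assert len(lib) >= 1
        for e in lib.entries:
            assert len(e.member_ids) >= params.min_domains_per_entry
            assert e.pssm.n_columns == e.alignment.n_columns
            assert e.pssm.n_columns == len(e.alignment.master_row)

    def test_provenance_counts_non_increasing(self, small_library):
        lib, _ = small_library
        for prov in lib.provenance["cells"].values():
            assert prov["initial"] >= prov["after_nr"] >= prov["kept"]

    def test_deterministic_serialization(self, tmp_path, small_world):
        w = small_world
        params = LibraryParams(calibration_n_random=100, calibration_length=60)
        for sub in ("one", "two"):
            lib = build_library(w.domains, w.chains, w.dag, params, seed=7)
            save_library(lib, tmp_path / sub)
        files1 = sorted((tmp_path / "one").iterdir())
        files2 = sorted((tmp_path / "two").iterdir())
        assert [f.name for f in files1] == [f.name for f in files2]
        for f1, f2 in zip(files1, files2):
            assert f1.read_bytes() == f2.read_bytes()

    def test_save_load_roundtrip(self, tmp_path, small_library):
        lib, _ = small_library
        save_library(lib, tmp_path / "lib")
        again = load_library(tmp_path / "lib")
        assert len(again) == len(lib)
        for a, b in zip(lib.entries, again.entries):
            assert (a.fold_id, a.go_id, a.master_id) == (b.fold_id, b.go_id, b.master_id)
            assert a.member_ids == b.member_ids
            assert a.conserved == b.conserved
            assert a.alignment.rows == b.alignment.rows
            assert np.allclose(a.pssm.scores, b.pssm.scores, atol=0.005 + 1e-12)
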