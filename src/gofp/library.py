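"""Building the Fold x Function profile library.

Each library entry represents all (non-redundant) domain sequences known to
carry a given GO:MF term within a given structural fold.  The build
pipeline per (fold, term) cell is:

1. exclude multidomain-entry domains and domains of mutant /
   circular-permutation chains; drop terms too close to the ontology root;
2. reduce the cell to <40% mutual identity (greedy longest-first
   representative selection);
3. discard cells with fewer than 3 survivors;
4. pick the master: the domain whose length is closest to the cell's mean;
5. align every survivor to the master (binary alignments) and pile them up
   into a master-framed pseudo-multiple alignment, discarding insertions
   relative to the master;
6. build the PSSM, flag conserved columns, and calibrate E-value
   parameters for the entry.

Entry-level randomness (E-value calibration) is seeded from a stable hash
of the entry's membership, so rebuilding the library after removing
unrelated domains reproduces untouched entries bit-for-bit — which also
makes leave-cluster-out benchmark rebuilds cheap to cache.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np

from .alphabet import GAP, robinson_background
from .align import (
    DEFAULT_GAP_EXTEND,
    DEFAULT_GAP_OPEN,
    EvalueParams,
    PairwiseAlignment,
    calibrate_evalue,
    global_align,
    percent_identity,
)
from .annotation import ChainRecord, DomainRecord
from .ontology import GoDag
from .pssm import (
    MultipleAlignment,
    Pssm,
    build_pssm,
    conserved_columns,
    pssm_from_tsv,
    pssm_sidecar,
    pssm_to_tsv,
)

logger = logging.getLogger(__name__)

Aligner = Callable[..., PairwiseAlignment]


@dataclass(frozen=True)
class LibraryParams:
    """Knobs of the library build; defaults follow the method's protocol."""

    nr_identity_cutoff: float = 40.0      # percent; survivors are < cutoff
    min_domains_per_entry: int = 3
    min_term_depth: int = 3               # terms at depth <= 2 are never used
    conservation_threshold: float = 0.95
    beta: float = 5.0
    #: fixed effective observation count per PSSM column (puts entries of
    #: different sizes on one score scale); None = raw counts
    pssm_effective_count: float | None = 5.0
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND
    #: gap penalties for sequence-vs-profile alignment, on the PSSM's
    #: log2-odds (bit) scale; -5.5/-0.5 is the bit-unit equivalent of the
    #: -11/-1 convention on BLOSUM62's half-bit scale
    profile_gap_open: float = -5.5
    profile_gap_extend: float = -0.5
    calibration_n_random: int = 500
    calibration_length: int = 200

    def __post_init__(self) -> None:
        if not (0 < self.nr_identity_cutoff <= 100):
            raise ValueError("nr_identity_cutoff must be in (0, 100]")
        if self.min_domains_per_entry < 2:
            raise ValueError("min_domains_per_entry must be >= 2")

    def key(self) -> tuple:
        return tuple(sorted(asdict(self).items()))


@dataclass
class ProfileEntry:
    """One (fold, GO term) cell: alignment + PSSM + conserved columns."""

    fold_id: str
    go_id: str
    master_id: str
    alignment: MultipleAlignment
    pssm: Pssm
    conserved: set[int]
    evalue_params: EvalueParams
    member_ids: list[str]

    def __post_init__(self) -> None:
        if self.pssm.n_columns != self.alignment.n_columns:
            raise ValueError("PSSM column count differs from alignment width")


@dataclass
class ProfileLibrary:
    entries: list[ProfileEntry]
    params: LibraryParams
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(e.fold_id, e.go_id) for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (fold, go) entries in library")

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, fold_id: str, go_id: str) -> ProfileEntry | None:
        for e in self.entries:
            if e.fold_id == fold_id and e.go_id == go_id:
                return e
        return None


def build_matrix(
    domains: list[DomainRecord],
    chains: list[ChainRecord],
    dag: GoDag,
    params: LibraryParams,
) -> dict[tuple[str, str], list[DomainRecord]]:
    """Group eligible domains into (fold, GO term) cells.

    Excluded up front: multidomain-entry domains and domains of flagged
    chains.  Terms closer to the root than ``min_term_depth`` are dropped.
    A domain carrying k eligible terms joins k cells.
    """
    flagged_chains = {c.chain_id for c in chains if c.excluded}
    cells: dict[tuple[str, str], list[DomainRecord]] = {}
    depth_ok: dict[str, bool] = {}
    for d in domains:
        if d.is_multidomain_entry or d.chain_id in flagged_chains:
            continue
        for term in sorted(d.domain_go_ids):
            ok = depth_ok.get(term)
            if ok is None:
                if term not in dag:
                    logger.warning("term %s absent from ontology; skipped", term)
                    ok = False
                else:
                    ok = dag.distance_to_root(term) >= params.min_term_depth
                depth_ok[term] = ok
            if ok:
                cells.setdefault((d.fold_id, term), []).append(d)
    return cells


def reduce_redundancy(
    cell_domains: list[DomainRecord],
    cutoff: float = 40.0,
    aligner: Aligner = global_align,
) -> list[DomainRecord]:
    """Greedy longest-first representative selection at < ``cutoff`` % identity."""
    if not cell_domains:
        raise ValueError("empty cell")
    ordered = sorted(cell_domains, key=lambda d: (-len(d.sequence), d.domain_id))
    kept: list[DomainRecord] = []
    for cand in ordered:
        redundant = False
        for rep in kept:
            aln = aligner(rep.sequence, cand.sequence,
                          id_a=rep.domain_id, id_b=cand.domain_id)
            if percent_identity(aln) >= cutoff:
                redundant = True
                break
        if not redundant:
            kept.append(cand)
    return kept


def select_master(cell_domains: list[DomainRecord]) -> DomainRecord:
    """The domain whose length is closest to the cell's mean length.

    Ties broken towards the shorter domain, then ascending id.
    """
    if not cell_domains:
        raise ValueError("empty cell")
    mean_len = sum(len(d.sequence) for d in cell_domains) / len(cell_domains)
    return min(
        cell_domains,
        key=lambda d: (abs(len(d.sequence) - mean_len), len(d.sequence), d.domain_id),
    )


def pileup(
    master: DomainRecord,
    binary_alns: list[PairwiseAlignment],
) -> MultipleAlignment:
    """Pile binary master-vs-domain alignments into a master-framed MSA.

    Columns are exactly the master's residue positions.  Residues of a
    domain aligned to a master position land in that column; residues
    falling in insertions relative to the master are discarded and counted.
    """
    mseq = master.sequence.upper()
    n_cols = len(mseq)
    row_ids = [master.domain_id]
    rows = [mseq]
    discarded: dict[str, int] = {}
    for aln in binary_alns:
        if aln.id_a == master.domain_id:
            g_master, g_dom, dom_id = aln.gapped_a, aln.gapped_b, aln.id_b
        elif aln.id_b == master.domain_id:
            g_master, g_dom, dom_id = aln.gapped_b, aln.gapped_a, aln.id_a
        else:
            raise ValueError(
                f"binary alignment {aln.id_a}/{aln.id_b} does not involve "
                f"master {master.domain_id}"
            )
        if g_master.replace(GAP, "") != mseq:
            raise ValueError(
                f"master row of binary alignment {dom_id} does not match "
                f"the master sequence"
            )
        row = []
        dropped = 0
        for cm, cd in zip(g_master, g_dom):
            if cm == GAP:
                if cd != GAP:
                    dropped += 1  # insertion relative to the master
            else:
                row.append(cd)
        row_ids.append(dom_id)
        rows.append("".join(row))
        discarded[dom_id] = dropped
        assert len(rows[-1]) == n_cols
    return MultipleAlignment(
        master_id=master.domain_id,
        row_ids=row_ids,
        rows=rows,
        discarded_insertions=discarded,
    )


def _entry_seed(seed: int, fold_id: str, go_id: str, member_ids: list[str]) -> int:
    """Stable per-entry calibration seed, invariant across library rebuilds."""
    text = f"{seed}|{fold_id}|{go_id}|{','.join(sorted(member_ids))}"
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


def build_entry(
    fold_id: str,
    go_id: str,
    cell_domains: list[DomainRecord],
    params: LibraryParams,
    aligner: Aligner = global_align,
    background: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[ProfileEntry | None, dict]:
    """Run the per-cell pipeline; returns (entry or None, provenance counts)."""
    if background is None:
        background = robinson_background()
    prov = {"initial": len(cell_domains)}
    # redundancy is always judged on sequence identity (the equivalent of a
    # sequence-alignment identity filter); only the binary master
    # alignments fed to the pile-up come from the injectable aligner,
    # which may be structure-derived
    survivors = reduce_redundancy(cell_domains, params.nr_identity_cutoff)
    prov["after_nr"] = len(survivors)
    if len(survivors) < params.min_domains_per_entry:
        prov["kept"] = 0
        return None, prov
    master = select_master(survivors)
    binaries = [
        aligner(master.sequence, d.sequence,
                id_a=master.domain_id, id_b=d.domain_id)
        for d in survivors
        if d.domain_id != master.domain_id
    ]
    aln = pileup(master, binaries)
    pssm = build_pssm(aln, background=background, beta=params.beta,
                      effective_count=params.pssm_effective_count)
    conserved = conserved_columns(aln, params.conservation_threshold)
    member_ids = [d.domain_id for d in survivors]
    ev = calibrate_evalue(
        pssm,
        n_random=params.calibration_n_random,
        length=params.calibration_length,
        background=background,
        rng_seed=_entry_seed(seed, fold_id, go_id, member_ids),
        gap_open=params.profile_gap_open,
        gap_extend=params.profile_gap_extend,
    )
    entry = ProfileEntry(
        fold_id=fold_id,
        go_id=go_id,
        master_id=master.domain_id,
        alignment=aln,
        pssm=pssm,
        conserved=conserved,
        evalue_params=ev,
        member_ids=member_ids,
    )
    prov["kept"] = len(member_ids)
    return entry, prov


def build_library(
    domains: list[DomainRecord],
    chains: list[ChainRecord],
    dag: GoDag,
    params: LibraryParams | None = None,
    aligner: Aligner = global_align,
    background: np.ndarray | None = None,
    seed: int = 0,
    entry_cache: dict | None = None,
) -> ProfileLibrary:
    """Build the full library; per-cell failures are skipped with a warning.

    ``entry_cache`` (optional dict) memoises finished entries keyed by their
    cell membership, which makes leave-cluster-out rebuilds nearly free.
    """
    params = params or LibraryParams()
    cells = build_matrix(domains, chains, dag, params)
    entries: list[ProfileEntry] = []
    provenance: dict = {"n_domains": len(domains), "n_cells": len(cells), "cells": {}}
    for (fold_id, go_id) in sorted(cells):
        cell_domains = cells[(fold_id, go_id)]
        cache_key = None
        if entry_cache is not None:
            cache_key = (
                fold_id, go_id,
                tuple(sorted(d.domain_id for d in cell_domains)),
                params.key(), seed,
            )
            if cache_key in entry_cache:
                entry, prov = entry_cache[cache_key]
                provenance["cells"][f"{fold_id}|{go_id}"] = prov
                if entry is not None:
                    entries.append(entry)
                continue
        try:
            entry, prov = build_entry(
                fold_id, go_id, cell_domains, params,
                aligner=aligner, background=background, seed=seed,
            )
        except Exception as exc:  # never abort the whole build on one cell
            logger.warning("cell (%s, %s) skipped: %s", fold_id, go_id, exc)
            entry, prov = None, {"initial": len(cell_domains), "error": str(exc)}
        if entry_cache is not None:
            entry_cache[cache_key] = (entry, prov)
        provenance["cells"][f"{fold_id}|{go_id}"] = prov
        if entry is not None:
            entries.append(entry)
    provenance["n_entries"] = len(entries)
    if not entries:
        logger.warning("library is empty after filtering")
    return ProfileLibrary(entries=entries, params=params, provenance=provenance)


# ---------------------------------------------------------------------------
# serialization: a directory with a JSON manifest plus per-entry aligned
# FASTA and PSSM TSV/JSON sidecar
# ---------------------------------------------------------------------------

def save_library(library: ProfileLibrary, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = []
    for i, e in enumerate(library.entries):
        stem = f"entry_{i:04d}"
        index.append({
            "stem": stem,
            "fold_id": e.fold_id,
            "go_id": e.go_id,
            "master_id": e.master_id,
            "member_ids": e.member_ids,
            "conserved": sorted(e.conserved),
            "evalue_params": {
                "lambda_": e.evalue_params.lambda_,
                "k": e.evalue_params.k,
                "m": e.evalue_params.m,
                "n": e.evalue_params.n,
            },
            "discarded_insertions": e.alignment.discarded_insertions,
        })
        with open(out / f"{stem}.afa", "w") as fh:
            for rid, row in zip(e.alignment.row_ids, e.alignment.rows):
                fh.write(f">{rid}\n{row}\n")
        with open(out / f"{stem}.pssm.tsv", "w") as fh:
            fh.write(pssm_to_tsv(e.pssm))
        with open(out / f"{stem}.pssm.json", "w") as fh:
            fh.write(pssm_sidecar(
                e.pssm, master_id=e.master_id, fold_id=e.fold_id, go_id=e.go_id,
            ))
    manifest = {
        "params": asdict(library.params),
        "provenance": library.provenance,
        "entries": index,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def load_library(in_dir: str | Path) -> ProfileLibrary:
    src = Path(in_dir)
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    params = LibraryParams(**manifest["params"])
    entries = []
    for meta in manifest["entries"]:
        stem = meta["stem"]
        row_ids, rows = [], []
        with open(src / f"{stem}.afa") as fh:
            rid = None
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    rid = line[1:]
                    row_ids.append(rid)
                    rows.append("")
                elif line:
                    rows[-1] += line
        aln = MultipleAlignment(
            master_id=meta["master_id"],
            row_ids=row_ids,
            rows=rows,
            discarded_insertions=dict(meta["discarded_insertions"]),
        )
        pssm = pssm_from_tsv(
            (src / f"{stem}.pssm.tsv").read_text(),
            (src / f"{stem}.pssm.json").read_text(),
        )
        entries.append(ProfileEntry(
            fold_id=meta["fold_id"],
            go_id=meta["go_id"],
            master_id=meta["master_id"],
            alignment=aln,
            pssm=pssm,
            conserved=set(meta["conserved"]),
            evalue_params=EvalueParams(**meta["evalue_params"]),
            member_ids=list(meta["member_ids"]),
        ))
    return ProfileLibrary(
        entries=entries, params=params, provenance=manifest["provenance"]
    )
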