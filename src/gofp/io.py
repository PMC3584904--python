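"""Readers and writers for the on-disk formats.

Everything tabular is TSV with a header row; ``#``-prefixed comment lines
are allowed, unknown extra columns are accepted with a warning, UTF-8,
``\\n`` line endings.  Sequences travel as FASTA, the ontology as OBO 1.2.
All writers are deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from .annotation import ChainRecord, DomainRecord
from .library import LibraryParams
from .ontology import GoDag, parse_obo, write_obo
from .world import DomainTruth, SyntheticWorld

logger = logging.getLogger(__name__)

DOMAIN_COLUMNS = ["domain_id", "chain_id", "fold_id", "flags", "go_ids"]
CHAIN_COLUMNS = ["chain_id", "cluster_id", "flags", "go_ids"]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """FASTA records as (id, uppercased sequence); ids are the first
    whitespace token; duplicate ids and empty records are errors."""
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    rid = None
    chunks: list[str] = []

    def flush() -> None:
        if rid is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rid!r}")
        records.append((rid, seq))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                rid = line[1:].split()[0] if line[1:].split() else ""
                if not rid:
                    raise ValueError("FASTA record with an empty id")
                if rid in seen:
                    raise ValueError(f"duplicate FASTA id {rid!r}")
                seen.add(rid)
                chunks = []
            else:
                if rid is None:
                    raise ValueError("sequence data before the first FASTA header")
                chunks.append(line)
    flush()
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _read_tsv(path: str | Path, required: list[str]) -> list[dict[str, str]]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty table")
    header = lines[0].split("\t")
    missing = [c for c in required if c not in header]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    extra = [c for c in header if c not in required]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, extra)
    rows = []
    for ln in lines[1:]:
        vals = ln.split("\t")
        rows.append({h: (vals[i] if i < len(vals) else "") for i, h in enumerate(header)})
    return rows


def _split(field: str) -> list[str]:
    return [x for x in field.split(";") if x]


def read_domain_table(
    domains_tsv: str | Path,
    chains_tsv: str | Path,
    fasta: str | Path,
) -> tuple[list[DomainRecord], list[ChainRecord]]:
    """Parse the domain + chain tables and sequences, cross-validated.

    Chain membership and domain order come from the domain table's row
    order; every reference must resolve in both directions.
    """
    seqs = dict(read_fasta(fasta))
    domain_rows = _read_tsv(domains_tsv, DOMAIN_COLUMNS)
    chain_rows = _read_tsv(chains_tsv, CHAIN_COLUMNS)
    chain_meta = {r["chain_id"]: r for r in chain_rows}
    domains: list[DomainRecord] = []
    chain_domains: dict[str, list[str]] = {}
    dangling: list[str] = []
    for r in domain_rows:
        did = r["domain_id"]
        if did not in seqs:
            dangling.append(f"domain {did}: no sequence in FASTA")
            continue
        if r["chain_id"] not in chain_meta:
            dangling.append(f"domain {did}: unknown chain {r['chain_id']}")
            continue
        flags = set(_split(r["flags"]))
        domains.append(DomainRecord(
            domain_id=did,
            chain_id=r["chain_id"],
            fold_id=r["fold_id"],
            sequence=seqs[did],
            is_multidomain_entry="multidomain_entry" in flags,
            domain_go_ids=set(_split(r["go_ids"])),
        ))
        chain_domains.setdefault(r["chain_id"], []).append(did)
    for cid in chain_meta:
        if cid not in chain_domains:
            dangling.append(f"chain {cid}: no domains")
    if dangling:
        raise ValueError("inconsistent tables:\n  " + "\n  ".join(dangling))
    chains = [
        ChainRecord(
            chain_id=cid,
            domain_ids=chain_domains[cid],
            chain_go_ids=set(_split(chain_meta[cid]["go_ids"])),
            cluster_id=chain_meta[cid]["cluster_id"],
            flags=set(_split(chain_meta[cid]["flags"])),
        )
        for cid in (r["chain_id"] for r in chain_rows)
    ]
    return domains, chains


def read_annotation_table(path: str | Path) -> dict[str, set[str]]:
    """id -> set of GO ids (works for chain- or domain-level tables)."""
    rows = _read_tsv(path, ["id", "go_ids"])
    return {r["id"]: set(_split(r["go_ids"])) for r in rows}


def write_annotation_table(path: str | Path, annotations: dict[str, set[str]]) -> None:
    with open(path, "w") as fh:
        fh.write("id\tgo_ids\n")
        for key in sorted(annotations):
            fh.write(f"{key}\t{';'.join(sorted(annotations[key]))}\n")


def write_world(world: SyntheticWorld, out_dir: str | Path) -> None:
    """Write a synthetic world in the same dialects the real pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "domains.fasta",
                [(d.domain_id, d.sequence) for d in world.domains])
    with open(out / "domains.tsv", "w") as fh:
        fh.write("\t".join(DOMAIN_COLUMNS) + "\n")
        for d in world.domains:
            flags = "multidomain_entry" if d.is_multidomain_entry else ""
            fh.write("\t".join([
                d.domain_id, d.chain_id, d.fold_id, flags,
                ";".join(sorted(d.domain_go_ids)),
            ]) + "\n")
    with open(out / "chains.tsv", "w") as fh:
        fh.write("\t".join(CHAIN_COLUMNS) + "\n")
        for c in world.chains:
            fh.write("\t".join([
                c.chain_id, c.cluster_id, ";".join(sorted(c.flags)),
                ";".join(sorted(c.chain_go_ids)),
            ]) + "\n")
    with open(out / "ontology.obo", "w") as fh:
        fh.write(write_obo(world.dag.terms.values()))
    truth = {
        did: {
            "fold_id": t.fold_id,
            "go_ids": sorted(t.go_ids),
            "motif_positions": t.motif_positions,
            "ancestor_map": t.ancestor_map,
        }
        for did, t in sorted(world.truth.items())
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_world_dir(
    in_dir: str | Path,
) -> tuple[list[DomainRecord], list[ChainRecord], GoDag, dict[str, DomainTruth]]:
    src = Path(in_dir)
    domains, chains = read_domain_table(
        src / "domains.tsv", src / "chains.tsv", src / "domains.fasta"
    )
    dag = parse_obo((src / "ontology.obo").read_text())
    truth: dict[str, DomainTruth] = {}
    truth_path = src / "truth.json"
    if truth_path.exists():
        raw = json.loads(truth_path.read_text())
        truth = {
            did: DomainTruth(
                fold_id=t["fold_id"],
                go_ids=set(t["go_ids"]),
                motif_positions=list(t["motif_positions"]),
                ancestor_map=list(t.get("ancestor_map", [])),
            )
            for did, t in raw.items()
        }
    return domains, chains, dag, truth


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration echoed into every output directory."""

    library: LibraryParams
    seed: int = 0
    max_evalue: float = 10.0
    depths: tuple[int, ...] = (2, 4)
    verbosity: str = "info"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {"library", "seed", "max_evalue", "depths", "verbosity"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        lib = data.get("library", {})
        if isinstance(lib, dict):
            lib_unknown = set(lib) - set(asdict(LibraryParams()))
            if lib_unknown:
                raise ValueError(f"unknown library parameter(s): {sorted(lib_unknown)}")
            lib = LibraryParams(**lib)
        return cls(
            library=lib,
            seed=int(data.get("seed", 0)),
            max_evalue=float(data.get("max_evalue", 10.0)),
            depths=tuple(data.get("depths", (2, 4))),
            verbosity=str(data.get("verbosity", "info")),
        )

    def to_dict(self) -> dict:
        return {
            "library": asdict(self.library),
            "seed": self.seed,
            "max_evalue": self.max_evalue,
            "depths": list(self.depths),
            "verbosity": self.verbosity,
        }


def echo_config(out_dir: str | Path, config: RunConfig) -> None:
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"version": __version__, "config": config.to_dict()}
    with open(out / "config.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
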