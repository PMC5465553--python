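"""Reaction database: metabolites, reactions and enzyme sequences.

The database is a deliberately small, flat-file stand-in for a full
biochemical reaction resource: a metabolite table (id, name, carbon count),
a reaction table (id plus the set of participating metabolite ids) and an
enzyme FASTA whose description field cross-references the catalyzed
reactions (``reactions=R1;R2``).  Reactions are undirected: a reaction *is*
its metabolite set, because graph edges downstream are shared-metabolite
links with no notion of substrate versus product.

Currency metabolites — ubiquitous compounds such as water or ATP that would
stitch unrelated reactions together — are defined purely by occurrence: any
metabolite participating in at least ``cutoff`` reactions is currency.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Default ids for the butyrate -> butyryl-CoA host pseudo-reaction.
DEFAULT_BUTYRATE_ID = "BUTYRATE"
DEFAULT_BUTYRYL_COA_ID = "BUTYRYL_COA"
PSEUDO_REACTION_ID = "HOST_BUTYRATE_PSEUDO"


class DatabaseError(ValueError):
    """Raised for schema violations: dangling references, duplicates, etc."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str
    carbon_count: int
    #: number of distinct reactions containing this metabolite (computed)
    occurrence: int = 0

    def __post_init__(self) -> None:
        if self.carbon_count < 0:
            raise DatabaseError(f"negative carbon count for {self.id!r}")


@dataclass(frozen=True)
class Reaction:
    id: str
    metabolite_ids: frozenset[str]
    enzyme_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.metabolite_ids:
            raise DatabaseError(f"reaction {self.id!r} has no metabolites")


@dataclass(frozen=True)
class EnzymeSequence:
    id: str
    residues: str
    reaction_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.reaction_ids:
            raise DatabaseError(f"enzyme {self.id!r} lists no reactions")
        if len(self.residues) < 30:
            raise DatabaseError(
                f"enzyme {self.id!r} shorter than 30 residues ({len(self.residues)})"
            )
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise DatabaseError(
                f"enzyme {self.id!r} has non-amino-acid characters {sorted(bad)}"
            )


@dataclass
class ReactionDatabase:
    """Cross-referenced collection of metabolites, reactions and enzymes.

    Iteration order over all keyed collections is sorted by id so that every
    downstream computation is bit-reproducible.
    """

    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    enzymes: dict[str, EnzymeSequence]
    source_label: str = "microbial"

    def __post_init__(self) -> None:
        if self.source_label not in ("host", "microbial"):
            raise DatabaseError(f"unknown source label {self.source_label!r}")
        self.metabolites = dict(sorted(self.metabolites.items()))
        self.reactions = dict(sorted(self.reactions.items()))
        self.enzymes = dict(sorted(self.enzymes.items()))
        self._validate()
        self._recompute_occurrence()

    def _validate(self) -> None:
        for rxn in self.reactions.values():
            for mid in rxn.metabolite_ids:
                if mid not in self.metabolites:
                    raise DatabaseError(
                        f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                    )
            for eid in rxn.enzyme_ids:
                if eid not in self.enzymes:
                    raise DatabaseError(
                        f"reaction {rxn.id!r} references unknown enzyme {eid!r}"
                    )
        for enz in self.enzymes.values():
            for rid in enz.reaction_ids:
                if rid not in self.reactions:
                    raise DatabaseError(
                        f"enzyme {enz.id!r} references unknown reaction {rid!r}"
                    )

    def _recompute_occurrence(self) -> None:
        counts: dict[str, int] = {mid: 0 for mid in self.metabolites}
        for rxn in self.reactions.values():
            for mid in rxn.metabolite_ids:
                counts[mid] += 1
        self.metabolites = {
            mid: replace(met, occurrence=counts[mid])
            for mid, met in self.metabolites.items()
        }

    # -- convenience accessors -------------------------------------------------

    def reactions_of_enzyme(self, enzyme_id: str) -> frozenset[str]:
        return self.enzymes[enzyme_id].reaction_ids

    def carbon_sum(self, reaction_id: str) -> int:
        """Total carbon atoms over the reaction's metabolite set."""
        rxn = self.reactions[reaction_id]
        return sum(self.metabolites[m].carbon_count for m in rxn.metabolite_ids)


_HEADER_RE = re.compile(r"reactions=([^\s]+)")


def _read_tsv(path: Path, expected_cols: list[str]) -> list[list[str]]:
    lines = Path(path).read_text().rstrip("\n").split("\n")
    header = lines[0].split("\t")
    if header != expected_cols:
        raise DatabaseError(
            f"{path}: expected columns {expected_cols}, found {header}"
        )
    return [line.split("\t") for line in lines[1:] if line]


def load_database(
    metabolite_table_path: str | Path,
    reaction_table_path: str | Path,
    enzyme_fasta_path: str | Path,
    source_label: str = "microbial",
) -> ReactionDatabase:
    """Load and fully cross-reference a reaction database from flat files.

    Raises :class:`DatabaseError` naming the offending id on duplicates,
    dangling references or malformed records.
    """
    metabolites: dict[str, Metabolite] = {}
    for row in _read_tsv(Path(metabolite_table_path), ["metabolite_id", "name", "carbon_count"]):
        if len(row) != 3:
            raise DatabaseError(f"malformed metabolite row: {row!r}")
        mid, name, carbon = row
        if mid in metabolites:
            raise DatabaseError(f"duplicate metabolite id {mid!r}")
        metabolites[mid] = Metabolite(id=mid, name=name, carbon_count=int(carbon))

    reactions: dict[str, Reaction] = {}
    enzymes_of: dict[str, set[str]] = {}
    for row in _read_tsv(Path(reaction_table_path), ["reaction_id", "metabolite_ids"]):
        if len(row) != 2:
            raise DatabaseError(f"malformed reaction row: {row!r}")
        rid, mids = row
        if rid in reactions:
            raise DatabaseError(f"duplicate reaction id {rid!r}")
        reactions[rid] = Reaction(
            id=rid, metabolite_ids=frozenset(m for m in mids.split(";") if m)
        )
        enzymes_of[rid] = set()

    enzymes: dict[str, EnzymeSequence] = {}
    for record in SeqIO.parse(str(enzyme_fasta_path), "fasta"):
        if record.id in enzymes:
            raise DatabaseError(f"duplicate enzyme id {record.id!r}")
        m = _HEADER_RE.search(record.description)
        if not m:
            raise DatabaseError(
                f"enzyme {record.id!r} header lacks a reactions= field"
            )
        rids = frozenset(r for r in m.group(1).split(";") if r)
        enzymes[record.id] = EnzymeSequence(
            id=record.id, residues=str(record.seq).upper(), reaction_ids=rids
        )
        for rid in rids:
            if rid in enzymes_of:
                enzymes_of[rid].add(record.id)

    reactions = {
        rid: replace(rxn, enzyme_ids=frozenset(enzymes_of[rid]))
        for rid, rxn in reactions.items()
    }
    return ReactionDatabase(
        metabolites=metabolites,
        reactions=reactions,
        enzymes=enzymes,
        source_label=source_label,
    )


def write_database(db: ReactionDatabase, out_dir: str | Path) -> None:
    """Write the three flat files consumed by :func:`load_database`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "metabolites.tsv", "w") as fh:
        fh.write("metabolite_id\tname\tcarbon_count\n")
        for met in db.metabolites.values():
            fh.write(f"{met.id}\t{met.name}\t{met.carbon_count}\n")
    with open(out / "reactions.tsv", "w") as fh:
        fh.write("reaction_id\tmetabolite_ids\n")
        for rxn in db.reactions.values():
            fh.write(f"{rxn.id}\t{';'.join(sorted(rxn.metabolite_ids))}\n")
    records = [
        SeqRecord(
            Seq(enz.residues),
            id=enz.id,
            description=f"reactions={';'.join(sorted(enz.reaction_ids))}",
        )
        for enz in db.enzymes.values()
    ]
    SeqIO.write(records, str(out / "enzymes.fasta"), "fasta")


def load_database_dir(db_dir: str | Path, source_label: str = "microbial") -> ReactionDatabase:
    d = Path(db_dir)
    return load_database(
        d / "metabolites.tsv", d / "reactions.tsv", d / "enzymes.fasta", source_label
    )


def currency_metabolites(db: ReactionDatabase, cutoff: int) -> set[str]:
    """Metabolite ids occurring in ``cutoff`` **or more** reactions."""
    if cutoff < 1:
        raise ValueError("currency cutoff must be >= 1")
    return {mid for mid, met in db.metabolites.items() if met.occurrence >= cutoff}


def add_butyrate_pseudoreaction(
    host_db: ReactionDatabase,
    butyrate_id: str = DEFAULT_BUTYRATE_ID,
    butyryl_coa_id: str = DEFAULT_BUTYRYL_COA_ID,
) -> ReactionDatabase:
    """Return a host database with the butyrate -> butyryl-CoA pseudo-reaction.

    The ruminant host absorbs microbially produced butyrate and activates it
    to butyryl-CoA; adding this enzyme-free pseudo-reaction lets the host
    graph touch butyrate even when no annotated host reaction uses it.
    Idempotent: a second call changes nothing.
    """
    if host_db.source_label != "host":
        raise DatabaseError("pseudo-reaction belongs to the host database")
    target = frozenset({butyrate_id, butyryl_coa_id})
    for rxn in host_db.reactions.values():
        if rxn.metabolite_ids == target:
            return host_db
    metabolites = dict(host_db.metabolites)
    if butyrate_id not in metabolites:
        metabolites[butyrate_id] = Metabolite(butyrate_id, "butyrate", 4)
    if butyryl_coa_id not in metabolites:
        metabolites[butyryl_coa_id] = Metabolite(butyryl_coa_id, "butyryl-CoA", 25)
    reactions = dict(host_db.reactions)
    reactions[PSEUDO_REACTION_ID] = Reaction(
        id=PSEUDO_REACTION_ID, metabolite_ids=target
    )
    return ReactionDatabase(
        metabolites=metabolites,
        reactions=reactions,
        enzymes=dict(host_db.enzymes),
        source_label="host",
    )
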