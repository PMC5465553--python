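"""Translated-read mapping onto enzyme sequences.

Pipeline per read pair: quality truncation and pair-level filtering;
six-frame translation into maximal stop-free ORFs (both mates must carry an
ORF of at least 30 residues); seeded Smith-Waterman against the enzyme
database (a candidate must share two identical 7-residue words with the
query before alignment, then exceed 80% identity over more than 80% of the
ORF); and multi-hit resolution: hits whose reaction sets are identical or
nested are assigned to the node(s) of the minimal set, while hits to
unrelated reactions, or mates that disagree, discard the pair.

The aligner is an affine-gap local (Gotoh) dynamic program with
BLOSUM62 scoring, gap open 11 / extend 1; identity is computed over aligned
columns with gap columns counted as mismatches, and coverage is the
fraction of ORF residues inside the local alignment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .reaction_db import ReactionDatabase

# ---------------------------------------------------------------------------
# parameters and records

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM62.alphabet)
_CHAR_TO_IDX = {c: i for i, c in enumerate(_ALPHABET)}
_SCORE = np.asarray(_BLOSUM62, dtype=np.int32)


@dataclass(frozen=True)
class MappingParams:
    identity_threshold: float = 0.80
    coverage_threshold: float = 0.80
    word_length: int = 7
    required_words: int = 2
    min_orf_residues: int = 30
    trim_q: int = 15
    trim_run: int = 3
    min_mean_q: float = 25.0
    min_len_nt: int = 85
    gap_open: int = 11
    gap_extend: int = 1
    #: strict ">" thresholds (the printed ">80%" convention); False means ">="
    strict: bool = True

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "coverage_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("word_length", "required_words", "min_orf_residues",
                     "trim_run", "min_len_nt", "gap_open", "gap_extend"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    qual1: tuple[int, ...]
    seq2: str
    qual2: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"sequence/quality length mismatch in {self.read_id!r}")


@dataclass(frozen=True)
class Discarded:
    read_id: str
    reason: str  # quality | no_orf | no_hit | unrelated_multi | discordant_pair


@dataclass(frozen=True)
class TranslatedOrfPair:
    read_id: str
    orfs1: tuple[str, ...]
    orfs2: tuple[str, ...]


@dataclass(frozen=True)
class MappingHit:
    enzyme_id: str
    score: int
    identity: float
    coverage: float
    orf_index: int = 0


@dataclass(frozen=True)
class NodeAssignment:
    read_id: str
    status: str  # UNIQUE | MULTI | DISCARDED
    node_ids: frozenset[str] = frozenset()
    reason: str = ""


@dataclass
class MappingSummary:
    raw_pairs: int = 0
    valid_orf_pairs: int = 0
    node_hit_pairs: int = 0
    multi_pairs: int = 0
    discarded: Counter = field(default_factory=Counter)
    host_hit_pairs: int | None = None

    @property
    def node_hit_pct(self) -> float:
        return node_hit_percentage(self.node_hit_pairs, self.valid_orf_pairs)

    @property
    def host_hit_pct(self) -> float | None:
        if self.host_hit_pairs is None:
            return None
        return node_hit_percentage(self.host_hit_pairs, self.raw_pairs)


def node_hit_percentage(hits: int, denominator: int) -> float:
    """Percentage of mapped pairs, reported to two decimals."""
    if denominator <= 0:
        return 0.0
    return round(100.0 * hits / denominator, 2)


# ---------------------------------------------------------------------------
# quality filtering

def _truncate_low_quality(seq: str, qual: Sequence[int], p: MappingParams) -> tuple[str, tuple[int, ...]]:
    """Cut the read at the start of the first run of trim_run bases < trim_q."""
    run = 0
    for i, q in enumerate(qual):
        run = run + 1 if q < p.trim_q else 0
        if run == p.trim_run:
            cut = i - p.trim_run + 1
            return seq[:cut], tuple(qual[:cut])
    return seq, tuple(qual)


def quality_filter(pair: ReadPair, p: MappingParams) -> ReadPair | Discarded:
    """Truncate each mate at its first low-quality run, then filter the pair.

    The pair is discarded when either truncated mate is shorter than
    ``min_len_nt`` bases or has mean phred quality below ``min_mean_q``.
    """
    seq1, qual1 = _truncate_low_quality(pair.seq1, pair.qual1, p)
    seq2, qual2 = _truncate_low_quality(pair.seq2, pair.qual2, p)
    for seq, qual in ((seq1, qual1), (seq2, qual2)):
        if len(seq) < p.min_len_nt:
            return Discarded(pair.read_id, "quality")
        if sum(qual) / len(qual) < p.min_mean_q:
            return Discarded(pair.read_id, "quality")
    return ReadPair(pair.read_id, seq1, qual1, seq2, qual2)


# ---------------------------------------------------------------------------
# six-frame ORF extraction

def _frame_orfs(seq: str, p: MappingParams) -> list[str]:
    allowed = set("ACGTN")
    bad = set(seq.upper()) - allowed
    if bad:
        raise ValueError(f"non-ACGTN characters in read: {sorted(bad)}")
    orfs: list[str] = []
    s = Seq(seq.upper())
    for strand in (s, s.reverse_complement()):
        for frame in range(3):
            sub = strand[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) == 0:
                continue
            for piece in str(sub.translate()).split("*"):
                if len(piece) >= p.min_orf_residues:
                    orfs.append(piece)
    return orfs


def six_frame_orfs(pair: ReadPair, p: MappingParams) -> TranslatedOrfPair | Discarded:
    """All qualifying stop-free ORFs per mate; both mates must have one."""
    orfs1 = _frame_orfs(pair.seq1, p)
    orfs2 = _frame_orfs(pair.seq2, p)
    if not orfs1 or not orfs2:
        return Discarded(pair.read_id, "no_orf")
    return TranslatedOrfPair(pair.read_id, tuple(orfs1), tuple(orfs2))


# ---------------------------------------------------------------------------
# seeded Smith-Waterman

def _encode(peptide: str) -> np.ndarray:
    try:
        return np.fromiter((_CHAR_TO_IDX[c] for c in peptide), dtype=np.int32, count=len(peptide))
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"unknown residue {exc} in peptide") from exc


def kmer_set(peptide: str, k: int) -> set[str]:
    return {peptide[i: i + k] for i in range(len(peptide) - k + 1)}


def shares_seed_words(orf: str, enzyme: str, p: MappingParams) -> bool:
    """True when the two peptides share >= required_words distinct k-mers."""
    shared = kmer_set(orf, p.word_length) & kmer_set(enzyme, p.word_length)
    return len(shared) >= p.required_words


def smith_waterman(query: str, target: str, gap_open: int, gap_extend: int) -> tuple[int, float, float]:
    """Affine-gap local alignment (Gotoh) of two peptides.

    Returns ``(score, identity, coverage)`` where identity is the fraction
    of matching columns over all aligned columns (gap columns count as
    mismatches) and coverage the fraction of *query* residues inside the
    aligned region.  Ties in the traceback prefer diagonal, then a gap in
    the query, then a gap in the target; the start cell is the first
    (row-major) maximum.
    """
    q = _encode(query)
    t = _encode(target)
    m, n = len(q), len(t)
    NEG = -(10**9)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    # traceback codes: H -> 0 stop, 1 diag, 2 E, 3 F; E/F -> 1 open, 0 extend
    ptrH = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrE = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrF = np.zeros((m + 1, n + 1), dtype=np.int8)
    sub = _SCORE[q][:, t]  # m x n substitution scores

    for i in range(1, m + 1):
        Hi, Hprev = H[i], H[i - 1]
        Ei, Fi, Fprev = E[i], F[i], F[i - 1]
        subrow = sub[i - 1]
        for j in range(1, n + 1):
            e_open = Hi[j - 1] - gap_open
            e_ext = Ei[j - 1] - gap_extend
            if e_open >= e_ext:
                Ei[j] = e_open
                ptrE[i, j] = 1
            else:
                Ei[j] = e_ext
            f_open = Hprev[j] - gap_open
            f_ext = Fprev[j] - gap_extend
            if f_open >= f_ext:
                Fi[j] = f_open
                ptrF[i, j] = 1
            else:
                Fi[j] = f_ext
            diag = Hprev[j - 1] + subrow[j - 1]
            best, code = 0, 0
            if diag > best:
                best, code = diag, 1
            if Ei[j] > best:
                best, code = Ei[j], 2
            if Fi[j] > best:
                best, code = Fi[j], 3
            Hi[j] = best
            ptrH[i, j] = code

    flat = int(np.argmax(H))
    i, j = divmod(flat, n + 1)
    score = int(H[i, j])
    if score <= 0:
        return 0, 0.0, 0.0

    matches = columns = q_res = 0
    state = "H"
    while True:
        if state == "H":
            code = ptrH[i, j]
            if code == 0:
                break
            if code == 1:
                columns += 1
                q_res += 1
                if q[i - 1] == t[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif code == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in query, consume target residue
            columns += 1
            opened = ptrE[i, j]
            j -= 1
            if opened:
                state = "H"
        else:  # gap in target, consume query residue
            columns += 1
            q_res += 1
            opened = ptrF[i, j]
            i -= 1
            if opened:
                state = "H"
    identity = matches / columns if columns else 0.0
    coverage = q_res / m if m else 0.0
    return score, identity, coverage


def _passes(value: float, threshold: float, strict: bool) -> bool:
    return value > threshold if strict else value >= threshold


def align_orf(orf: str, enzyme_residues: str, p: MappingParams, *, skip_seed: bool = False) -> MappingHit | None:
    """Seeded local alignment of one ORF against one enzyme.

    A hit requires (i) two identical ``word_length``-mers shared anywhere,
    (ii) identity above the threshold, (iii) alignment coverage above the
    threshold of the ORF.  Returns ``None`` otherwise.
    """
    if len(orf) < p.min_orf_residues:
        raise ValueError(f"ORF shorter than {p.min_orf_residues} residues")
    if not skip_seed and not shares_seed_words(orf, enzyme_residues, p):
        return None
    score, identity, coverage = smith_waterman(orf, enzyme_residues, p.gap_open, p.gap_extend)
    if score <= 0:
        return None
    if not _passes(identity, p.identity_threshold, p.strict):
        return None
    if not _passes(coverage, p.coverage_threshold, p.strict):
        return None
    return MappingHit(enzyme_id="", score=score, identity=identity, coverage=coverage)


# ---------------------------------------------------------------------------
# database k-mer index

class EnzymeIndex:
    """Inverted 7-mer index over enzyme sequences for the seed screen."""

    def __init__(self, db: ReactionDatabase, p: MappingParams):
        self.db = db
        self.params = p
        self._kmers: dict[str, EnzymeKmers] = {}
        self._index: dict[str, set[str]] = {}
        for eid, enz in db.enzymes.items():
            ks = kmer_set(enz.residues, p.word_length)
            self._kmers[eid] = ks
            for kmer in ks:
                self._index.setdefault(kmer, set()).add(eid)

    def candidates(self, orf: str, exclude: str | None = None) -> list[str]:
        """Enzyme ids sharing >= required_words distinct words with the ORF."""
        counts: Counter[str] = Counter()
        for kmer in kmer_set(orf, self.params.word_length):
            for eid in self._index.get(kmer, ()):
                counts[eid] += 1
        return sorted(
            eid
            for eid, c in counts.items()
            if c >= self.params.required_words and eid != exclude
        )

    def hits_for_orf(self, orf: str, orf_index: int = 0, exclude: str | None = None) -> list[MappingHit]:
        hits = []
        for eid in self.candidates(orf, exclude=exclude):
            hit = align_orf(orf, self.db.enzymes[eid].residues, self.params, skip_seed=True)
            if hit is not None:
                hits.append(replace(hit, enzyme_id=eid, orf_index=orf_index))
        return hits


EnzymeKmers = set  # alias for readability above


# ---------------------------------------------------------------------------
# multi-hit resolution

def _best_orf_hits(hits: Iterable[MappingHit]) -> list[MappingHit]:
    """Keep the hits of the single best-scoring ORF for one mate.

    The winning ORF is the one carrying the top-scoring hit; score ties
    break toward the lower ORF index, then the lexicographically smaller
    enzyme id.
    """
    hits = list(hits)
    if not hits:
        return []
    best = min(hits, key=lambda h: (-h.score, h.orf_index, h.enzyme_id))
    return [h for h in hits if h.orf_index == best.orf_index]


def resolve_assignment(
    read_id: str,
    hits_mate1: Sequence[MappingHit],
    hits_mate2: Sequence[MappingHit],
    enzyme_reactions: Mapping[str, frozenset],
    reaction_to_node: Mapping[str, str] | None = None,
) -> NodeAssignment:
    """Resolve per-mate enzyme hits into a node assignment.

    The reaction sets of all hit enzymes must be identical or totally
    ordered by inclusion; the pair is then assigned to the node(s) of the
    minimal set (UNIQUE when that is a single node, MULTI otherwise).
    Mates with no common reaction discard the pair as ``discordant_pair``;
    incomparable reaction sets discard it as ``unrelated_multi``.
    """
    kept1 = _best_orf_hits(hits_mate1)
    kept2 = _best_orf_hits(hits_mate2)
    if not kept1 or not kept2:
        return NodeAssignment(read_id, "DISCARDED", reason="no_hit")

    sets1 = {frozenset(enzyme_reactions[h.enzyme_id]) for h in kept1}
    sets2 = {frozenset(enzyme_reactions[h.enzyme_id]) for h in kept2}
    union1 = frozenset().union(*sets1)
    union2 = frozenset().union(*sets2)
    if not union1 & union2:
        return NodeAssignment(read_id, "DISCARDED", reason="discordant_pair")

    chain = sorted(sets1 | sets2, key=len)
    for small, big in zip(chain, chain[1:]):
        if not small <= big:
            return NodeAssignment(read_id, "DISCARDED", reason="unrelated_multi")

    minimal = chain[0]
    if reaction_to_node is None:
        node_ids = frozenset(minimal)
    else:
        node_ids = frozenset(
            reaction_to_node[r] for r in minimal if r in reaction_to_node
        )
        if not node_ids:
            return NodeAssignment(read_id, "DISCARDED", reason="no_hit")
    status = "UNIQUE" if len(node_ids) == 1 else "MULTI"
    return NodeAssignment(read_id, status, node_ids=node_ids)


# ---------------------------------------------------------------------------
# whole-sample mapping

def iter_read_pairs(fastq1: str | Path, fastq2: str | Path) -> Iterator[ReadPair]:
    it1 = SeqIO.parse(str(fastq1), "fastq")
    it2 = SeqIO.parse(str(fastq2), "fastq")
    for rec1, rec2 in zip(it1, it2, strict=True):
        yield ReadPair(
            read_id=rec1.id,
            seq1=str(rec1.seq),
            qual1=tuple(rec1.letter_annotations["phred_quality"]),
            seq2=str(rec2.seq),
            qual2=tuple(rec2.letter_annotations["phred_quality"]),
        )


def map_read_pair(
    pair: ReadPair, index: EnzymeIndex, p: MappingParams,
    reaction_to_node: Mapping[str, str] | None = None,
) -> NodeAssignment:
    filtered = quality_filter(pair, p)
    if isinstance(filtered, Discarded):
        return NodeAssignment(pair.read_id, "DISCARDED", reason=filtered.reason)
    orfs = six_frame_orfs(filtered, p)
    if isinstance(orfs, Discarded):
        return NodeAssignment(pair.read_id, "DISCARDED", reason=orfs.reason)
    hits1 = [h for i, orf in enumerate(orfs.orfs1) for h in index.hits_for_orf(orf, i)]
    hits2 = [h for i, orf in enumerate(orfs.orfs2) for h in index.hits_for_orf(orf, i)]
    enzyme_reactions = {eid: index.db.enzymes[eid].reaction_ids for eid in
                        {h.enzyme_id for h in hits1 + hits2}}
    return resolve_assignment(pair.read_id, hits1, hits2, enzyme_reactions, reaction_to_node)


def map_sample(
    fastq1: str | Path,
    fastq2: str | Path,
    db: ReactionDatabase,
    p: MappingParams | None = None,
    reaction_to_node: Mapping[str, str] | None = None,
    host_hit_pairs: int | None = None,
) -> tuple[dict[str, int], MappingSummary]:
    """Map one animal's paired FASTQ to per-node unique read counts.

    Returns the per-node count column (UNIQUE assignments only) and a
    summary with the totals behind the per-sample read-statistics table:
    raw pairs, pairs with valid ORFs in both mates, node-hit pairs with
    their percentage of valid pairs, and separately tallied multi-node
    pairs.  ``host_hit_pairs`` is a precomputed host-genome contamination
    count carried through from sample metadata.
    """
    p = p or MappingParams()
    index = EnzymeIndex(db, p)
    counts: Counter[str] = Counter()
    summary = MappingSummary(host_hit_pairs=host_hit_pairs)
    for pair in iter_read_pairs(fastq1, fastq2):
        summary.raw_pairs += 1
        assignment = map_read_pair(pair, index, p, reaction_to_node)
        if assignment.status == "DISCARDED" and assignment.reason in ("quality", "no_orf"):
            summary.discarded[assignment.reason] += 1
            continue
        summary.valid_orf_pairs += 1
        if assignment.status == "UNIQUE":
            summary.node_hit_pairs += 1
            counts[next(iter(assignment.node_ids))] += 1
        elif assignment.status == "MULTI":
            summary.multi_pairs += 1
        else:
            summary.discarded[assignment.reason] += 1
    return dict(sorted(counts.items())), summary


# ---------------------------------------------------------------------------
# pseudo-read validation

@dataclass(frozen=True)
class PseudoReadPair:
    pair_id: str
    source_enzyme_id: str
    offset: int
    segment1: str
    segment2: str


def generate_pseudo_reads(
    db: ReactionDatabase,
    n_pairs: int = 20000,
    segment_len: int = 30,
    insert_len: int = 70,
    seed: int = 0,
) -> list[PseudoReadPair]:
    """Draw peptide read pairs directly from enzyme sequences.

    Each pair is two ``segment_len``-residue windows from one enzyme
    separated by an unsequenced insert of exactly ``insert_len`` residues;
    sampling is uniform over all valid (enzyme, offset) positions.
    """
    span = 2 * segment_len + insert_len
    positions: list[tuple[str, int]] = []
    for eid, enz in db.enzymes.items():
        for offset in range(len(enz.residues) - span + 1):
            positions.append((eid, offset))
    if not positions:
        raise ValueError(f"no enzyme of length >= {span} residues in the database")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(positions), size=n_pairs)
    pairs = []
    for i, k in enumerate(picks):
        eid, off = positions[int(k)]
        res = db.enzymes[eid].residues
        pairs.append(
            PseudoReadPair(
                pair_id=f"pseudo_{i}",
                source_enzyme_id=eid,
                offset=off,
                segment1=res[off: off + segment_len],
                segment2=res[off + segment_len + insert_len: off + span],
            )
        )
    return pairs


def validate_mapping(
    pseudo_reads: Sequence[PseudoReadPair],
    db: ReactionDatabase,
    identity_grid: Sequence[float] = (0.95, 0.90, 0.85, 0.80),
    p: MappingParams | None = None,
) -> list[dict]:
    """Map pseudo-reads back to the database, source enzyme withheld.

    For each identity threshold the report gives the fraction of pairs
    mapped at all, the unique:multi ratio, and the fraction of mapped pairs
    assigned only to reactions foreign to the source enzyme (incorrect
    nodes).  Alignments are computed once; thresholds are applied post hoc.
    """
    p = p or MappingParams()
    index = EnzymeIndex(db, p)
    loose = replace(p, identity_threshold=min(identity_grid))

    cached: list[tuple[PseudoReadPair, list[MappingHit], list[MappingHit]]] = []
    for pr in pseudo_reads:
        hits1, hits2 = [], []
        for segment, bucket in ((pr.segment1, hits1), (pr.segment2, hits2)):
            for eid in index.candidates(segment, exclude=pr.source_enzyme_id):
                hit = align_orf(segment, db.enzymes[eid].residues, loose, skip_seed=True)
                if hit is not None:
                    bucket.append(replace(hit, enzyme_id=eid))
        cached.append((pr, hits1, hits2))

    rows = []
    for threshold in identity_grid:
        n_unique = n_multi = n_incorrect = 0
        for pr, hits1, hits2 in cached:
            keep1 = [h for h in hits1 if _passes(h.identity, threshold, p.strict)]
            keep2 = [h for h in hits2 if _passes(h.identity, threshold, p.strict)]
            enzyme_reactions = {
                h.enzyme_id: db.enzymes[h.enzyme_id].reaction_ids
                for h in keep1 + keep2
            }
            assignment = resolve_assignment(pr.pair_id, keep1, keep2, enzyme_reactions)
            if assignment.status == "UNIQUE":
                n_unique += 1
            elif assignment.status == "MULTI":
                n_multi += 1
            else:
                continue
            source_rxns = db.enzymes[pr.source_enzyme_id].reaction_ids
            if not assignment.node_ids & source_rxns:
                n_incorrect += 1
        n_mapped = n_unique + n_multi
        rows.append(
            {
                "identity_threshold": threshold,
                "frac_mapped": n_mapped / len(pseudo_reads) if pseudo_reads else 0.0,
                "n_unique": n_unique,
                "n_multi": n_multi,
                "unique_multi_ratio": n_unique / n_multi if n_multi else float("inf"),
                "frac_incorrect": n_incorrect / n_mapped if n_mapped else 0.0,
            }
        )
    return rows
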