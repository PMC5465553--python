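"""Quality filtering, ORF extraction, seeded alignment and hit resolution."""

import numpy as np
import pytest

from rumennet.read_mapping import (
    Discarded,
    EnzymeIndex,
    MappingHit,
    MappingParams,
    ReadPair,
    align_orf,
    generate_pseudo_reads,
    map_sample,
    node_hit_percentage,
    quality_filter,
    resolve_assignment,
    six_frame_orfs,
    smith_waterman,
    validate_mapping,
)
from rumennet.reaction_db import EnzymeSequence, Metabolite, Reaction, ReactionDatabase
from rumennet.synthetic import RESIDUES, ScenarioConfig, back_translate, gen_reads

from .conftest import random_peptide
from .sw_oracle import oracle_align

P = MappingParams()


def _pair(seq1, qual1, seq2=None, qual2=None, rid="r1"):
    seq2 = seq2 if seq2 is not None else seq1
    qual2 = qual2 if qual2 is not None else qual1
    return ReadPair(rid, seq1, tuple(qual1), seq2, tuple(qual2))


# ---------------------------------------------------------------------------
# quality filtering

def test_high_quality_read_is_unchanged():
    pair = _pair("A" * 100, [40] * 100)
    out = quality_filter(pair, P)
    assert isinstance(out, ReadPair) and out.seq1 == "A" * 100


def test_truncation_at_first_low_quality_run_keeps_pair():
    qual = [40] * 89 + [14, 14, 14] + [40] * 8
    out = quality_filter(_pair("A" * 100, qual), P)
    assert isinstance(out, ReadPair)
    assert len(out.seq1) == 89


def test_truncation_below_length_floor_discards_pair():
    qual = [40] * 80 + [14, 14, 14] + [40] * 17
    out = quality_filter(_pair("A" * 100, qual), P)
    assert isinstance(out, Discarded) and out.reason == "quality"


def test_low_mean_quality_discards_pair():
    out = quality_filter(_pair("A" * 100, [24] * 100), P)
    assert isinstance(out, Discarded) and out.reason == "quality"


# ---------------------------------------------------------------------------
# ORF extraction

def test_stop_free_100nt_read_yields_33_residue_orf():
    rng = np.random.default_rng(0)
    nt = back_translate(random_peptide(rng, 33), rng) + "A"
    out = six_frame_orfs(_pair(nt, [40] * 100), P)
    assert not isinstance(out, Discarded)
    assert max(len(o) for o in out.orfs1) == 33


def test_short_orfs_on_both_mates_discard_pair():
    # 87 nt caps every frame at 29 residues
    out = six_frame_orfs(_pair("A" * 87, [40] * 87), P)
    assert isinstance(out, Discarded) and out.reason == "no_orf"


def test_one_failing_mate_discards_pair():
    rng = np.random.default_rng(1)
    good = back_translate(random_peptide(rng, 33), rng) + "A"
    out = six_frame_orfs(_pair(good, [40] * 100, "A" * 87, [40] * 87), P)
    assert isinstance(out, Discarded) and out.reason == "no_orf"


def test_invalid_nucleotides_raise():
    with pytest.raises(ValueError, match="non-ACGTN"):
        six_frame_orfs(_pair("A" * 99 + "X", [40] * 100), P)


# ---------------------------------------------------------------------------
# seeded alignment

def test_exact_substring_hit_has_unit_identity_and_coverage():
    rng = np.random.default_rng(2)
    enzyme = random_peptide(rng, 120)
    orf = enzyme[40:73]
    hit = align_orf(orf, enzyme, P)
    assert hit is not None
    assert hit.identity == 1.0 and hit.coverage == 1.0


def test_single_shared_word_fails_seed_screen():
    rng = np.random.default_rng(3)
    enzyme = random_peptide(rng, 120)
    # one planted 7-mer, remainder guaranteed dissimilar (disjoint alphabets)
    orf = "".join(rng.choice(list("ACDEF"), size=30)) + enzyme[50:57]
    enzyme = enzyme[:30].replace("A", "K") + "".join(
        rng.choice(list("KLMNP"), size=20)
    ) + enzyme[50:]
    assert align_orf(orf, enzyme, P) is None


def test_clustered_substitutions_fall_below_thresholds():
    rng = np.random.default_rng(4)
    enzyme = random_peptide(rng, 150)
    orf = list(enzyme[60:93])
    for i in range(8):  # corrupt one flank; 25-residue run keeps the seeds
        orf[i] = "W" if orf[i] != "W" else "Y"
    orf = "".join(orf)
    assert align_orf(orf, enzyme, P) is None
    score, identity, coverage = smith_waterman(orf, enzyme, P.gap_open, P.gap_extend)
    assert (score, identity, coverage) == oracle_align(orf, enzyme)


def test_aligner_matches_independent_oracle_on_random_pairs():
    rng = np.random.default_rng(5)
    for trial in range(60):
        a = random_peptide(rng, int(rng.integers(30, 61)))
        b = random_peptide(rng, int(rng.integers(30, 61)))
        if trial % 3 == 0:  # plant overlap so positive scores occur
            b = b[:10] + a[5:25] + b[30:]
        assert smith_waterman(a, b, 11, 1) == oracle_align(a, b)


# ---------------------------------------------------------------------------
# hit resolution

def _hits(*enzyme_ids, score=100):
    return [MappingHit(e, score, 0.9, 0.9) for e in enzyme_ids]


def test_same_reaction_enzymes_resolve_unique():
    rxns = {"Ea": frozenset({"R1"}), "Eb": frozenset({"R1"})}
    a = resolve_assignment("r", _hits("Ea", "Eb"), _hits("Ea", "Eb"), rxns)
    assert a.status == "UNIQUE" and a.node_ids == {"R1"}


def test_subset_reaction_sets_resolve_to_minimal():
    rxns = {"Ea": frozenset({"R1", "R2"}), "Eb": frozenset({"R1"})}
    a = resolve_assignment("r", _hits("Ea"), _hits("Eb"), rxns)
    assert a.status == "UNIQUE" and a.node_ids == {"R1"}


def test_minimal_set_of_two_reactions_is_multi():
    rxns = {"Ea": frozenset({"R1", "R2"})}
    a = resolve_assignment("r", _hits("Ea"), _hits("Ea"), rxns)
    assert a.status == "MULTI" and a.node_ids == {"R1", "R2"}


def test_discordant_mates_are_discarded():
    rxns = {"Ea": frozenset({"R1"}), "Eb": frozenset({"R3"})}
    a = resolve_assignment("r", _hits("Ea"), _hits("Eb"), rxns)
    assert a.status == "DISCARDED" and a.reason == "discordant_pair"


def test_incomparable_sets_are_unrelated_multi():
    rxns = {"Ea": frozenset({"R1", "R2"}), "Eb": frozenset({"R1", "R3"})}
    a = resolve_assignment("r", _hits("Ea", "Eb"), _hits("Ea"), rxns)
    assert a.status == "DISCARDED" and a.reason == "unrelated_multi"


# ---------------------------------------------------------------------------
# sample mapping and the summary arithmetic

@pytest.mark.parametrize(
    "hits,denom,pct",
    [
        (271571, 14521805, 1.87),
        (761728, 30282660, 2.52),
        (1175563, 47234706, 2.49),
    ],
)
def test_summary_percentage_arithmetic(hits, denom, pct):
    assert node_hit_percentage(hits, denom) == pct


def test_map_sample_conserves_pairs_and_recovers_truth(tmp_path, tiny_db):
    cfg = ScenarioConfig(
        n_animals_per_diet=1, fastq_pairs_per_animal=40, substitution_rate=0.0, seed=9
    )
    truth = gen_reads(tiny_db, cfg, tmp_path, n_pairs=40)
    counts, summary = map_sample(
        tmp_path / "F01_1.fastq", tmp_path / "F01_2.fastq", tiny_db
    )
    assert summary.raw_pairs == 40
    accounted = (
        summary.node_hit_pairs
        + summary.multi_pairs
        + sum(summary.discarded.values())
    )
    assert accounted == summary.raw_pairs
    # every unique assignment agrees with the truth table
    truth_f = truth[truth.animal == "F01"].set_index("read_id")
    assert summary.node_hit_pairs + summary.multi_pairs == 40
    total_assigned = sum(counts.values())
    assert total_assigned == summary.node_hit_pairs


def test_empty_fastq_yields_zero_summary(tmp_path, tiny_db):
    (tmp_path / "e_1.fastq").write_text("")
    (tmp_path / "e_2.fastq").write_text("")
    counts, summary = map_sample(tmp_path / "e_1.fastq", tmp_path / "e_2.fastq", tiny_db)
    assert counts == {} and summary.raw_pairs == 0
    assert summary.node_hit_pct == 0.0


# ---------------------------------------------------------------------------
# pseudo-read validation

def test_pseudo_read_geometry():
    rng = np.random.default_rng(6)
    residues = random_peptide(rng, 130)
    db = ReactionDatabase(
        {"A": Metabolite("A", "a", 1)},
        {"R1": Reaction("R1", frozenset({"A"}), frozenset({"E1"}))},
        {"E1": EnzymeSequence("E1", residues, frozenset({"R1"}))},
        "microbial",
    )
    pairs = generate_pseudo_reads(db, n_pairs=5, seed=0)
    assert len(pairs) == 5
    for pr in pairs:
        assert pr.offset == 0  # 130 = 30 + 70 + 30 leaves a single position
        assert pr.segment1 == residues[:30]
        assert pr.segment2 == residues[100:130]


def test_unmutated_pseudo_reads_map_to_source_when_retained(tiny_db):
    pairs = generate_pseudo_reads(tiny_db, n_pairs=20, seed=1)
    index = EnzymeIndex(tiny_db, P)
    for pr in pairs:
        hits1 = index.hits_for_orf(pr.segment1)
        hits2 = index.hits_for_orf(pr.segment2)
        rxns = {h.enzyme_id: tiny_db.enzymes[h.enzyme_id].reaction_ids
                for h in hits1 + hits2}
        a = resolve_assignment(pr.pair_id, hits1, hits2, rxns)
        assert a.status in ("UNIQUE", "MULTI")
        assert a.node_ids & tiny_db.enzymes[pr.source_enzyme_id].reaction_ids


def test_dissimilar_database_maps_nothing_with_source_withheld(tiny_db):
    pairs = generate_pseudo_reads(tiny_db, n_pairs=30, seed=2)
    report = validate_mapping(pairs, tiny_db, identity_grid=(0.80,))
    assert report[0]["frac_mapped"] == 0.0


def test_duplicate_of_source_still_maps_correctly():
    rng = np.random.default_rng(7)
    residues = random_peptide(rng, 200)
    mets = {"A": Metabolite("A", "a", 1)}
    rxns = {"R1": Reaction("R1", frozenset({"A"}), frozenset({"E1", "E2"}))}
    enzymes = {
        "E1": EnzymeSequence("E1", residues, frozenset({"R1"})),
        "E2": EnzymeSequence("E2", residues, frozenset({"R1"})),
    }
    db = ReactionDatabase(mets, rxns, enzymes, "microbial")
    pairs = [p for p in generate_pseudo_reads(db, 10, seed=3) if p.source_enzyme_id == "E1"]
    report = validate_mapping(pairs, db, identity_grid=(0.80,))
    assert report[0]["frac_mapped"] == 1.0
    assert report[0]["frac_incorrect"] == 0.0


def _block_mutated(residues: str, intact: int, mutated: int, rng) -> str:
    """Mutate ``mutated`` residues after every ``intact`` intact ones,
    leaving runs long enough to keep 7-mer seeds alive."""
    out = list(residues)
    alphabet = list(RESIDUES)
    period = intact + mutated
    for start in range(intact, len(out), period):
        for i in range(start, min(start + mutated, len(out))):
            choices = [c for c in alphabet if c != out[i]]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def test_incorrect_node_fraction_decreases_toward_threshold_080():
    """High identity cutoffs hide reaction ambiguity: reads then map
    uniquely to the nearest (wrong-reaction) homolog, while at 0.80 the
    competing correct-reaction homolog re-enters and the ambiguity is
    caught."""
    rng = np.random.default_rng(8)
    source = random_peptide(rng, 240)
    near_wrong = _block_mutated(source, 13, 2, rng)  # ~87% identity, wrong rxn
    far_right = _block_mutated(source, 12, 3, rng)   # ~80% identity, right rxn
    mets = {"A": Metabolite("A", "a", 1), "B": Metabolite("B", "b", 1)}
    rxns = {
        "RS": Reaction("RS", frozenset({"A"}), frozenset({"ES", "EC"})),
        "RX": Reaction("RX", frozenset({"B"}), frozenset({"EW"})),
    }
    enzymes = {
        "ES": EnzymeSequence("ES", source, frozenset({"RS"})),
        "EW": EnzymeSequence("EW", near_wrong, frozenset({"RX"})),
        "EC": EnzymeSequence("EC", far_right, frozenset({"RS"})),
    }
    db = ReactionDatabase(mets, rxns, enzymes, "microbial")
    pairs = [p for p in generate_pseudo_reads(db, 60, seed=4) if p.source_enzyme_id == "ES"]
    report = {
        row["identity_threshold"]: row
        for row in validate_mapping(pairs, db, identity_grid=(0.84, 0.78))
    }
    assert report[0.84]["frac_mapped"] > 0
    assert report[0.84]["frac_incorrect"] > report[0.78]["frac_incorrect"]


def test_lower_identity_threshold_never_maps_fewer_pairs(tiny_db, small_study):
    microbial, _, _, _, _ = small_study
    pairs = generate_pseudo_reads(microbial, n_pairs=20, seed=5)
    report = validate_mapping(pairs, microbial, identity_grid=(0.95, 0.85, 0.75, 0.60))
    fractions = [row["frac_mapped"] for row in report]
    assert fractions == sorted(fractions)
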