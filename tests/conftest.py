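"""Shared fixtures: a tiny hand-built database and a small synthetic study."""

from __future__ import annotations

import numpy as np
import pytest

from rumennet.network_build import build_graph, make_interface_set, merge_networks
from rumennet.reaction_db import (
    EnzymeSequence,
    Metabolite,
    Reaction,
    ReactionDatabase,
    add_butyrate_pseudoreaction,
)
from rumennet.synthetic import RESIDUES, ScenarioConfig, gen_count_matrix, gen_reaction_db


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RESIDUES), size=length))


@pytest.fixture(scope="session")
def tiny_db() -> ReactionDatabase:
    """Four-reaction microbial database with controlled enzyme sequences."""
    rng = np.random.default_rng(42)
    mets = {
        "A": Metabolite("A", "met A", 3),
        "B": Metabolite("B", "met B", 5),
        "C": Metabolite("C", "met C", 2),
        "D": Metabolite("D", "met D", 6),
        "E": Metabolite("E", "met E", 1),
    }
    rxns = {
        "R1": Reaction("R1", frozenset({"A", "B"}), frozenset({"E1", "E12"})),
        "R2": Reaction("R2", frozenset({"B", "C"}), frozenset({"E2", "E12"})),
        "R3": Reaction("R3", frozenset({"C", "D"}), frozenset({"E3"})),
        "R4": Reaction("R4", frozenset({"D", "E"}), frozenset({"E4"})),
    }
    enzymes = {
        "E1": EnzymeSequence("E1", random_peptide(rng, 200), frozenset({"R1"})),
        "E2": EnzymeSequence("E2", random_peptide(rng, 180), frozenset({"R2"})),
        "E3": EnzymeSequence("E3", random_peptide(rng, 160), frozenset({"R3"})),
        "E4": EnzymeSequence("E4", random_peptide(rng, 220), frozenset({"R4"})),
        "E12": EnzymeSequence("E12", random_peptide(rng, 150), frozenset({"R1", "R2"})),
    }
    return ReactionDatabase(mets, rxns, enzymes, "microbial")


@pytest.fixture(scope="session")
def small_scenario() -> ScenarioConfig:
    return ScenarioConfig(
        n_metabolites=150,
        n_microbial_reactions=200,
        n_host_reactions=40,
        reads_per_animal=20000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_scenario):
    """(microbial db, host db, merged network, count matrix, OTU table)."""
    microbial, host = gen_reaction_db(small_scenario)
    host = add_butyrate_pseudoreaction(host)
    merged = merge_networks(
        build_graph(host, 50),
        build_graph(microbial, 50),
        make_interface_set("VFA_AA"),
    )
    cm, otus = gen_count_matrix(merged, small_scenario)
    return microbial, host, merged, cm, otus
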