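"""Synthetic study generator: reaction databases, reads and count matrices.

Emulates the statistical structure of a two-diet rumen metagenome study so
the whole pipeline runs without downloads: eight forage-fed (FORG) and
eight concentrate-fed (CONC) animals; per-node read densities following
the zero / one / log-normal three-state mixture; a diet effect that tilts
CONC reads toward low-layer, high-centrality nodes; larger animal-to-animal
dispersion under CONC; and three "high-RFI-like" CONC animals sharing a
degenerate profile dominated by a few nodes.  Nothing here mimics real
rumen taxa or real reaction-database content — ids and sequences are
synthetic throughout.

All outputs are deterministic functions of the scenario seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .config import AMINO_ACID_NAMES
from .diet_stats import CountMatrix
from .network_build import MergedNetwork
from .reaction_db import (
    EnzymeSequence,
    Metabolite,
    Reaction,
    ReactionDatabase,
)

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

_CODONS: dict[str, list[str]] = {}
for codon, aa in unambiguous_dna_by_id[1].forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()


@dataclass
class ScenarioConfig:
    """Study-scale knobs; defaults are the scenario the package is sized for."""

    n_metabolites: int = 300
    n_microbial_reactions: int = 400
    n_host_reactions: int = 60
    currency_fraction: float = 0.05
    carbon_min: int = 1
    carbon_max: int = 10
    interface_reaction_fraction: float = 0.15
    multi_reaction_enzyme_fraction: float = 0.05

    n_animals_per_diet: int = 8
    reads_per_animal: int = 50000
    fastq_pairs_per_animal: int = 300
    substitution_rate: float = 0.0

    # three-state read-density parameters of the base (FORG-like) intensity
    p0: float = 0.25
    p1: float = 0.08
    meanlog: float = 3.0
    sdlog: float = 1.703  # log-variance 2.9
    conc_sdlog: float = 1.643  # log-variance 2.7
    # log-fold enrichment of low-layer nodes per layer step in CONC
    layer_bias: float = 0.5
    # per-animal multiplicative log-normal dispersion
    forg_dispersion: float = 0.25
    conc_dispersion: float = 0.60
    # probability a node is silenced in exactly one diet (diet-exclusive nodes)
    exclusive_fraction: float = 0.05

    n_degenerate_animals: int = 3
    n_dominant_nodes: int = 8
    degenerate_dominance: float = 0.3

    n_otus: int = 80
    otu_reads_per_animal: int = 20000
    otu_diet_effect: float = 1.0

    seed: int = 0

    def animal_ids(self) -> tuple[list[str], list[str]]:
        forg = [f"F{i:02d}" for i in range(1, self.n_animals_per_diet + 1)]
        conc = [f"C{i:02d}" for i in range(1, self.n_animals_per_diet + 1)]
        return forg, conc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


# ---------------------------------------------------------------------------
# reaction databases

def _interface_metabolites() -> list[Metabolite]:
    mets = [
        Metabolite("ACETATE", "acetate", 2),
        Metabolite("PROPIONATE", "propionate", 3),
        Metabolite("BUTYRATE", "butyrate", 4),
        Metabolite("BUTYRYL_COA", "butyryl-CoA", 25),
    ]
    # plausible carbon counts for the 20 amino acids
    carbons = [3, 6, 4, 4, 3, 5, 5, 2, 6, 6, 6, 6, 5, 9, 5, 3, 4, 11, 9, 5]
    for name, c in zip(AMINO_ACID_NAMES, carbons):
        mets.append(Metabolite(f"AA_{name.upper()}", name, c))
    return mets


def gen_reaction_db(cfg: ScenarioConfig) -> tuple[ReactionDatabase, ReactionDatabase]:
    """Generate the microbial database and the host reaction set.

    Both databases share one metabolite table so interface ids match.  A
    designated currency pool is reused broadly (in three frequency tiers)
    so the occurrence cutoffs genuinely remove metabolites; a configurable
    fraction of reactions on each side uses an interface metabolite so the
    merged network has a frontier.
    """
    rng = np.random.default_rng((cfg.seed, 11))

    metabolites: dict[str, Metabolite] = {}
    for met in _interface_metabolites():
        metabolites[met.id] = met
    generic = [f"M{i:04d}" for i in range(cfg.n_metabolites)]
    for mid in generic:
        metabolites[mid] = Metabolite(
            mid, f"compound {mid}", int(rng.integers(cfg.carbon_min, cfg.carbon_max + 1))
        )

    n_currency = max(3, round(cfg.currency_fraction * cfg.n_metabolites))
    currency_pool = generic[:n_currency]
    # three frequency tiers, sized so the three occurrence cutoffs each bite:
    # tier probabilities target mean occurrences of ~140, ~60 and ~32 at the
    # default 400 reactions (water-like, ATP-like, and borderline compounds)
    tiers = np.array_split(np.asarray(currency_pool), 3)
    tier_prob = {0: 0.35, 1: 0.15, 2: 0.08}
    ordinary = generic[n_currency:]
    interface_ids = [m.id for m in _interface_metabolites() if m.id != "BUTYRYL_COA"]

    def draw_reaction_metabolites(use_interface: bool) -> frozenset[str]:
        mset: set[str] = set()
        for tier_idx, tier in enumerate(tiers):
            for mid in tier:
                if rng.random() < tier_prob[tier_idx]:
                    mset.add(str(mid))
        if use_interface:
            mset.add(str(rng.choice(interface_ids)))
        n_ordinary = int(rng.integers(2, 5))
        mset.update(rng.choice(ordinary, size=n_ordinary, replace=False))
        return frozenset(mset)

    vfas = ["ACETATE", "PROPIONATE", "BUTYRATE"]

    def build_reactions(prefix: str, n: int) -> dict[str, Reaction]:
        reactions = {}
        for i in range(n):
            rid = f"{prefix}{i:04d}"
            use_iface = rng.random() < cfg.interface_reaction_fraction
            mset = draw_reaction_metabolites(use_iface)
            # VFA production (microbial) and uptake (host) are obligatory in
            # the rumen: pin each VFA to one reaction per side
            if i < len(vfas):
                mset = mset | {vfas[i]}
            reactions[rid] = Reaction(rid, mset)
        return reactions

    microbial_reactions = build_reactions("R", cfg.n_microbial_reactions)

    enzymes: dict[str, EnzymeSequence] = {}
    rxn_ids = sorted(microbial_reactions)
    for i, rid in enumerate(rxn_ids):
        eid = f"E{i:04d}"
        length = int(rng.integers(130, 401))
        residues = "".join(rng.choice(list(RESIDUES), size=length))
        rids = {rid}
        if rng.random() < cfg.multi_reaction_enzyme_fraction:
            rids.add(str(rng.choice(rxn_ids)))
        enzymes[eid] = EnzymeSequence(eid, residues, frozenset(rids))
    enzymes_of: dict[str, set[str]] = {rid: set() for rid in microbial_reactions}
    for eid, enz in enzymes.items():
        for rid in enz.reaction_ids:
            enzymes_of[rid].add(eid)
    microbial_reactions = {
        rid: Reaction(rid, rxn.metabolite_ids, frozenset(enzymes_of[rid]))
        for rid, rxn in microbial_reactions.items()
    }

    microbial = ReactionDatabase(
        metabolites=dict(metabolites),
        reactions=microbial_reactions,
        enzymes=enzymes,
        source_label="microbial",
    )
    host = ReactionDatabase(
        metabolites=dict(metabolites),
        reactions=build_reactions("H", cfg.n_host_reactions),
        enzymes={},
        source_label="host",
    )
    return microbial, host


# ---------------------------------------------------------------------------
# intensity model shared by reads and count matrices

def _base_intensity(n_nodes: int, cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Three-state base intensity: zeros, a one-read-scale mass, log-normal."""
    u = rng.random(n_nodes)
    intensity = np.zeros(n_nodes)
    one_scale = 1.0
    lognormal = rng.lognormal(cfg.meanlog, cfg.sdlog, size=n_nodes)
    intensity = np.where(u < cfg.p0, 0.0, np.where(u < cfg.p0 + cfg.p1, one_scale, lognormal))
    return intensity


def _diet_intensities(
    node_ids: list[str],
    layers: dict[str, int | None],
    cfg: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(FORG, CONC) mean intensity per node with the layer-bias diet effect."""
    base = _base_intensity(len(node_ids), cfg, rng)
    layer_values = np.array(
        [layers.get(n) if layers.get(n) is not None else -1 for n in node_ids],
        dtype=float,
    )
    defined = layer_values >= 0
    max_layer = layer_values[defined].max() if defined.any() else 0.0
    layer_values[~defined] = max_layer  # unreachable nodes behave like the rim
    ref = layer_values[defined].mean() if defined.any() else 0.0
    tilt = np.exp(cfg.layer_bias * (ref - layer_values))
    conc = base * tilt
    # CONC also gets its own (slightly tighter) log-normal spread
    if cfg.conc_sdlog != cfg.sdlog:
        scale = cfg.conc_sdlog / cfg.sdlog
        positive = conc > 1.0
        logs = np.log(conc[positive])
        conc[positive] = np.exp(logs.mean() + (logs - logs.mean()) * scale)
    forg = base.copy()
    # diet-exclusive nodes: silence a small fraction on exactly one side
    u = rng.random(len(node_ids))
    forg[u < cfg.exclusive_fraction / 2] = 0.0
    conc[(u >= cfg.exclusive_fraction / 2) & (u < cfg.exclusive_fraction)] = 0.0
    return forg, conc


def gen_count_matrix(
    merged: MergedNetwork, cfg: ScenarioConfig
) -> tuple[CountMatrix, pd.DataFrame]:
    """Sample the node x animal count matrix and a matching OTU table.

    Each animal's counts are multinomial over nodes with probabilities
    proportional to its diet's mean intensity times animal-level
    log-normal dispersion (larger under CONC); the configured number of
    CONC animals share a common few-node-dominated degenerate profile.
    """
    rng = np.random.default_rng((cfg.seed, 23))
    graph = merged.microbial_graph
    node_ids = sorted(graph.nodes)
    forg_mean, conc_mean = _diet_intensities(node_ids, merged.layer, cfg, rng)

    forg_ids, conc_ids = cfg.animal_ids()
    degenerate = set(conc_ids[: cfg.n_degenerate_animals])
    dominant_idx = rng.choice(len(node_ids), size=cfg.n_dominant_nodes, replace=False)
    dominant_weights = rng.dirichlet(np.full(cfg.n_dominant_nodes, cfg.degenerate_dominance))

    columns = {}
    for animal in forg_ids + conc_ids:
        if animal in forg_ids:
            mean, sigma = forg_mean, cfg.forg_dispersion
        else:
            mean, sigma = conc_mean, cfg.conc_dispersion
        if animal in degenerate:
            # shared few-node-dominated profile: heavy mass on the dominant
            # nodes, a faint background on nodes the diet actually expresses
            intensity = np.where(mean > 0, 1e-4, 0.0)
            intensity[dominant_idx] = dominant_weights
            intensity *= rng.lognormal(0.0, 0.15, size=len(node_ids))
        else:
            intensity = mean * rng.lognormal(0.0, sigma, size=len(node_ids))
        total = intensity.sum()
        if total <= 0:
            raise ValueError("degenerate scenario: zero total intensity")
        columns[animal] = rng.multinomial(cfg.reads_per_animal, intensity / total)

    counts = pd.DataFrame(columns, index=node_ids)
    diets = pd.Series(
        {a: "FORG" for a in forg_ids} | {a: "CONC" for a in conc_ids}
    )
    totals = pd.Series({a: cfg.reads_per_animal for a in forg_ids + conc_ids})
    cm = CountMatrix(counts=counts, diets=diets, mapped_totals=totals)

    otus = _gen_otu_matrix(cfg, forg_ids, conc_ids, rng)
    return cm, otus


def _gen_otu_matrix(
    cfg: ScenarioConfig,
    forg_ids: list[str],
    conc_ids: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    otu_ids = [f"OTU{i:03d}" for i in range(cfg.n_otus)]
    base = rng.lognormal(0.0, 1.0, size=cfg.n_otus)
    effect = np.ones(cfg.n_otus)
    affected = rng.random(cfg.n_otus) < 0.5
    effect[affected] = np.exp(rng.normal(0.0, cfg.otu_diet_effect, size=int(affected.sum())))
    columns = {}
    for animal in forg_ids + conc_ids:
        mean = base if animal in forg_ids else base * effect
        sigma = cfg.forg_dispersion if animal in forg_ids else cfg.conc_dispersion
        intensity = mean * rng.lognormal(0.0, sigma, size=cfg.n_otus)
        columns[animal] = rng.multinomial(cfg.otu_reads_per_animal, intensity / intensity.sum())
    return pd.DataFrame(columns, index=otu_ids)


# ---------------------------------------------------------------------------
# paired-end reads

def back_translate(residues: str, rng: np.random.Generator) -> str:
    """Nucleotide sequence for a peptide, synonymous codons chosen uniformly."""
    return "".join(_CODONS[aa][int(rng.integers(len(_CODONS[aa])))] for aa in residues)


def gen_reads(
    db: ReactionDatabase,
    cfg: ScenarioConfig,
    out_dir: str | Path,
    n_pairs: int | None = None,
) -> pd.DataFrame:
    """Write paired FASTQ per animal plus a read -> source truth table.

    Fragments are drawn from back-translated enzyme coding sequences with
    insert length ~ N(309, 30) capped at the library's 420 bp size
    selection; both 100 bp mates therefore sit inside a stop-free coding
    frame.  Per-animal node intensities reuse the three-state model, and
    substitutions are applied at ``cfg.substitution_rate`` per base.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_pairs = n_pairs if n_pairs is not None else cfg.fastq_pairs_per_animal
    rng = np.random.default_rng((cfg.seed, 37))

    enzyme_ids = sorted(db.enzymes)
    nt_cache = {eid: back_translate(db.enzymes[eid].residues, rng) for eid in enzyme_ids}
    forg_ids, conc_ids = cfg.animal_ids()

    truth_rows = []
    for animal in forg_ids + conc_ids:
        weights = _base_intensity(len(enzyme_ids), cfg, rng)
        if weights.sum() <= 0:
            weights = np.ones(len(enzyme_ids))
        probs = weights / weights.sum()
        f1 = open(out / f"{animal}_1.fastq", "w")
        f2 = open(out / f"{animal}_2.fastq", "w")
        with f1, f2:
            for i in range(n_pairs):
                eid = enzyme_ids[int(rng.choice(len(enzyme_ids), p=probs))]
                nt = nt_cache[eid]
                insert = int(np.clip(rng.normal(309, 30), 210, min(420, len(nt))))
                start = int(rng.integers(0, len(nt) - insert + 1))
                fragment = nt[start: start + insert]
                mate1 = _mutate(fragment[:100], cfg.substitution_rate, rng)
                mate2 = _mutate(_revcomp(fragment[-100:]), cfg.substitution_rate, rng)
                rid = f"{animal}_read{i:06d}"
                qual = "I" * 100  # phred 40
                f1.write(f"@{rid}\n{mate1}\n+\n{qual}\n")
                f2.write(f"@{rid}\n{mate2}\n+\n{qual}\n")
                truth_rows.append(
                    {"read_id": rid, "animal": animal, "enzyme_id": eid,
                     "reaction_ids": ";".join(sorted(db.enzymes[eid].reaction_ids))}
                )
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return truth


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    bases = "ACGT"
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = bases[int(rng.integers(4))]
    return "".join(out)
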