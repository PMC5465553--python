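"""Compound vectors and the simulated-annealing diet-shift search.

A *compound vector* projects a per-node read distribution onto metabolite
space: the raw entry for metabolite c is the total read count of all nodes
whose reaction uses c, and vectors are rescaled to sum to 100,000 before
comparison.  The diet-shift simulation asks whether very different
read-to-node distributions can produce near-identical compound profiles:
starting from one animal's node counts, simulated annealing (Metropolis
acceptance, geometric cooling) searches for read distributions whose
scaled compound vector approaches a target — the diet-average compound
vector — under one of two move rules:

* ``swap1`` moves a single read from a read-bearing node (chosen with
  probability proportional to counts) to a uniformly chosen node;
* ``swap2`` moves a *pair* of reads from two edge-connected read-bearing
  nodes onto another pair of edge-connected nodes, a proxy for the genomic
  linkage of enzymes that cannot relocate independently.

Each search runs several independent restarts from the same start and
keeps the one whose best-ever state is closest to the target.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diet_stats import CountMatrix
from .distance_analysis import profile_vector
from .network_build import MetabolicGraph

SCALE_TOTAL = 100000.0


# ---------------------------------------------------------------------------
# compound vectors

class CompoundSpace:
    """Node -> metabolite incidence for fast compound-vector arithmetic."""

    def __init__(self, graph: MetabolicGraph, node_ids: Sequence[str]):
        unknown = [n for n in node_ids if n not in graph.nodes]
        if unknown:
            raise KeyError(f"unknown node ids: {unknown[:5]}")
        self.node_ids = list(node_ids)
        metabolites = sorted(
            set().union(*(graph.nodes[n].metabolite_ids for n in node_ids))
        )
        self.metabolite_ids = metabolites
        midx = {m: i for i, m in enumerate(metabolites)}
        self.incidence = np.zeros((len(node_ids), len(metabolites)))
        for i, n in enumerate(node_ids):
            for m in graph.nodes[n].metabolite_ids:
                self.incidence[i, midx[m]] = 1.0

    def raw_vector(self, node_counts: np.ndarray) -> np.ndarray:
        return node_counts @ self.incidence


def compound_vector(
    node_counts: Mapping[str, float], graph: MetabolicGraph
) -> pd.Series:
    """Raw metabolite-indexed read mass for one read distribution."""
    space = CompoundSpace(graph, sorted(node_counts))
    counts = np.array([node_counts[n] for n in space.node_ids], dtype=float)
    return pd.Series(space.raw_vector(counts), index=space.metabolite_ids)


def scale_vector(v: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Rescale a compound vector to total exactly 100,000."""
    total = float(np.sum(np.asarray(v, dtype=float)))
    if total <= 0:
        raise ValueError("cannot scale a zero compound vector")
    return v * (SCALE_TOTAL / total)


def make_target(cm: CountMatrix, diet: str, graph: MetabolicGraph) -> pd.Series:
    """Scaled compound vector of a diet's pooled read distribution."""
    animals = cm.animals(diet)
    if not animals:
        raise ValueError(f"no animals in diet {diet!r}")
    pooled = cm.counts[animals].sum(axis=1)
    pooled = pooled[pooled.index.isin(graph.nodes)]
    return scale_vector(compound_vector(pooled.to_dict(), graph))


# ---------------------------------------------------------------------------
# annealing

@dataclass(frozen=True)
class AnnealingConfig:
    move_rule: str = "swap1"  # swap1 | swap2
    iterations: int = 200000
    initial_temperature: float = 1.0
    cooling_factor: float = 0.9995
    restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.move_rule not in ("swap1", "swap2"):
            raise ValueError(f"unknown move rule {self.move_rule!r}")
        if not 0 < self.cooling_factor < 1:
            raise ValueError("cooling factor must be in (0, 1)")
        if self.iterations < 1 or self.restarts < 1:
            raise ValueError("iterations and restarts must be >= 1")


@dataclass
class AnnealingResult:
    start_label: str
    final_counts: pd.Series  # best-ever per-node read counts
    objective_trajectory: np.ndarray  # best-so-far, non-increasing
    final_distance: float
    restart_index: int


def _edge_arrays(space: CompoundSpace, graph: MetabolicGraph) -> np.ndarray:
    idx = {n: i for i, n in enumerate(space.node_ids)}
    edges = [
        (idx[a], idx[b])
        for a, b in graph.graph.edges
        if a in idx and b in idx
    ]
    return np.array(sorted(edges), dtype=int) if edges else np.empty((0, 2), dtype=int)


def propose_move(
    counts: np.ndarray,
    rule: str,
    rng: np.random.Generator,
    edges: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Return the move as (node index, delta) pairs; total reads conserved.

    ``swap1``: one read leaves a node chosen proportional to counts and
    lands on a uniformly chosen node.  ``swap2``: a source edge with reads
    on both endpoints and an arbitrary destination edge are chosen
    uniformly; one read moves along each pairing.
    """
    total = counts.sum()
    if total < 1:
        raise ValueError("state has no reads to move")
    if rule == "swap1":
        src = int(rng.choice(len(counts), p=counts / total))
        dst = int(rng.integers(len(counts)))
        return [(src, -1), (dst, +1)]
    if rule == "swap2":
        if edges is None or len(edges) == 0:
            raise ValueError("swap2 requires graph edges")
        positive = (counts[edges[:, 0]] > 0) & (counts[edges[:, 1]] > 0)
        eligible = np.nonzero(positive)[0]
        if len(eligible) == 0:
            raise ValueError("no edge joins two read-bearing nodes")
        a, b = edges[int(rng.choice(eligible))]
        c, d = edges[int(rng.integers(len(edges)))]
        if rng.random() < 0.5:
            c, d = d, c
        return [(int(a), -1), (int(b), -1), (int(c), +1), (int(d), +1)]
    raise ValueError(f"unknown move rule {rule!r}")


def _objective(raw: np.ndarray, target_scaled: np.ndarray) -> float:
    total = raw.sum()
    if total <= 0:
        return float("inf")
    return float(np.linalg.norm(raw * (SCALE_TOTAL / total) - target_scaled))


def _anneal_chain(
    start: np.ndarray,
    target_scaled: np.ndarray,
    space: CompoundSpace,
    cfg: AnnealingConfig,
    edges: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    counts = start.astype(float).copy()
    raw = space.raw_vector(counts)
    current = _objective(raw, target_scaled)
    best_counts, best = counts.copy(), current
    trajectory = np.empty(cfg.iterations)
    temperature = cfg.initial_temperature
    inc = space.incidence
    for it in range(cfg.iterations):
        try:
            move = propose_move(counts, cfg.move_rule, rng, edges)
        except ValueError:
            trajectory[it:] = best
            break
        # reject moves that would drive a count negative
        feasible = all(counts[i] + d >= 0 for i, d in move)
        if feasible:
            delta_raw = np.zeros_like(raw)
            for i, d in move:
                delta_raw += d * inc[i]
            candidate = _objective(raw + delta_raw, target_scaled)
            diff = candidate - current
            if diff <= 0 or rng.random() < np.exp(-diff / max(temperature, 1e-300)):
                for i, d in move:
                    counts[i] += d
                raw += delta_raw
                current = candidate
                if current < best:
                    best = current
                    best_counts = counts.copy()
        temperature *= cfg.cooling_factor
        trajectory[it] = best
    return best_counts, trajectory


def anneal(
    start_counts: Mapping[str, float] | pd.Series,
    target: pd.Series,
    cfg: AnnealingConfig,
    graph: MetabolicGraph,
    start_label: str = "start",
) -> AnnealingResult:
    """Best-of-restarts annealing of a read distribution toward a target.

    The objective is the Euclidean distance between the state's scaled
    compound vector and the (scaled) target.  Each restart runs an
    independent chain from the same start with a sub-seed derived from
    ``cfg.seed``; the restart whose best-ever state is closest to the
    target wins.
    """
    start = pd.Series(start_counts).astype(float)
    if start.sum() <= 0:
        raise ValueError("start distribution has no reads")
    space = CompoundSpace(graph, list(start.index))
    target_aligned = target.reindex(space.metabolite_ids, fill_value=0.0).to_numpy()
    target_scaled = np.asarray(scale_vector(target_aligned))
    edges = _edge_arrays(space, graph)

    best_result: AnnealingResult | None = None
    for restart in range(cfg.restarts):
        label_code = zlib.crc32(start_label.encode()) % (2**31)
        rng = np.random.default_rng((cfg.seed, label_code, restart))
        counts, trajectory = _anneal_chain(
            start.to_numpy(), target_scaled, space, cfg, edges, rng
        )
        result = AnnealingResult(
            start_label=start_label,
            final_counts=pd.Series(counts, index=space.node_ids),
            objective_trajectory=trajectory,
            final_distance=float(trajectory[-1]),
            restart_index=restart,
        )
        if best_result is None or result.final_distance < best_result.final_distance:
            best_result = result
    assert best_result is not None
    return best_result


# ---------------------------------------------------------------------------
# the full diet-shift experiment

def diet_shift_experiment(
    cm: CountMatrix,
    graph: MetabolicGraph,
    cfg: AnnealingConfig,
    start_diet: str = "FORG",
) -> dict:
    """Anneal every start-diet animal toward both diet-average targets.

    For each animal of the start diet, each target diet and each move rule,
    the best-of-restarts annealing result is retained; all unordered
    pairwise compound distances and unit-profile node distances among the
    per-condition best simulations are tabulated, with the real animals'
    pairwise distances included for reference.
    """
    node_ids = [n for n in cm.counts.index if n in graph.nodes]
    targets = {d: make_target(cm, d, graph) for d in ("FORG", "CONC")}
    space = CompoundSpace(graph, node_ids)

    def scaled_compound(counts: pd.Series) -> np.ndarray:
        raw = space.raw_vector(counts.reindex(node_ids, fill_value=0.0).to_numpy())
        return np.asarray(scale_vector(raw))

    animals = cm.animals(start_diet)
    results: dict[tuple[str, str, str], AnnealingResult] = {}
    for target_diet, target in targets.items():
        for rule in ("swap1", "swap2"):
            rule_cfg = AnnealingConfig(
                move_rule=rule,
                iterations=cfg.iterations,
                initial_temperature=cfg.initial_temperature,
                cooling_factor=cfg.cooling_factor,
                restarts=cfg.restarts,
                seed=cfg.seed,
            )
            for animal in animals:
                start = cm.counts.loc[node_ids, animal]
                results[(animal, target_diet, rule)] = anneal(
                    start, target, rule_cfg, graph,
                    start_label=f"{animal}|{target_diet}|{rule}",
                )

    def pairwise_rows(counts_by_animal: dict[str, pd.Series], condition: str) -> list[dict]:
        rows = []
        names = sorted(counts_by_animal)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                ca, cb = counts_by_animal[a], counts_by_animal[b]
                compound_d = float(
                    np.linalg.norm(scaled_compound(ca) - scaled_compound(cb))
                )
                node_d = float(
                    np.linalg.norm(
                        profile_vector(ca.reindex(node_ids, fill_value=0.0).to_numpy())
                        - profile_vector(cb.reindex(node_ids, fill_value=0.0).to_numpy())
                    )
                )
                rows.append(
                    {"condition": condition, "a": a, "b": b,
                     "compound_distance": compound_d, "node_distance": node_d}
                )
        return rows

    rows: list[dict] = []
    for target_diet in targets:
        for rule in ("swap1", "swap2"):
            sims = {
                animal: results[(animal, target_diet, rule)].final_counts
                for animal in animals
            }
            rows += pairwise_rows(sims, f"sim:{target_diet}:{rule}")
    real = {a: cm.counts.loc[node_ids, a].astype(float) for a in cm.animals()}
    rows += pairwise_rows(real, "real")

    return {
        "results": results,
        "pairwise": pd.DataFrame(rows),
        "targets": targets,
    }
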