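"""Unit-vector abundance profiles and pairwise-distance analysis.

Each animal's node (or OTU) count vector is scaled to unit Euclidean
length, v_i = r_i / sqrt(sum_j r_j^2), and animals are compared by the
Euclidean distance between these profiles (bounded by sqrt(2) for
non-negative unit vectors).  Sampling noise is quantified by a
proportional-reassignment null: within each diet, the pooled per-node
reads are multinomially redistributed to the diet's animals in proportion
to their original mapped totals, and the distance matrix recomputed.  The
same resamplings provide the null for the correlation between node-space
and OTU-space distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .diet_stats import DIETS, CountMatrix


@dataclass
class DistanceMatrix:
    matrix: pd.DataFrame  # symmetric, zero diagonal
    feature_space: str  # node | OTU

    def pair_table(self, diets: pd.Series) -> pd.DataFrame:
        """Long-format unordered pairs with FORG-FORG / CONC-CONC / cross labels."""
        animals = list(self.matrix.index)
        rows = []
        for i, a in enumerate(animals):
            for b in animals[i + 1:]:
                da, db = diets[a], diets[b]
                label = f"{da}-{db}" if da == db else "FORG-CONC"
                rows.append((a, b, label, self.matrix.loc[a, b]))
        return pd.DataFrame(rows, columns=["a", "b", "pair_class", "distance"])


def profile_vector(counts: Sequence[float] | np.ndarray) -> np.ndarray:
    """Scale a non-negative count vector to unit Euclidean length."""
    v = np.asarray(counts, dtype=float)
    if (v < 0).any():
        raise ValueError("negative counts in profile")
    norm = float(np.sqrt(np.sum(v**2)))
    if norm == 0:
        raise ValueError("all-zero count vector has no profile")
    return v / norm


def profiles_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-animal unit profiles from a feature x animal count table."""
    arr = counts.to_numpy(dtype=float)
    norms = np.sqrt((arr**2).sum(axis=0))
    zero = norms == 0
    if zero.any():
        raise ValueError(f"all-zero count columns: {list(counts.columns[zero])}")
    return pd.DataFrame(arr / norms, index=counts.index, columns=counts.columns)


def pairwise_distances(counts: pd.DataFrame, feature_space: str = "node") -> DistanceMatrix:
    """Euclidean distances between all pairs of unit-length profiles."""
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 animals")
    profiles = profiles_from_counts(counts)
    dm = squareform(pdist(profiles.to_numpy().T, metric="euclidean"))
    return DistanceMatrix(
        matrix=pd.DataFrame(dm, index=counts.columns, columns=counts.columns),
        feature_space=feature_space,
    )


def _within_diet_pairs(animals: list[str], diets: pd.Series) -> list[tuple[str, str]]:
    pairs = []
    for i, a in enumerate(animals):
        for b in animals[i + 1:]:
            if diets[a] == diets[b]:
                pairs.append((a, b))
    return pairs


def _reassign_counts(cm: CountMatrix, rng: np.random.Generator, exact: bool = False) -> pd.DataFrame:
    """One proportional-reassignment replicate of the raw count table.

    Within each diet, each node's pooled reads are multinomially split
    over the diet's animals with probabilities proportional to their
    original mapped totals (expected-total conservation); ``exact``
    partitions each animal's exact original total instead.
    """
    out = {}
    for diet in DIETS:
        animals = cm.animals(diet)
        pooled = cm.diet_pooled(diet).to_numpy()
        totals = cm.mapped_totals[animals].to_numpy(dtype=float)
        probs = totals / totals.sum()
        if exact:
            # partition the diet's pooled reads so each animal keeps its
            # exact original assigned-read total (without replacement)
            counts = np.zeros((len(cm.counts.index), len(animals)), dtype=int)
            remaining = pooled.astype(int).copy()
            for k, animal in enumerate(animals[:-1]):
                draw = rng.multivariate_hypergeometric(remaining, int(cm.counts[animal].sum()))
                counts[:, k] = draw
                remaining -= draw
            counts[:, -1] = remaining
        else:
            counts = np.array([rng.multinomial(int(n), probs) for n in pooled])
        for k, animal in enumerate(animals):
            out[animal] = counts[:, k]
    frame = pd.DataFrame(out, index=cm.counts.index)
    return frame[cm.counts.columns]


def reassignment_null(
    cm: CountMatrix, n_rep: int = 1000, seed: int = 0, exact: bool = False
) -> dict:
    """Null pairwise node distances under proportional read reassignment.

    Returns per-replicate minimum and maximum within-diet distances per
    diet, plus the replicate count tables' distance matrices summarised as
    extremes only (full matrices are not retained).
    """
    for diet in DIETS:
        if len(cm.animals(diet)) < 2:
            raise ValueError(f"need >= 2 animals in {diet} for pairwise distances")
    rng = np.random.default_rng(seed)
    mins: dict[str, list[float]] = {d: [] for d in DIETS}
    maxs: dict[str, list[float]] = {d: [] for d in DIETS}
    for _ in range(n_rep):
        counts = _reassign_counts(cm, rng, exact=exact)
        dm = pairwise_distances(counts).matrix
        for diet in DIETS:
            animals = cm.animals(diet)
            sub = dm.loc[animals, animals].to_numpy()
            vals = sub[np.triu_indices(len(animals), k=1)]
            mins[diet].append(float(vals.min()))
            maxs[diet].append(float(vals.max()))
    return {
        "min": {d: np.array(v) for d, v in mins.items()},
        "max": {d: np.array(v) for d, v in maxs.items()},
        "n_rep": n_rep,
    }


def distance_exceedance_p(observed: np.ndarray, null_max: np.ndarray) -> float:
    """Add-one P for the observed minimum within-diet distance exceeding the null."""
    exceed = int(np.sum(null_max >= float(np.min(observed))))
    return (exceed + 1) / (len(null_max) + 1)


def node_otu_correlation(
    dm_nodes: DistanceMatrix,
    dm_otus: DistanceMatrix,
    diets: pd.Series,
    cm_nodes: CountMatrix | None = None,
    otu_counts: pd.DataFrame | None = None,
    n_rep: int = 100,
    seed: int = 0,
    within_diet_only: bool = True,
) -> dict:
    """Pearson correlation between node-space and OTU-space distances.

    Computed over within-diet animal pairs by default (all pairs behind the
    flag).  When the underlying count tables are supplied, the observed
    correlation is compared against correlations from proportional
    reassignments of both tables.
    """
    if list(dm_nodes.matrix.index) != list(dm_otus.matrix.index):
        raise ValueError("node and OTU matrices cover different animals")
    animals = list(dm_nodes.matrix.index)
    if within_diet_only:
        pairs = _within_diet_pairs(animals, diets)
    else:
        pairs = [(a, b) for i, a in enumerate(animals) for b in animals[i + 1:]]

    def corr(node_m: pd.DataFrame, otu_m: pd.DataFrame) -> float:
        x = np.array([node_m.loc[a, b] for a, b in pairs])
        y = np.array([otu_m.loc[a, b] for a, b in pairs])
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn("zero variance in distances; correlation undefined")
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])

    observed = corr(dm_nodes.matrix, dm_otus.matrix)
    result = {"r": observed, "n_pairs": len(pairs)}
    if cm_nodes is not None and otu_counts is not None:
        rng = np.random.default_rng(seed)
        cm_otus = CountMatrix(
            counts=otu_counts,
            diets=diets,
            mapped_totals=otu_counts.sum(axis=0).astype(int),
        )
        null = []
        for _ in range(n_rep):
            nodes_r = _reassign_counts(cm_nodes, rng)
            otus_r = _reassign_counts(cm_otus, rng)
            null.append(
                corr(
                    pairwise_distances(nodes_r).matrix,
                    pairwise_distances(otus_r).matrix,
                )
            )
        null = np.array(null)
        result["null_r"] = null
        result["p_value"] = (int(np.sum(null >= observed)) + 1) / (n_rep + 1)
    return result
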