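"""Diet-contrast statistics on node read counts.

Counts are normalized to reads per node per million mapped reads.  The
read-density model per diet is a three-state mixture: a point mass of nodes
with zero raw reads (``p0``), a point mass with exactly one raw read
(``p1``), and a log-normal (truncated to values above 1) for the remainder;
diets are compared with a likelihood-ratio test between separate and pooled
fits.  Per-node differential abundance uses two-sample Wilcoxon tests with
Benjamini-Hochberg FDR control at 5%.

Structural contrasts (mean interface layer, carbon sum, betweenness,
degree, clustering coefficient) weight each node's statistic by its read
mass and compare the diet means against a randomization null in which the
pooled per-node read masses are multinomially reassigned into pseudo-diets
of the original sizes; all randomization P-values use the add-one
estimator (#{|null| >= |observed|} + 1) / (n_rand + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .network_build import MetabolicGraph
from .reaction_db import ReactionDatabase

DIETS = ("FORG", "CONC")


# ---------------------------------------------------------------------------
# containers

@dataclass
class CountMatrix:
    """Node x animal raw read counts with diet labels and mapped totals."""

    counts: pd.DataFrame  # rows: node ids, columns: animal ids, int
    diets: pd.Series  # animal id -> FORG | CONC
    mapped_totals: pd.Series  # animal id -> mapped reads (>= column sum)

    def __post_init__(self) -> None:
        self.counts = self.counts.sort_index()
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")
        if not set(self.counts.columns) <= set(self.diets.index):
            raise ValueError("diet label missing for some animals")
        self.diets = self.diets.loc[self.counts.columns]
        self.mapped_totals = self.mapped_totals.loc[self.counts.columns]
        bad = self.diets[~self.diets.isin(DIETS)]
        if len(bad):
            raise ValueError(f"unknown diet labels: {sorted(set(bad))}")

    def animals(self, diet: str | None = None) -> list[str]:
        if diet is None:
            return list(self.counts.columns)
        return list(self.diets[self.diets == diet].index)

    def diet_pooled(self, diet: str) -> pd.Series:
        """Per-node raw counts summed over the diet's animals."""
        return self.counts[self.animals(diet)].sum(axis=1)


def load_count_matrix(counts_path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read the node x animal TSV and the sample-metadata TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col="animal_id")
    meta.index = meta.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return CountMatrix(
        counts=counts.astype(int),
        diets=meta["diet"],
        mapped_totals=meta["mapped_total"].astype(int),
    )


def write_count_matrix(cm: CountMatrix, counts_path: str | Path, metadata_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="node_id")
    meta = pd.DataFrame({"diet": cm.diets, "mapped_total": cm.mapped_totals})
    meta.to_csv(metadata_path, sep="\t", index_label="animal_id")


def normalize(cm: CountMatrix) -> pd.DataFrame:
    """Reads per node per 10^6 mapped reads, per animal."""
    totals = cm.mapped_totals.astype(float)
    if (totals <= 0).any():
        zero = list(totals[totals <= 0].index)
        raise ValueError(f"non-positive mapped totals for {zero}")
    return cm.counts * 1e6 / totals


# ---------------------------------------------------------------------------
# three-state read-density model

@dataclass(frozen=True)
class ThreeStateFit:
    p0: float
    p1: float
    meanlog: float
    sdlog: float
    loglik: float
    n: int


def _truncated_lognormal_nll(params: np.ndarray, logx: np.ndarray) -> float:
    mu, log_sigma = params
    sigma = np.exp(log_sigma)
    z = (logx - mu) / sigma
    # density of log-normal truncated to x > 1, i.e. log x > 0
    return float(
        len(logx) * (np.log(sigma) + 0.5 * np.log(2 * np.pi))
        + np.sum(logx)
        + 0.5 * np.sum(z**2)
        + len(logx) * np.log(stats.norm.cdf(mu / sigma))
    )


def fit_three_state(
    raw_counts: Sequence[int] | np.ndarray,
    normalized: Sequence[float] | np.ndarray | None = None,
) -> ThreeStateFit:
    """Maximum-likelihood fit of the zero / one / log-normal mixture.

    The two point masses are defined on the raw integer counts (closed-form
    empirical fractions); the log-normal component, truncated to values
    above 1, is fitted numerically to the values of nodes with raw count
    >= 2 — the normalized values when supplied, the raw counts otherwise.
    """
    raw = np.asarray(raw_counts)
    if len(raw) < 10:
        raise ValueError("need at least 10 nodes to fit the mixture")
    values = np.asarray(normalized, dtype=float) if normalized is not None else raw.astype(float)
    if len(values) != len(raw):
        raise ValueError("raw and normalized vectors differ in length")

    n = len(raw)
    n0 = int(np.sum(raw == 0))
    n1 = int(np.sum(raw == 1))
    p0, p1 = n0 / n, n1 / n
    tail = values[raw >= 2]

    def point_mass_ll() -> float:
        ll = 0.0
        if n0:
            ll += n0 * np.log(p0)
        if n1:
            ll += n1 * np.log(p1)
        if len(tail):
            ll += len(tail) * np.log(1 - p0 - p1)
        return ll

    if len(tail) == 0:
        return ThreeStateFit(p0, p1, float("nan"), float("nan"), point_mass_ll(), n)
    if len(np.unique(tail)) < 3:
        raise ValueError("fewer than 3 distinct values >= 2; log-normal tail unidentifiable")
    if np.any(tail <= 1):
        raise ValueError("tail values <= 1 violate the truncated log-normal support")

    logx = np.log(tail)
    init = np.array([logx.mean(), np.log(max(logx.std(), 1e-3))])
    res = optimize.minimize(
        _truncated_lognormal_nll, init, args=(logx,), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    mu, sigma = res.x[0], float(np.exp(res.x[1]))
    loglik = point_mass_ll() - res.fun
    return ThreeStateFit(p0, p1, float(mu), sigma, float(loglik), n)


def lrt_diets(
    fit_forg: ThreeStateFit, fit_conc: ThreeStateFit, fit_pooled: ThreeStateFit,
    df: int = 4,
) -> tuple[float, int, float]:
    """Likelihood-ratio test of separate versus pooled three-state fits.

    The nested difference in free parameters is 4 (p0, p1, meanlog, sdlog
    per diet); pass ``df=5`` to reproduce the alternative convention that
    also counts the mixture constraint.
    """
    statistic = 2.0 * (fit_forg.loglik + fit_conc.loglik - fit_pooled.loglik)
    statistic = max(statistic, 0.0)
    return statistic, df, float(stats.chi2.sf(statistic, df))


def fit_three_state_by_diet(cm: CountMatrix, df: int = 4) -> dict:
    """Convenience wrapper: per-diet fits, combined fit and the LRT.

    The single-distribution alternative is fitted to the *combined* data —
    both diets' per-node observations concatenated — so the separate fits
    nest inside it.
    """
    nc = normalize(cm)
    fits = {}
    raws, norms = [], []
    for diet in DIETS:
        raw = cm.diet_pooled(diet).to_numpy()
        norm = nc[cm.animals(diet)].sum(axis=1).to_numpy()
        fits[diet] = fit_three_state(raw, norm)
        raws.append(raw)
        norms.append(norm)
    fits["pooled"] = fit_three_state(np.concatenate(raws), np.concatenate(norms))
    stat, used_df, p = lrt_diets(fits["FORG"], fits["CONC"], fits["pooled"], df=df)
    return {"fits": fits, "lrt_statistic": stat, "df": used_df, "p_value": p}


# ---------------------------------------------------------------------------
# per-node differential abundance

def per_node_tests(cm: CountMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Two-sample Wilcoxon test per node with Benjamini-Hochberg control.

    Only nodes with at least one mapped read anywhere are tested.  The
    direction column marks which diet has the larger mean normalized count;
    significance is q < ``alpha``.
    """
    nc = normalize(cm)
    forg, conc = (nc[cm.animals(d)] for d in DIETS)
    keep = cm.counts.sum(axis=1) > 0
    rows = []
    for node in nc.index[keep]:
        x = forg.loc[node].to_numpy()
        y = conc.loc[node].to_numpy()
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            w, p = len(x) * len(y) / 2.0, 1.0
        else:
            both = np.concatenate([x, y])
            method = "exact" if len(np.unique(both)) == len(both) else "asymptotic"
            w, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        diff = x.mean() - y.mean()
        rows.append((node, w, p, "FORG" if diff > 0 else "CONC" if diff < 0 else "none"))
    table = pd.DataFrame(rows, columns=["node_id", "W", "P", "direction"]).set_index("node_id")
    if len(table):
        table["q"] = multipletests(table["P"], method="fdr_bh")[1]
    else:
        table["q"] = []
    table["significant"] = table["q"] < alpha
    return table


# ---------------------------------------------------------------------------
# randomization framework

@dataclass
class RandomizationResult:
    observed: float
    null: np.ndarray
    statistic_name: str = ""

    @property
    def max_abs_null(self) -> float:
        return float(np.max(np.abs(self.null)))

    @property
    def p_value(self) -> float:
        exceed = int(np.sum(np.abs(self.null) >= abs(self.observed)))
        return (exceed + 1) / (len(self.null) + 1)


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    total = weights.sum()
    if total <= 0:
        raise ValueError("no read mass to weight")
    return float(values @ weights / total)


def _multinomial_null_diffs(
    values: np.ndarray,
    forg_counts: np.ndarray,
    conc_counts: np.ndarray,
    n_rand: int,
    rng: np.random.Generator,
    exact: bool = False,
) -> np.ndarray:
    """Null distribution of the weighted-mean difference.

    Pools the two diets' per-node read masses and reassigns the original
    per-diet totals over nodes — multinomially with probabilities
    proportional to the pooled counts, or by exact without-replacement
    partition when ``exact``.
    """
    pooled = forg_counts + conc_counts
    total = int(pooled.sum())
    n_forg = int(forg_counts.sum())
    n_conc = int(conc_counts.sum())
    if total == 0:
        raise ValueError("no reads on statistic-bearing nodes")
    if exact:
        pseudo_f = np.array(
            [rng.multivariate_hypergeometric(pooled.astype(int), n_forg) for _ in range(n_rand)]
        )
        pseudo_c = pooled[None, :] - pseudo_f
    else:
        p = pooled / total
        pseudo_f = rng.multinomial(n_forg, p, size=n_rand)
        pseudo_c = rng.multinomial(n_conc, p, size=n_rand)
    mean_f = pseudo_f @ values / np.maximum(pseudo_f.sum(axis=1), 1)
    mean_c = pseudo_c @ values / np.maximum(pseudo_c.sum(axis=1), 1)
    return mean_f - mean_c


def _read_weighted_contrast(
    cm: CountMatrix,
    node_values: Mapping[str, float],
    n_rand: int,
    seed: int,
    name: str,
    weighting: str = "read_weighted",
    exact_null: bool = False,
) -> RandomizationResult:
    nodes = [n for n in cm.counts.index if n in node_values]
    if not nodes:
        raise ValueError("no overlap between count matrix and statistic values")
    values = np.array([node_values[n] for n in nodes], dtype=float)
    forg = cm.diet_pooled("FORG").loc[nodes].to_numpy(dtype=float)
    conc = cm.diet_pooled("CONC").loc[nodes].to_numpy(dtype=float)
    if weighting == "read_weighted":
        observed = _weighted_mean(values, forg) - _weighted_mean(values, conc)
    elif weighting == "product_mean":
        observed = float(np.mean(values * forg) - np.mean(values * conc))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    rng = np.random.default_rng(seed)
    null = _multinomial_null_diffs(values, forg, conc, n_rand, rng, exact=exact_null)
    return RandomizationResult(observed=observed, null=null, statistic_name=name)


def mean_layer_test(
    cm: CountMatrix,
    layers: Mapping[str, int | None],
    n_rand: int = 1000,
    seed: int = 0,
    exact_null: bool = False,
) -> RandomizationResult:
    """Read-weighted mean-layer difference (FORG - CONC) with its null.

    Reads on nodes without a defined layer are excluded.  The null pools
    all mapped reads and redistributes each diet's total over nodes.
    """
    layered = {n: float(l) for n, l in layers.items() if l is not None}
    return _read_weighted_contrast(cm, layered, n_rand, seed, "mean_layer",
                                   exact_null=exact_null)


def node_statistics(
    graph: MetabolicGraph,
    stat: str,
    db: ReactionDatabase | None = None,
) -> dict[str, float]:
    """Per-node structural statistic on one subnetwork graph."""
    g = graph.graph
    if stat == "carbon_sum":
        if db is None:
            raise ValueError("carbon_sum requires the reaction database")
        return {n: float(graph.carbon_sum(db, n)) for n in graph.nodes}
    if stat == "betweenness":
        return {n: float(v) for n, v in nx.betweenness_centrality(g, normalized=False).items()}
    if stat == "degree":
        return {n: float(d) for n, d in g.degree()}
    if stat == "clustering":
        return {n: float(v) for n, v in nx.clustering(g).items()}
    raise ValueError(f"unknown statistic {stat!r}; use carbon_sum, betweenness, degree or clustering")


def network_stat_contrast(
    cm: CountMatrix,
    graph: MetabolicGraph,
    stat: str,
    db: ReactionDatabase | None = None,
    n_rand: int = 1000,
    seed: int = 0,
    weighting: str = "read_weighted",
) -> RandomizationResult:
    """Diet contrast of a read-weighted structural statistic.

    The default weighting is the read-weighted mean (the average statistic
    value experienced by a mapped read); ``weighting='product_mean'``
    selects the unnormalized mean of per-node products instead.
    """
    values = node_statistics(graph, stat, db=db)
    return _read_weighted_contrast(cm, values, n_rand, seed, stat, weighting=weighting)


# ---------------------------------------------------------------------------
# layer correlation and per-layer summaries

def layer_correlation(
    cm: CountMatrix,
    layers: Mapping[str, int | None],
    per_node_table: pd.DataFrame | None = None,
) -> dict:
    """Pearson correlation of read counts with layer, plus layer histograms.

    Returns per-diet correlations between per-node diet-mean normalized
    counts and layer number, the per-layer cumulative read proportions per
    diet, and (when a differential-abundance table is supplied) the
    per-layer proportion of significant nodes with its correlation against
    layer.
    """
    nc = normalize(cm)
    layered = {n: l for n, l in layers.items() if l is not None and n in nc.index}
    node_ids = sorted(layered)
    layer_vec = np.array([layered[n] for n in node_ids], dtype=float)
    if len(np.unique(layer_vec)) < 3:
        raise ValueError("need at least 3 distinct layers for a correlation")

    out: dict = {"per_diet_r": {}, "layer_read_proportions": {}, "cumulative_proportions": {}}
    for diet in DIETS:
        mean_counts = nc.loc[node_ids, cm.animals(diet)].mean(axis=1).to_numpy()
        r, p = stats.pearsonr(mean_counts, layer_vec)
        out["per_diet_r"][diet] = (float(r), float(p))
        raw = cm.diet_pooled(diet).loc[node_ids].to_numpy(dtype=float)
        props = pd.Series(raw, index=layer_vec.astype(int)).groupby(level=0).sum()
        props = props / props.sum()
        out["layer_read_proportions"][diet] = props
        out["cumulative_proportions"][diet] = props.cumsum()

    if per_node_table is not None:
        sig = per_node_table["significant"]
        frame = pd.DataFrame(
            {"layer": [layered[n] for n in node_ids],
             "sig": [bool(sig.get(n, False)) for n in node_ids]}
        )
        per_layer = frame.groupby("layer")["sig"].mean()
        if len(per_layer) >= 3:
            r, p = stats.pearsonr(per_layer.index.to_numpy(float), per_layer.to_numpy())
            out["differential_proportion_r"] = (float(r), float(p))
        out["differential_proportion_by_layer"] = per_layer
    return out


# ---------------------------------------------------------------------------
# presence/absence

def presence_absence(cm: CountMatrix, n_rand: int = 1000, seed: int = 0, alpha: float = 0.01) -> dict:
    """Classify nodes by diet presence and test exclusivity by permutation.

    A diet-exclusive node's P-value is the probability, under random
    reassignment of its reads to animals proportional to their mapped
    totals, of seeing all of its reads in one diet and none in the other
    (add-one estimator over ``n_rand`` draws).
    """
    forg = cm.diet_pooled("FORG")
    conc = cm.diet_pooled("CONC")
    observed = (forg + conc) > 0
    shared = ((forg > 0) & (conc > 0)).sum()
    forg_only = list(forg[(forg > 0) & (conc == 0)].index)
    conc_only = list(conc[(conc > 0) & (forg == 0)].index)

    totals = cm.mapped_totals.astype(float)
    p_diet = {
        d: totals[cm.animals(d)].sum() / totals.sum() for d in DIETS
    }
    rng = np.random.default_rng(seed)
    results = {}
    for diet, exclusive in (("FORG", forg_only), ("CONC", conc_only)):
        p = p_diet[diet]
        sig = 0
        pvals = {}
        for node in exclusive:
            t = int((forg if diet == "FORG" else conc)[node])
            # replicate is as extreme as observed iff all t reads land in this diet
            draws = rng.binomial(t, p, size=n_rand)
            pval = (int(np.sum(draws == t)) + 1) / (n_rand + 1)
            pvals[node] = pval
            if pval < alpha:
                sig += 1
        results[diet] = {"exclusive": exclusive, "p_values": pvals, "n_significant": sig}

    diff_present = forg_only + conc_only
    reads_of = (forg + conc).loc[diff_present] if diff_present else pd.Series(dtype=float)
    return {
        "n_observed": int(observed.sum()),
        "n_shared": int(shared),
        "n_forg_only": len(forg_only),
        "n_conc_only": len(conc_only),
        "forg": results["FORG"],
        "conc": results["CONC"],
        "mean_reads_forg_only": float(forg.loc[forg_only].mean()) if forg_only else float("nan"),
        "mean_reads_conc_only": float(conc.loc[conc_only].mean()) if conc_only else float("nan"),
        "max_reads_differential": float(reads_of.max()) if len(reads_of) else float("nan"),
    }


# ---------------------------------------------------------------------------
# variance contrast with depth-equalized resampling

def _node_variances(values: pd.DataFrame) -> np.ndarray:
    return values.var(axis=1, ddof=1).to_numpy()


def variance_contrast(
    cm: CountMatrix,
    subsample_reads: int = 100000,
    n_rep: int = 1000,
    seed: int = 0,
) -> dict:
    """Diet contrast of across-animal per-node variance, depth-equalized.

    The observed test is a paired (node-wise) Wilcoxon signed-rank between
    the two diets' per-node variances of normalized counts.  Each replicate
    redraws ``subsample_reads`` mapped reads per animal without replacement
    (with replacement, and flagged, for animals with fewer mapped reads)
    and repeats the test, yielding the resampled P distribution.
    """
    nc = normalize(cm)
    keep = cm.counts.sum(axis=1) > 0
    forg_animals, conc_animals = cm.animals("FORG"), cm.animals("CONC")

    def paired_test(norm: pd.DataFrame) -> float:
        var_f = _node_variances(norm.loc[keep, forg_animals])
        var_c = _node_variances(norm.loc[keep, conc_animals])
        diff = var_f - var_c
        if np.allclose(diff, 0):
            return 1.0
        return float(stats.wilcoxon(var_f, var_c, zero_method="wilcox").pvalue)

    observed_p = paired_test(nc)

    rng = np.random.default_rng(seed)
    node_index = cm.counts.index
    resampled_p = np.empty(n_rep)
    flagged: set[str] = set()
    cols = {a: cm.counts[a].to_numpy() for a in cm.counts.columns}
    for rep in range(n_rep):
        sub = {}
        for animal, col in cols.items():
            total = int(col.sum())
            if total >= subsample_reads:
                draw = rng.multivariate_hypergeometric(col, subsample_reads)
            else:
                flagged.add(animal)
                p = col / total
                draw = rng.multinomial(subsample_reads, p)
            sub[animal] = draw * 1e6 / subsample_reads
        resampled_p[rep] = paired_test(pd.DataFrame(sub, index=node_index))

    return {
        "observed_p": observed_p,
        "resampled_p": resampled_p,
        "flagged_animals": sorted(flagged),
    }


# ---------------------------------------------------------------------------
# VFA concentration correlation

def vfa_correlation(
    cm: CountMatrix,
    vfa_node_map: Mapping[str, Sequence[str]],
    vfa_concentrations: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman correlation of VFA read fractions against concentrations.

    For each animal the read fraction is the share of uniquely mapped reads
    on nodes whose reaction uses the VFA; the correlation against the
    measured concentration is one-sided (positive association).  Animals
    missing a concentration are dropped per VFA; fewer than 5 paired
    observations is an error, and constant concentrations yield NaN with a
    warning.
    """
    total = cm.counts.sum(axis=0).astype(float)
    rows = []
    for vfa, nodes in vfa_node_map.items():
        present = [n for n in nodes if n in cm.counts.index]
        fractions = cm.counts.loc[present].sum(axis=0) / total
        conc = vfa_concentrations[vfa].dropna()
        animals = [a for a in fractions.index if a in conc.index]
        if len(animals) < 5:
            raise ValueError(f"fewer than 5 paired observations for {vfa}")
        x = conc.loc[animals].to_numpy(dtype=float)
        y = fractions.loc[animals].to_numpy(dtype=float)
        if np.all(x == x[0]):
            warnings.warn(f"constant concentrations for {vfa}; correlation undefined")
            rho, p = float("nan"), float("nan")
        else:
            res = stats.spearmanr(x, y, alternative="greater")
            rho, p = float(res.statistic), float(res.pvalue)
        rows.append((vfa, len(animals), len(present), rho, p))
    return pd.DataFrame(
        rows, columns=["vfa", "n_animals", "n_nodes", "rho", "P"]
    ).set_index("vfa")
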