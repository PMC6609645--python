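"""Phenotype-driven metabolite modules across tissues.

A Gaussian graphical model is estimated over all (metabolite, tissue) nodes:
the covariance is regularised by Ledoit-Wolf shrinkage toward a diagonal
target (the design has far more nodes than samples, so the sample covariance
is singular), inverted, and converted to partial correlations.  Edge
significance uses the parametric Beta null when the sample size supports
full partialling, and a median-calibrated scaled chi-square null in the
p >> n regime (shrinkage rescales all partial correlations roughly
uniformly, so the calibration is scale-free).  Edges kept at p < 0.1 are
labelled intra- or inter-tissue.

Modules are grown greedily from seed nodes: the module representative is the
first principal component ("eigenmetabolite") of the member profiles, its
phenotype association is a logistic score test, and a neighbour is accepted
only if it strictly decreases the association p.  The procedure mirrors
module-detection approaches of the MoDentify family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import LedoitWolf
from statsmodels.stats.multitest import multipletests

from .errors import MetmapError
from .ingest_annotate import SampleRecord
from .preprocess import ScaledTable

NODE_SEP = "::"


def node_name(tissue: str, metabolite_id: str) -> str:
    return f"{tissue}{NODE_SEP}{metabolite_id}"


def _stack_tissues(
    scaled_by_tissue: Mapping[str, ScaledTable],
) -> tuple[np.ndarray, list[str], list[str]]:
    """Column-stack all tissues over the common sample set.

    Returns (samples x nodes matrix, node names, common sample ids).
    """
    tissues = sorted(scaled_by_tissue)
    common = None
    for t in tissues:
        ids = set(scaled_by_tissue[t].sample_ids)
        common = ids if common is None else common & ids
    common = sorted(common or [])
    if len(common) < 10:
        raise MetmapError(
            f"only {len(common)} common samples; partial correlations unstable")
    blocks, names = [], []
    for t in tissues:
        st = scaled_by_tissue[t]
        blocks.append(st.values[common].to_numpy(dtype=float).T)
        names.extend(node_name(t, m) for m in st.metabolite_ids)
    return np.hstack(blocks), names, common


#: median of a chi-square with one degree of freedom
_CHI2_1_MEDIAN = float(stats.chi2.median(1))


def _edge_pvalues(r: np.ndarray, n: int, p_nodes: int,
                  shrinkage: float) -> tuple[np.ndarray, float]:
    """Two-sided p-values for off-diagonal partial correlations.

    When the sample size supports full partialling (n - p + 1 >= 10) *and*
    the estimated shrinkage is negligible (the partial correlations are then
    essentially unshrunk), the parametric null r^2 ~ Beta(1/2, (k-1)/2) with
    k = n - p + 1 conditioning degrees of freedom is used.  Otherwise the
    shrinkage scales every partial correlation by roughly the same factor,
    so r^2 is a scaled chi-square(1) under the null; the scale is fitted by
    the empirical median (robust to a minority of true edges) and
    p = P(chi2_1 >= c * r^2 / med) with c the chi-square(1) median.
    Returns (p, effective df or nan).
    """
    k = n - p_nodes + 1
    if k >= 10 and shrinkage <= 0.1:
        return stats.beta.sf(r ** 2, 0.5, (k - 1) / 2), float(k)
    med = float(np.median(r ** 2))
    med = max(med, 1e-300)
    return stats.chi2.sf(_CHI2_1_MEDIAN * r ** 2 / med, df=1), float("nan")


def build_network(
    scaled_by_tissue: Mapping[str, ScaledTable],
    samples: Sequence[SampleRecord] | None = None,
    edge_alpha: float = 0.1,
) -> nx.Graph:
    """Estimate the shrinkage partial-correlation network across tissues.

    Nodes are ``tissue::metabolite`` pairs; edges carry the partial
    correlation, its empirical-null p-value and the scope label
    (``intra_tissue`` when both endpoints share the tissue).
    """
    X, names, common = _stack_tissues(scaled_by_tissue)
    lw = LedoitWolf(assume_centered=False).fit(X)
    # cap the shrinkage below 1: at the cap the covariance would be exactly
    # diagonal and all partial correlations identically zero; the empirical
    # null only needs the relative magnitudes, which the cap preserves
    lam = min(float(lw.shrinkage_), 0.95)
    emp = np.cov(X, rowvar=False, ddof=0)
    mu = np.trace(emp) / emp.shape[0]
    shrunk = (1 - lam) * emp + lam * mu * np.eye(emp.shape[0])
    prec = np.linalg.inv(shrunk)
    d = np.sqrt(np.diag(prec))
    pcor = -prec / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = np.clip((pcor + pcor.T) / 2, -0.999999, 0.999999)

    iu = np.triu_indices_from(pcor, k=1)
    r = pcor[iu]
    p, k_df = _edge_pvalues(r, len(common), len(names), lam)
    fdr_p = multipletests(p, method="fdr_bh")[1]

    g = nx.Graph()
    g.graph["n_samples"] = len(common)
    g.graph["null_df"] = k_df
    g.graph["edge_alpha"] = edge_alpha
    g.graph["shrinkage"] = lam
    for name in names:
        tissue, met = name.split(NODE_SEP, 1)
        g.add_node(name, tissue=tissue, metabolite=met)
    keep = p < edge_alpha
    for (i, j, rv, pv, fv) in zip(iu[0][keep], iu[1][keep], r[keep], p[keep],
                                  fdr_p[keep]):
        a, b = names[i], names[j]
        scope = ("intra_tissue" if g.nodes[a]["tissue"] == g.nodes[b]["tissue"]
                 else "inter_tissue")
        g.add_edge(a, b, pcor=float(rv), p=float(pv), fdr_p=float(fv), scope=scope)
    return g


# ---------------------------------------------------------------------------
# module search
# ---------------------------------------------------------------------------

@dataclass
class ModuleResult:
    members: tuple[str, ...]
    seed_node: str
    representative: np.ndarray
    association_p: float
    gain_trace: list[float] = field(default_factory=list)
    significant: bool = False


def score_test_p(x: np.ndarray, y: np.ndarray) -> float:
    """Logistic score test of a binary outcome on one continuous summary.

    Score U = sum x_i (y_i - ybar), variance ybar(1-ybar) * sum (x_i-xbar)^2,
    U^2/V ~ chi2(1) under the null.  Avoids the separation failures of full
    maximum likelihood at small n.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ybar = y.mean()
    ssx = ((x - x.mean()) ** 2).sum()
    if ssx == 0 or ybar in (0.0, 1.0):
        return 1.0
    u = float(x @ (y - ybar))
    v = ybar * (1 - ybar) * ssx
    return float(stats.chi2.sf(u * u / v, df=1))


def _representative(block: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """First principal component scores of the member profiles, sign-anchored
    to correlate positively with the anchor (the seed profile)."""
    if block.shape[1] == 1:
        return block[:, 0]
    centred = block - block.mean(axis=0)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    rep = u[:, 0] * s[0]
    if np.dot(rep - rep.mean(), anchor - anchor.mean()) < 0:
        rep = -rep
    return rep


def _score_p_matrix(R: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Score-test p for every (representative column, outcome column) pair.

    R is samples x c candidate representatives, Y is samples x b outcome
    vectors (all sharing the same mean, i.e. permutations of one outcome).
    """
    ybar = Y.mean(axis=0)  # identical across permutations
    Rc = R - R.mean(axis=0)
    ssx = (Rc ** 2).sum(axis=0)
    ssx[ssx == 0] = np.inf
    U = Rc.T @ (Y - ybar)  # c x b
    V = (ybar * (1 - ybar))[None, :] * ssx[:, None]
    with np.errstate(invalid="ignore"):
        return stats.chi2.sf(U ** 2 / V, df=1)


def find_modules(
    network: nx.Graph,
    scaled_by_tissue: Mapping[str, ScaledTable],
    samples: Sequence[SampleRecord],
    seed_nodes: Sequence[str] | None = None,
    alpha: float = 0.1,
    max_size: int = 15,
    expansion_edge_p: float | None = 0.01,
    plateau_factor: float = 2.0,
) -> list[ModuleResult]:
    """Greedy module expansion from each seed node.

    From every seed, a greedy path is walked over the strong-edge
    neighbourhood: at each step the network neighbours of the current member
    set are scored by the association p of the updated representative, and
    the best candidate (ties broken by smaller node index) is appended.  The
    walk continues across local plateaus up to ``max_size``.  The *reported*
    module is the longest path prefix that (a) beats every one of its
    members' single-node associations (a combination is only worth reporting
    while it is more informative than each constituent alone) and (b) stays
    within ``plateau_factor`` of the best p reached along the path: members
    added on the significance plateau carry association statistically
    indistinguishable from the optimum, and cutting exactly at the minimum
    would arbitrarily truncate the correlated set.  A singleton is reported
    when no prefix qualifies.

    Expansion walks only strong edges (partial-correlation p below
    ``expansion_edge_p``; None walks every network edge): at this sample
    size the p < 0.1 edge set is dominated by false edges, and a greedy
    minimisation over such candidate sets drifts through null neighbours
    purely by selection, inflating both module size and apparent
    significance.  The reported network itself keeps the p < 0.1 threshold.
    Modules with identical member sets are deduplicated; results are sorted
    by association p.
    """
    X, names, common = _stack_tissues(scaled_by_tissue)
    col = {nm: j for j, nm in enumerate(names)}
    pheno = {s.sample_id: s.phenotype for s in samples}
    y = np.array([1.0 if pheno[sid] == "T2D" else 0.0 for sid in common])
    order = {nm: j for j, nm in enumerate(names)}
    if seed_nodes is None:
        seed_nodes = names
    results: dict[frozenset, ModuleResult] = {}
    for seed in sorted(seed_nodes, key=lambda nm: order.get(nm, 1 << 30)):
        if seed not in col or seed not in network:
            raise MetmapError(f"seed node {seed!r} not in network/data")
        path = [seed]
        anchor = X[:, col[seed]]
        path_reps = [anchor]
        path_ps = [score_test_p(anchor, y)]
        while len(path) < max_size:
            neigh = set()
            for m in path:
                for nb in network.neighbors(m):
                    if (expansion_edge_p is None or
                            network.edges[m, nb]["p"] < expansion_edge_p):
                        neigh.add(nb)
            candidates = sorted(neigh - set(path), key=order.get)
            if not candidates:
                break
            reps = np.column_stack([
                _representative(X[:, [col[m] for m in path] + [col[c]]], anchor)
                for c in candidates])
            p_true = _score_p_matrix(reps, y[:, None])[:, 0]
            best_j = int(np.argmin(p_true))  # lowest index wins ties
            path.append(candidates[best_j])
            path_ps.append(float(p_true[best_j]))
            path_reps.append(reps[:, best_j])
        p_arr = np.asarray(path_ps)
        p_min = float(p_arr.min())
        node_singles = np.array([score_test_p(X[:, col[m]], y) for m in path])
        best_single_so_far = np.minimum.accumulate(node_singles)
        eligible = np.nonzero((p_arr <= plateau_factor * p_min)
                              & (p_arr < best_single_so_far))[0]
        cut = int(eligible.max()) if eligible.size else 0
        members = path[:cut + 1]
        p_cur = path_ps[cut]
        key = frozenset(members)
        if key not in results or results[key].association_p > p_cur:
            results[key] = ModuleResult(
                members=tuple(members), seed_node=seed,
                representative=path_reps[cut], association_p=p_cur,
                gain_trace=path_ps[:cut + 1], significant=p_cur < alpha)
    return sorted(results.values(), key=lambda m: (m.association_p, m.members))


def single_node_p(
    scaled_by_tissue: Mapping[str, ScaledTable],
    samples: Sequence[SampleRecord],
) -> dict[str, float]:
    """Logistic score-test p of each single node against the phenotype."""
    X, names, common = _stack_tissues(scaled_by_tissue)
    pheno = {s.sample_id: s.phenotype for s in samples}
    y = np.array([1.0 if pheno[sid] == "T2D" else 0.0 for sid in common])
    return {nm: score_test_p(X[:, j], y) for j, nm in enumerate(names)}


# ---------------------------------------------------------------------------
# scope summaries and export
# ---------------------------------------------------------------------------

def summarize_scopes(
    modules: Sequence[ModuleResult],
    network: nx.Graph,
    class_of: Mapping[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Tabulate intra- vs inter-tissue edges overall, per class and within
    significant modules.

    ``class_of`` maps metabolite id to curated class; cross-class edges are
    counted once under each endpoint class.
    """
    rows = []
    for a, b, attrs in network.edges(data=True):
        rows.append({
            "scope": attrs["scope"],
            "tissue_a": network.nodes[a]["tissue"],
            "tissue_b": network.nodes[b]["tissue"],
            "class_a": (class_of or {}).get(network.nodes[a]["metabolite"], "unknown"),
            "class_b": (class_of or {}).get(network.nodes[b]["metabolite"], "unknown"),
        })
    edges = pd.DataFrame(rows, columns=["scope", "tissue_a", "tissue_b",
                                        "class_a", "class_b"])
    overall = (edges.groupby("scope").size().rename("n_edges").reset_index()
               if len(edges) else
               pd.DataFrame(columns=["scope", "n_edges"]))
    by_class_rows = []
    if len(edges):
        melted = pd.concat([
            edges[["scope", "class_a"]].rename(columns={"class_a": "class"}),
            edges[["scope", "class_b"]].rename(columns={"class_b": "class"}),
        ])
        by_class_rows = (melted.groupby(["class", "scope"]).size()
                         .rename("n_edges").reset_index())
    by_class = (by_class_rows if len(edges)
                else pd.DataFrame(columns=["class", "scope", "n_edges"]))

    mod_rows = []
    for mod in modules:
        if not mod.significant:
            continue
        sub = network.subgraph(mod.members)
        for _, _, attrs in sub.edges(data=True):
            mod_rows.append({"module": "|".join(mod.members), "scope": attrs["scope"]})
    in_modules = (pd.DataFrame(mod_rows).groupby("scope").size()
                  .rename("n_edges").reset_index()
                  if mod_rows else pd.DataFrame(columns=["scope", "n_edges"]))
    return {"overall": overall, "by_class": by_class, "in_significant_modules": in_modules}


def inter_tissue_fraction(summary_by_class: pd.DataFrame, cls: str) -> float:
    """Fraction of a class's edges that are inter-tissue."""
    sub = summary_by_class[summary_by_class["class"] == cls]
    total = sub["n_edges"].sum()
    if total == 0:
        return float("nan")
    inter = sub.loc[sub["scope"] == "inter_tissue", "n_edges"].sum()
    return float(inter / total)


def write_network(network: nx.Graph, graphml_path, edges_tsv_path) -> None:
    """Export the network as GraphML plus a scope-labelled edge-list TSV."""
    nx.write_graphml(network, graphml_path)
    rows = [
        {"source": a, "target": b, "pcor": attrs["pcor"], "p": attrs["p"],
         "scope": attrs["scope"]}
        for a, b, attrs in network.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "pcor", "p", "scope"]).to_csv(
        edges_tsv_path, sep="\t", index=False, float_format="%.10g")


def modules_table(modules: Sequence[ModuleResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "members": ["|".join(m.members) for m in modules],
        "seed_node": [m.seed_node for m in modules],
        "size": [len(m.members) for m in modules],
        "association_p": [m.association_p for m in modules],
        "significant": [m.significant for m in modules],
    })
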