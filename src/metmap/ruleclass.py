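"""All-relevant feature selection and rough-set rule classification.

Selection follows the shadow-probe scheme: each iteration appends a shuffled
copy of every undecided feature, fits a random-forest importance model, and
scores a "hit" for features beating the best shadow importance; features are
confirmed or rejected by a Bonferroni-corrected binomial test on their hit
counts.  Confirmed features are discretized into low/average/high levels by
equal-frequency cuts, reduced to (approximate) minimal discerning attribute
subsets (Johnson greedy set cover over the discernibility structure, with an
exhaustive enumeration mode for small tables), turned into minimal IF-THEN
rules with support/accuracy/coverage bookkeeping, and applied by
support x accuracy weighted voting.  Rules are exportable as co-predictive
descriptor networks.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .errors import MetmapError

LEVELS_3 = ("low", "average", "high")
LEVELS_2 = ("low", "high")


# ---------------------------------------------------------------------------
# all-relevant selection (shadow probes)
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    confirmed: list[str]
    rejected: list[str]
    tentative: list[str]
    importance_history: pd.DataFrame


def select_all_relevant(
    X: pd.DataFrame,
    y: Sequence,
    max_iter: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    n_estimators: int = 500,
) -> SelectionResult:
    """Shadow-probe all-relevant feature selection.

    Parameters
    ----------
    X : samples x features DataFrame.
    y : class labels (>= 2 classes, >= 10 samples).
    max_iter : maximum testing rounds; undecided features end up tentative.
    alpha : two-sided binomial significance level, Bonferroni-corrected by
        the initial feature count.
    n_estimators : trees per round; importance is mean impurity decrease.
    """
    y = np.asarray(y)
    if X.shape[1] < 2:
        raise MetmapError("need at least 2 features")
    if len(np.unique(y)) < 2 or X.shape[0] < 10:
        raise MetmapError("need >= 2 classes and >= 10 samples")
    rng = np.random.default_rng(seed)
    features = list(X.columns)
    undecided = list(features)
    hits = {f: 0 for f in features}
    rounds = {f: 0 for f in features}
    confirmed: list[str] = []
    rejected: list[str] = []
    alpha_corr = alpha / len(features)
    history = []
    for it in range(1, max_iter + 1):
        if not undecided:
            break
        sub = X[undecided]
        shadow = sub.to_numpy().copy()
        for j in range(shadow.shape[1]):
            rng.shuffle(shadow[:, j])
        design = np.hstack([sub.to_numpy(), shadow])
        rf = RandomForestClassifier(
            n_estimators=n_estimators, max_features="sqrt",
            random_state=int(rng.integers(0, 2 ** 31 - 1)), n_jobs=1)
        rf.fit(design, y)
        imp = rf.feature_importances_
        real_imp = imp[:len(undecided)]
        shadow_max = imp[len(undecided):].max()
        for f, v in zip(undecided, real_imp):
            rounds[f] += 1
            if v > shadow_max:
                hits[f] += 1
            history.append({"iteration": it, "feature": f, "importance": float(v),
                            "shadow_max": float(shadow_max)})
        still = []
        for f in undecided:
            n, h = rounds[f], hits[f]
            if stats.binom.sf(h - 1, n, 0.5) < alpha_corr:
                confirmed.append(f)
            elif stats.binom.cdf(h, n, 0.5) < alpha_corr:
                rejected.append(f)
            else:
                still.append(f)
        undecided = still
    return SelectionResult(
        confirmed=confirmed, rejected=rejected, tentative=undecided,
        importance_history=pd.DataFrame(
            history, columns=["iteration", "feature", "importance", "shadow_max"]))


# ---------------------------------------------------------------------------
# decision tables
# ---------------------------------------------------------------------------

@dataclass
class DecisionTable:
    values: pd.DataFrame          # objects x attributes, level strings
    decision: pd.Series           # per-object class
    cut_points: dict[str, tuple[float, ...]]

    @property
    def objects(self) -> list:
        return list(self.values.index)

    @property
    def attributes(self) -> list[str]:
        return list(self.values.columns)


def _levels_for(n_cuts: int) -> tuple[str, ...]:
    return {0: ("average",), 1: LEVELS_2, 2: LEVELS_3}[n_cuts]


def apply_cuts(values: np.ndarray, cuts: Sequence[float]) -> np.ndarray:
    """Map numeric values to level strings given trained cut points.

    value <= first cut -> low; above last cut -> high.  Values beyond the
    training range simply land in the outer levels.
    """
    levels = _levels_for(len(cuts))
    idx = np.zeros(len(values), dtype=int)
    for c in cuts:
        idx += (np.asarray(values, dtype=float) > c).astype(int)
    return np.array([levels[i] for i in idx])


def discretize(
    X: pd.DataFrame,
    decision: Sequence,
    n_bins: int = 3,
    cut_points: Mapping[str, Sequence[float]] | None = None,
) -> DecisionTable:
    """Equal-frequency discretization into low/average/high levels.

    Cut points are computed on the given data (training) unless supplied, in
    which case they are applied unchanged (test-time use).  Attributes with
    too few distinct values for 3 bins fall back to 2 bins with a warning.
    """
    if n_bins not in (1, 2, 3):
        raise MetmapError("n_bins must be 1, 2 or 3")
    out = {}
    cuts_out: dict[str, tuple[float, ...]] = {}
    for colname in X.columns:
        col = X[colname].to_numpy(dtype=float)
        if cut_points is not None:
            cuts = tuple(cut_points[colname])
        else:
            if np.unique(col).size < 2 and n_bins > 1:
                raise MetmapError(f"attribute {colname!r} is constant")
            qs = [i / n_bins for i in range(1, n_bins)]
            cuts = tuple(np.quantile(col, qs)) if qs else ()
            if cuts and (len(cuts) != len(set(cuts))
                         or len(set(apply_cuts(col, cuts))) < n_bins):
                warnings.warn(
                    f"attribute {colname!r}: too few distinct values for "
                    f"{n_bins} bins; falling back to 2", stacklevel=2)
                cuts = (float(np.quantile(col, 0.5)),)
                if len(set(apply_cuts(col, cuts))) < 2:
                    cuts = ()
        cuts_out[colname] = cuts
        out[colname] = apply_cuts(col, cuts)
    return DecisionTable(
        values=pd.DataFrame(out, index=X.index),
        decision=pd.Series(list(decision), index=X.index, name="decision"),
        cut_points=cuts_out,
    )


# ---------------------------------------------------------------------------
# reducts
# ---------------------------------------------------------------------------

def _discernibility_pairs(table: DecisionTable) -> list[frozenset[int]]:
    """Attribute index sets discerning each object pair with different
    (generalized) decisions.  Pairs that are indiscernible over all
    attributes are excluded (their generalized decisions coincide)."""
    vals = table.values.to_numpy()
    dec = table.decision.to_numpy()
    n = vals.shape[0]
    pairs = []
    for i, j in itertools.combinations(range(n), 2):
        if dec[i] == dec[j]:
            continue
        diff = frozenset(np.nonzero(vals[i] != vals[j])[0])
        if diff:
            pairs.append(diff)
    return pairs


def _covers(subset: frozenset[int], pairs: Sequence[frozenset[int]]) -> bool:
    return all(subset & p for p in pairs)


def compute_reducts(
    table: DecisionTable,
    strategy: str = "johnson",
    seed: int | None = None,
    exhaustive_max_attrs: int = 12,
) -> list[tuple[str, ...]]:
    """Compute decision-relative reducts.

    ``johnson``: greedy set cover — repeatedly pick the attribute discerning
    the most not-yet-discerned pairs (ties by attribute index), then prune
    removable attributes so the result is irreducible.  Returns one reduct.

    ``exhaustive``: enumerate all minimal discerning subsets (tables up to
    ``exhaustive_max_attrs`` attributes).
    """
    if not len(table.values):
        raise MetmapError("empty decision table")
    attrs = table.attributes
    pairs = _discernibility_pairs(table)
    m = len(attrs)
    if not pairs:  # single class or totally inconsistent: all attrs redundant
        return [()]
    if strategy == "johnson":
        uncovered = list(pairs)
        chosen: list[int] = []
        while uncovered:
            counts = np.zeros(m, dtype=int)
            for p in uncovered:
                for a in p:
                    counts[a] += 1
            best = int(np.argmax(counts))  # argmax takes the lowest index on ties
            chosen.append(best)
            uncovered = [p for p in uncovered if best not in p]
        # prune: drop any attribute whose removal keeps full coverage
        for a in sorted(chosen):
            trial = frozenset(chosen) - {a}
            if trial and _covers(trial, pairs):
                chosen.remove(a)
        return [tuple(attrs[a] for a in sorted(chosen))]
    if strategy == "exhaustive":
        if m > exhaustive_max_attrs:
            raise MetmapError(
                f"exhaustive mode limited to {exhaustive_max_attrs} attributes")
        minimal: list[frozenset[int]] = []
        for size in range(1, m + 1):
            for combo in itertools.combinations(range(m), size):
                s = frozenset(combo)
                if any(r <= s for r in minimal):
                    continue
                if _covers(s, pairs):
                    minimal.append(s)
        return [tuple(attrs[a] for a in sorted(s)) for s in minimal]
    raise MetmapError(f"unknown reduct strategy {strategy!r}")


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rule:
    antecedent: frozenset  # of (attribute, level) descriptors
    decision_class: str
    support: int
    accuracy: float
    coverage: float

    def describe(self) -> str:
        conds = " AND ".join(f"{a}={lv}" for a, lv in sorted(self.antecedent))
        return (f"IF {conds} THEN {self.decision_class} "
                f"(support={self.support}, accuracy={self.accuracy:.2f}, "
                f"coverage={self.coverage:.2f})")


def _matches(antecedent: frozenset, row: Mapping) -> bool:
    return all(row[a] == lv for a, lv in antecedent)


def induce_rules(table: DecisionTable, reducts: Sequence[Sequence[str]]) -> list[Rule]:
    """Instantiate each object over each reduct into an IF-THEN rule.

    Identical (antecedent, decision) rules merge; support, accuracy and
    coverage are computed by direct counting over the table.
    """
    rows = table.values.to_dict("records")
    dec = list(table.decision)
    class_sizes = table.decision.value_counts().to_dict()
    seen: dict[tuple[frozenset, str], None] = {}
    for reduct in reducts:
        for row, d in zip(rows, dec):
            if not reduct:
                continue
            ant = frozenset((a, row[a]) for a in reduct)
            seen.setdefault((ant, str(d)), None)
    rules = []
    for ant, d in seen:
        match_idx = [i for i, row in enumerate(rows) if _matches(ant, row)]
        support = sum(1 for i in match_idx if str(dec[i]) == d)
        if support == 0:
            continue
        rules.append(Rule(
            antecedent=ant,
            decision_class=d,
            support=support,
            accuracy=support / len(match_idx),
            coverage=support / class_sizes[d],
        ))
    return sorted(rules, key=lambda r: (-r.support, sorted(r.antecedent), r.decision_class))


@dataclass
class ClassificationResult:
    predicted: str
    votes: dict[str, float]
    flag: str | None = None  # None, "no_rule" or "tie"


def classify(
    rules: Sequence[Rule],
    object_levels: Mapping[str, str],
    scheme: str = "support_weighted_voting",
    default_class: str | None = None,
) -> ClassificationResult:
    """Vote matching rules; weight = support x accuracy (or plain support).

    No matching rule falls back to the training majority class with the
    ``no_rule`` flag; tied tallies resolve to the lexicographically smaller
    class with the ``tie`` flag.
    """
    if scheme not in ("support_weighted_voting", "support"):
        raise MetmapError(f"unknown voting scheme {scheme!r}")
    votes: dict[str, float] = {}
    for rule in rules:
        if _matches(rule.antecedent, object_levels):
            w = rule.support * (rule.accuracy if scheme == "support_weighted_voting"
                                else 1.0)
            votes[rule.decision_class] = votes.get(rule.decision_class, 0.0) + w
    if not votes:
        if default_class is None:
            raise MetmapError("no rule fired and no default class provided")
        return ClassificationResult(default_class, votes, flag="no_rule")
    top = max(votes.values())
    winners = sorted(c for c, v in votes.items() if v == top)
    flag = "tie" if len(winners) > 1 else None
    return ClassificationResult(winners[0], votes, flag=flag)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def crossvalidate(
    X: pd.DataFrame,
    y: Sequence,
    k: int = 10,
    seed: int = 0,
    selection: bool = False,
    selection_kwargs: Mapping | None = None,
    n_bins: int = 3,
    reduct_strategy: str = "johnson",
    scheme: str = "support_weighted_voting",
) -> dict:
    """Stratified k-fold CV of the full discretize/reduct/rule chain.

    The chain (optionally including shadow-probe selection) is refit inside
    every training fold; test objects are discretized with the fold's
    training cut points.  Returns overall, per-fold and per-class accuracy.
    """
    y = pd.Series(list(y), index=X.index, name="decision").astype(str)
    class_counts = y.value_counts()
    k_eff = min(k, int(class_counts.min()))
    if k_eff < k:
        warnings.warn(f"class with {class_counts.min()} members: k reduced "
                      f"from {k} to {k_eff}", stacklevel=2)
    if k_eff < 2:
        raise MetmapError("smallest class too small for cross-validation")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    fold_acc, per_class_hits, per_class_tot = [], {}, {}
    predictions = pd.Series(index=X.index, dtype=object)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        X_tr, y_tr = X.iloc[tr], y.iloc[tr]
        X_te, y_te = X.iloc[te], y.iloc[te]
        feats = list(X.columns)
        if selection:
            sel = select_all_relevant(X_tr, y_tr, seed=seed + fold,
                                      **dict(selection_kwargs or {}))
            if sel.confirmed:
                feats = sel.confirmed
        table = discretize(X_tr[feats], y_tr, n_bins=n_bins)
        reducts = compute_reducts(table, strategy=reduct_strategy)
        rules = induce_rules(table, reducts)
        majority = y_tr.value_counts().index[0]
        test_table = discretize(X_te[feats], y_te, n_bins=n_bins,
                                cut_points=table.cut_points)
        hits = 0
        for oid in X_te.index:
            levels = test_table.values.loc[oid].to_dict()
            res = classify(rules, levels, scheme=scheme, default_class=majority)
            predictions[oid] = res.predicted
            truth = y_te[oid]
            per_class_tot[truth] = per_class_tot.get(truth, 0) + 1
            if res.predicted == truth:
                hits += 1
                per_class_hits[truth] = per_class_hits.get(truth, 0) + 1
        fold_acc.append(hits / len(te))
    per_class = {c: per_class_hits.get(c, 0) / per_class_tot[c]
                 for c in per_class_tot}
    overall = float(np.mean([  # sample-weighted overall accuracy
        (predictions == y).mean()]))
    return {
        "accuracy": overall,
        "fold_accuracy": [float(a) for a in fold_acc],
        "per_class_accuracy": {str(c): float(v) for c, v in per_class.items()},
        "k": k_eff,
        "seed": seed,
        "predictions": predictions,
    }


# ---------------------------------------------------------------------------
# rule networks
# ---------------------------------------------------------------------------

def build_rule_network(rules: Sequence[Rule], min_support: int = 1,
                       ) -> dict[str, nx.Graph]:
    """Per-decision-class descriptor co-occurrence graphs.

    Nodes are ``attribute=level`` descriptors; two descriptors are linked if
    they co-occur in at least one rule (with support >= min_support), with
    edge weight the sum of supports of the shared rules.
    """
    if not rules:
        raise MetmapError("no rules to build a network from")
    nets: dict[str, nx.Graph] = {}
    for rule in rules:
        if rule.support < min_support:
            continue
        g = nets.setdefault(rule.decision_class, nx.Graph())
        descs = sorted(f"{a}={lv}" for a, lv in rule.antecedent)
        g.add_nodes_from(descs)
        for d1, d2 in itertools.combinations(descs, 2):
            w = g.edges[d1, d2]["weight"] if g.has_edge(d1, d2) else 0
            g.add_edge(d1, d2, weight=w + rule.support)
    return nets


def rules_table(rules: Sequence[Rule]) -> pd.DataFrame:
    return pd.DataFrame({
        "antecedent": [" AND ".join(f"{a}={lv}" for a, lv in sorted(r.antecedent))
                       for r in rules],
        "decision_class": [r.decision_class for r in rules],
        "support": [r.support for r in rules],
        "accuracy": [r.accuracy for r in rules],
        "coverage": [r.coverage for r in rules],
    })
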