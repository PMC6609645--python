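"""Overrepresentation of metabolite classes, pathways and biological roles.

Given the per-tissue set of significant metabolites and the per-tissue
background (every metabolite detected after filtering in that tissue), each
annotation term is tested with the one-sided hypergeometric upper tail
(equivalently a one-sided Fisher exact test); Benjamini-Hochberg adjustment
is applied within (term type x tissue).  Reported p-values are floored at
the smallest positive double rather than 0.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import MetmapError
from .ingest_annotate import MetaboliteRecord

_P_FLOOR = np.nextafter(0, 1)

TERM_TYPES = ("class", "pathway", "role")

_COLUMNS = ["term", "term_type", "tissue", "k", "K", "n", "N", "p", "fdr_p"]


def overrepresentation(
    significant_ids: Iterable[str],
    background_ids: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    term_type: str = "class",
    tissue: str | None = None,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of each term among the significant set.

    With N background metabolites, K of them in the term, and n significant,
    p = P(X >= k) for X hypergeometric; terms without background members are
    skipped.  fdr_p is the BH adjustment across the tested terms.
    """
    background = set(background_ids)
    if not background:
        raise MetmapError("empty background")
    significant = set(significant_ids)
    if not significant <= background:
        extra = sorted(significant - background)[:5]
        raise MetmapError(f"significant ids outside background, e.g. {extra}")
    N, n = len(background), len(significant)
    rows = []
    for term in sorted(term_map):
        members = set(term_map[term]) & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & significant)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, term_type, tissue, k, K, n, N, max(p, _P_FLOOR)))
    df = pd.DataFrame(rows, columns=_COLUMNS[:-1])
    if len(df):
        df["fdr_p"] = np.maximum(multipletests(df["p"], method="fdr_bh")[1], df["p"])
        df = df.sort_values(["p", "term"], ignore_index=True)
    else:
        df["fdr_p"] = []
    return df


def build_term_maps(annotations: Sequence[MetaboliteRecord]) -> dict[str, dict[str, set[str]]]:
    """Term -> member-id maps for classes, sub-classes, pathways and roles.

    Sub-class labels (LPC, carnitine, BCAA, ...) are folded into the
    ``class`` vocabulary so that both granularities are tested.
    """
    class_map: dict[str, set[str]] = {}
    pathway_map: dict[str, set[str]] = {}
    role_map: dict[str, set[str]] = {}
    for rec in annotations:
        class_map.setdefault(rec.curated_class, set()).add(rec.local_id)
        if rec.sub_class:
            class_map.setdefault(rec.sub_class, set()).add(rec.local_id)
        for pw in rec.pathways:
            pathway_map.setdefault(pw, set()).add(rec.local_id)
        for role in rec.biological_roles:
            role_map.setdefault(role, set()).add(rec.local_id)
    return {"class": class_map, "pathway": pathway_map, "role": role_map}


def enrich_all(
    diff_results: pd.DataFrame,
    annotations: Sequence[MetaboliteRecord],
) -> pd.DataFrame:
    """Run class/pathway/role overrepresentation per tissue.

    ``diff_results`` is the long differential-screen table (needs columns
    metabolite_id, tissue, significant); the background for each tissue is
    the set of metabolites tested there.  Tissues with no significant
    metabolites yield no rows (noted via an attrs note on the result).
    """
    maps = build_term_maps(annotations)
    frames, empty_tissues = [], []
    for tissue, sub in diff_results.groupby("tissue"):
        background = set(sub["metabolite_id"])
        significant = set(sub.loc[sub["significant"], "metabolite_id"])
        if not significant:
            empty_tissues.append(tissue)
            continue
        for term_type in TERM_TYPES:
            frames.append(overrepresentation(
                significant, background, maps[term_type],
                term_type=term_type, tissue=tissue))
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=_COLUMNS))
    out.attrs["tissues_without_significant"] = empty_tissues
    return out
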