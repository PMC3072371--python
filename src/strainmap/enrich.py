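"""Gene-set over-representation with EASE-style conservative tails and
kappa-based annotation clustering.

For a query of n genes against a set of X genes in a background of N, the
nominal P is the hypergeometric upper tail P(overlap >= x); EASE mode
removes one observed gene (tail from x - 1), which penalizes sets whose
evidence rests on a single gene. Terms are clustered by Cohen's kappa of
their gene-membership agreement, and each cluster is summarized by an
enrichment score, the mean of -log10 nominal P over member terms (the
-log10 of their geometric mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import GeneSetCollection

log = logging.getLogger("strainmap.enrich")


# ------------------------------------------------------------------- tails

def hypergeom_tail(x: int, n: int, X: int, N: int) -> float:
    """P(overlap >= x) drawing n from N with X marked."""
    if x <= 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, X, n))


def ease_tail(x: int, n: int, X: int, N: int) -> float:
    """EASE score: hypergeometric tail with one observed gene removed."""
    return hypergeom_tail(max(x - 1, 0), n, X, N)


def fold_enrichment(x: int, n: int, X: int, N: int) -> float:
    """FE = (x/n) / (X/N); NaN (flagged undefined) when X == 0."""
    if n <= 0 or N <= 0:
        raise ValueError("n and N must be positive")
    if X == 0:
        log.warning("fold enrichment undefined for empty set (X=0)")
        return float("nan")
    return (x / n) / (X / N)


# ---------------------------------------------------------------- results

@dataclass
class EnrichmentResult:
    term: str
    description: str
    x: int                         # query ∩ set
    n: int                         # query size (mapped to background)
    X: int                         # set size in background
    N: int                         # background size
    p_nominal: float
    p_bonferroni: float
    fold_enrichment: float
    pct: float                     # 100 * x / n
    captured_fraction: float       # x / X, the "fraction of the category"


def set_enrichment(query_genes: Iterable, sets: GeneSetCollection,
                   background: Optional[Iterable] = None,
                   mode: str = "ease") -> list[EnrichmentResult]:
    """Over-representation of each gene set in the query.

    Query and sets are intersected with the background first; only sets
    with x >= 1 are reported; Bonferroni correction is over the tested
    sets. mode: "ease" (default, conservative) or "hypergeometric".
    """
    if mode not in ("ease", "hypergeometric"):
        raise ValueError(f"unknown mode: {mode}")
    bg = set(background) if background is not None else set(sets.universe)
    if not bg:
        raise ValueError("empty background")
    query = set(query_genes) & bg
    n, N = len(query), len(bg)
    tail = ease_tail if mode == "ease" else hypergeom_tail

    tested = []
    for term, members in sets.sets.items():
        mem = members & bg
        x = len(query & mem)
        if x < 1:
            continue
        X = len(mem)
        p = tail(x, n, X, N)
        tested.append(EnrichmentResult(
            term=term, description=sets.descriptions.get(term, ""),
            x=x, n=n, X=X, N=N, p_nominal=p, p_bonferroni=np.nan,
            fold_enrichment=fold_enrichment(x, n, X, N),
            pct=100.0 * x / n if n else 0.0,
            captured_fraction=x / X if X else float("nan"),
        ))
    m = len(tested)
    for r in tested:
        r.p_bonferroni = min(1.0, r.p_nominal * m)
    tested.sort(key=lambda r: (r.p_nominal, r.term))
    return tested


def neighborhood_enrichment(neighborhood_genes: Iterable, category_set: set,
                            module_genes: Iterable,
                            mode: str = "hypergeometric") -> EnrichmentResult:
    """Enrichment of one category within a module, with the module (not
    the whole array) as background; reports the captured fraction x/X
    alongside P."""
    bg = set(module_genes)
    neigh = set(neighborhood_genes)
    if not neigh <= bg:
        raise ValueError("neighborhood genes must be a subset of the module "
                         "background")
    coll = GeneSetCollection(sets={"category": set(category_set) & bg},
                             descriptions={"category": ""}, universe=bg)
    res = set_enrichment(neigh, coll, background=bg, mode=mode)
    if not res:
        X = len(set(category_set) & bg)
        return EnrichmentResult(term="category", description="", x=0,
                                n=len(neigh), X=X, N=len(bg), p_nominal=1.0,
                                p_bonferroni=1.0,
                                fold_enrichment=0.0 if X else float("nan"),
                                pct=0.0, captured_fraction=0.0)
    return res[0]


# ----------------------------------------------------------------- kappa

def cohens_kappa(members_a: set, members_b: set, background: set) -> float:
    """Cohen's kappa of the 2x2 gene-membership agreement over the
    background."""
    N = len(background)
    if N == 0:
        raise ValueError("empty background")
    A = members_a & background
    B = members_b & background
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = N - a - b - c
    po = (a + d) / N
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (N * N)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def enrichment_score(p_values: Sequence[float]) -> float:
    """Mean -log10 nominal P over a cluster's terms (equivalently the
    -log10 of their geometric mean)."""
    p = np.asarray(list(p_values), float)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]; floor zeros upstream")
    return float(np.mean(-np.log10(p)))


@dataclass
class TermCluster:
    terms: list
    enrichment_score: float
    significant: bool
    kappa_matrix: Optional[pd.DataFrame] = None


def kappa_cluster(results: list[EnrichmentResult], sets: GeneSetCollection,
                  background: Optional[set] = None, kappa_min: float = 0.35,
                  link_frac: float = 0.5,
                  es_min: float = 3.0) -> list[TermCluster]:
    """Greedy agglomeration of enriched terms by membership kappa.

    Seed groups are term pairs with kappa >= kappa_min; groups sharing
    >= link_frac of their (smaller) membership merge, iterating to a
    fixed point. Clusters may overlap (terms can seed several pairs, and
    singletons stand alone). Deterministic: terms are pre-sorted by
    nominal P then name.
    """
    bg = set(background) if background is not None else set(sets.universe)
    ordered = sorted(results, key=lambda r: (r.p_nominal, r.term))
    terms = [r.term for r in ordered]
    p_of = {r.term: r.p_nominal for r in ordered}
    members = {t: sets.sets[t] & bg for t in terms}

    kap = pd.DataFrame(np.eye(len(terms)), index=terms, columns=terms)
    for i, a in enumerate(terms):
        for b in terms[i + 1:]:
            k = cohens_kappa(members[a], members[b], bg)
            kap.loc[a, b] = kap.loc[b, a] = k

    groups: list[set] = []
    clustered = set()
    for i, a in enumerate(terms):
        for b in terms[i + 1:]:
            if kap.loc[a, b] >= kappa_min:
                groups.append({a, b})
                clustered |= {a, b}
    # merge groups sharing >= link_frac of the smaller group's terms
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                shared = len(groups[i] & groups[j])
                if shared and shared / min(len(groups[i]), len(groups[j])) >= link_frac:
                    groups[i] |= groups[j]
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    # deduplicate identical groups, keep singletons for unclustered terms
    uniq = []
    for g in groups:
        if g not in uniq:
            uniq.append(g)
    for t in terms:
        if t not in clustered:
            uniq.append({t})

    clusters = []
    for g in uniq:
        ordered_terms = sorted(g, key=lambda t: (p_of[t], t))
        es = enrichment_score([p_of[t] for t in ordered_terms])
        clusters.append(TermCluster(
            terms=ordered_terms, enrichment_score=es,
            significant=bool(es > es_min),
            kappa_matrix=kap.loc[ordered_terms, ordered_terms],
        ))
    clusters.sort(key=lambda c: -c.enrichment_score)
    return clusters
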