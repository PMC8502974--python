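"""Comparative-transcriptomics stage: DEG thresholding, core-gene
intersection, overrepresentation analysis, GSEA and enrichment maps.

All statistics are computed from first principles on in-memory DE
tables and gene-set collections:

* **Thresholding** uses strict cuts (q < q_max, |log2FC| > cut),
  mirroring FDR-based DEG calling.
* **ORA** tests a query gene set against each annotated set within a
  universe by the upper-tail hypergeometric probability
  ``P(X >= k | N, K, n)``, BH-adjusted across sets.
* **GSEA** is the weighted Kolmogorov-Smirnov running sum over a ranked
  gene list: hit increments proportional to |score|^w normalized over
  the set's hits, miss decrement 1/(N - Nh); the enrichment score ES is
  the maximum-magnitude deviation, NES normalizes by the mean
  magnitude of same-sign gene-label-permutation scores, and nominal
  p / FDR come from the permutation null.
* **Enrichment maps** connect surviving sets whose combined
  Overlap+Jaccard similarity ``k*O + (1-k)*J`` reaches the cutoff
  (inclusive); clusters are the connected components.

Gene symbols are case-normalized to upper case before any set
operation (mouse and human symbol casing differs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

from .iolib import DegRecord, GeneSet, ValidationError
from .stats import bh_fdr

__all__ = [
    "OraResult",
    "GseaResult",
    "SimilarityEdge",
    "threshold_degs",
    "core_deg_intersection",
    "overrepresentation",
    "gsea",
    "gsea_batch",
    "set_similarity",
    "enrichment_map",
]


def _norm(genes: Iterable[str]) -> frozenset[str]:
    return frozenset(g.upper() for g in genes)


@dataclass(frozen=True)
class OraResult:
    """One overrepresentation test: overlap k of a size-n query with a
    size-K set inside a size-N universe."""

    name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float
    overlap_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValidationError("overlap exceeds set or query size")


@dataclass(frozen=True)
class GseaResult:
    """Enrichment of one gene set along a ranked list."""

    name: str
    ES: float
    NES: float
    nominal_p: float
    FDR: float
    leading_edge: tuple[str, ...]
    n_hits: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.ES <= 1.0 + 1e-9:
            raise ValidationError("ES outside [-1, 1]")
        if self.NES * self.ES < 0:
            raise ValidationError("NES and ES must share a sign")


@dataclass(frozen=True)
class SimilarityEdge:
    """Pairwise gene-set similarity: Jaccard J, overlap coefficient O
    and the combined score k*O + (1-k)*J."""

    set_a: str
    set_b: str
    jaccard: float
    overlap: float
    combined: float

    def __post_init__(self) -> None:
        if self.overlap < self.jaccard - 1e-12:
            raise ValidationError("overlap coefficient must be >= Jaccard")


def threshold_degs(
    table: Sequence[DegRecord],
    q_max: float = 0.05,
    min_abs_log2fc: float = 0.0,
) -> frozenset[str]:
    """Genes with q < q_max and |log2FC| > min_abs_log2fc (both strict)."""
    return _norm(
        r.gene
        for r in table
        if r.qvalue < q_max and abs(r.log2fc) > min_abs_log2fc
    )


def core_deg_intersection(
    strong_a: Iterable[str], all_b: Iterable[str]
) -> frozenset[str]:
    """Exact intersection of two gene lists, case-normalized."""
    return _norm(strong_a) & _norm(all_b)


def overrepresentation(
    query: Iterable[str],
    sets: Sequence[GeneSet],
    universe: Iterable[str],
    q_cut: float = 0.05,
    top: int | None = None,
) -> list[OraResult]:
    """Hypergeometric overrepresentation of ``query`` in each gene set.

    Each set is intersected with the universe before testing;
    ``p = P(X >= k)`` with N = |universe|, K = |set & universe|,
    n = |query|; q-values are BH across all tested sets.  Results are
    ranked by decreasing -log10(q) (ties broken by p); ``top`` limits
    the output (e.g. the ten most enriched terms).
    """
    uni = _norm(universe)
    qry = _norm(query)
    if not qry <= uni:
        raise ValidationError("query must be a subset of the universe")
    N, n = len(uni), len(qry)
    rows = []
    for gs in sets:
        members = gs.as_set() & uni if not isinstance(gs, frozenset) else gs & uni
        members = _norm(members)
        K = len(members)
        if K == 0:
            continue
        hit = qry & members
        k = len(hit)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append((gs.name, k, K, tuple(sorted(hit)), min(1.0, p)))
    if not rows:
        return []
    qvals = bh_fdr([r[4] for r in rows])
    out = [
        OraResult(name=name, k=k, K=K, n=n, N=N, p=p, q=float(q),
                  overlap_genes=hit)
        for (name, k, K, hit, p), q in zip(rows, qvals)
    ]
    out.sort(key=lambda r: (r.q, r.p, r.name))
    if top is not None:
        out = out[:top]
    return out


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------


def _running_es(
    scores: np.ndarray, hit_mask: np.ndarray, weight: float
) -> tuple[float, int]:
    """Weighted KS running-sum enrichment score and its extremum index.

    Hits increment by |score|^weight normalized over the hits; misses
    decrement by 1/(N - Nh).  Returns (ES, index of the extremum).
    """
    n = len(scores)
    nh = int(hit_mask.sum())
    w = np.abs(scores) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all-zero hit scores: fall back to unweighted hits
        hit_w = hit_mask.astype(float)
        denom = hit_w.sum()
    miss = np.where(hit_mask, 0.0, 1.0 / (n - nh)) if n > nh else np.zeros(n)
    running = np.cumsum(hit_w / denom - miss)
    i_ext = int(np.argmax(np.abs(running)))
    return float(running[i_ext]), i_ext


def _rank_table(ranked: Mapping[str, float] | Sequence[tuple[str, float]]):
    items = list(ranked.items()) if isinstance(ranked, Mapping) else list(ranked)
    genes = [g.upper() for g, _ in items]
    if len(set(genes)) != len(genes):
        raise ValidationError("ranked list has duplicate genes")
    scores = np.array([float(s) for _, s in items])
    order = np.argsort(-scores, kind="mergesort")
    return [genes[i] for i in order], scores[order]


def gsea(
    ranked: Mapping[str, float] | Sequence[tuple[str, float]],
    geneset: GeneSet,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """GSEA of one gene set against a gene -> score ranked list.

    The list is sorted by decreasing score; the null is gene-label
    permutation (hit positions re-drawn uniformly), appropriate for a
    pipeline that consumes pre-ranked lists rather than sample-level
    expression.  NES = ES / mean(|permutation ES| of matching sign);
    nominal p is the same-sign permutation tail frequency (add-one
    smoothed).  With a single set the permutation FDR reduces to the
    nominal p.
    """
    res = gsea_batch(ranked, [geneset], weight_p=weight_p, n_perm=n_perm,
                     seed=seed)
    return res[0]


def gsea_batch(
    ranked: Mapping[str, float] | Sequence[tuple[str, float]],
    sets: Sequence[GeneSet],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[GseaResult]:
    """GSEA over a collection of sets with a pooled permutation FDR.

    FDR(NES*) follows the standard convention: the fraction of pooled
    same-sign permutation NES values at least as extreme as NES*,
    divided by the fraction of observed same-sign NES values at least
    as extreme, clipped to [0, 1].
    """
    genes, scores = _rank_table(ranked)
    n = len(genes)
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    per_set = []
    for gs in sets:
        hits = sorted(pos[g] for g in _norm(gs.members) if g in pos)
        if not hits:
            raise ValidationError(
                f"gene set {gs.name!r} has no members in the ranked list"
            )
        hit_mask = np.zeros(n, dtype=bool)
        hit_mask[hits] = True
        es, i_ext = _running_es(scores, hit_mask, weight_p)
        if es >= 0:
            lead = [genes[i] for i in hits if i <= i_ext]
        else:
            lead = [genes[i] for i in hits if i > i_ext]
        nh = len(hits)
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=nh, replace=False)] = True
            perm_es[b], _ = _running_es(scores, mask, weight_p)
        same = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        if same.size:
            nominal_p = (1 + int(np.sum(np.abs(same) >= abs(es)))) / (1 + same.size)
            mean_mag = float(np.mean(np.abs(same)))
        else:
            nominal_p, mean_mag = 1.0, 0.0
        nes = es / mean_mag if mean_mag > 0 else 0.0
        per_set.append(
            dict(name=gs.name, es=es, nes=nes, p=float(nominal_p),
                 lead=tuple(lead), nh=nh, perm_es=perm_es)
        )

    # pooled FDR over permutation NES (each set's permutations normalized
    # by that set's same-sign mean magnitude)
    pooled: list[float] = []
    for d in per_set:
        pe = d["perm_es"]
        for sign in (1.0, -1.0):
            sel = pe[np.sign(pe) == sign]
            if sel.size:
                pooled.extend((sel / np.mean(np.abs(sel))).tolist())
    pooled_arr = np.asarray(pooled)
    obs_nes = np.asarray([d["nes"] for d in per_set])

    out = []
    for d in per_set:
        nes = d["nes"]
        if nes == 0 or pooled_arr.size == 0:
            fdr = 1.0
        else:
            sign = np.sign(nes)
            pool_same = pooled_arr[np.sign(pooled_arr) == sign]
            obs_same = obs_nes[np.sign(obs_nes) == sign]
            num = (
                np.mean(np.abs(pool_same) >= abs(nes)) if pool_same.size else 0.0
            )
            den = np.mean(np.abs(obs_same) >= abs(nes)) if obs_same.size else 1.0
            fdr = float(np.clip(num / den if den > 0 else 1.0, 0.0, 1.0))
        out.append(
            GseaResult(
                name=d["name"], ES=d["es"], NES=float(d["nes"]),
                nominal_p=d["p"], FDR=fdr, leading_edge=d["lead"],
                n_hits=d["nh"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# enrichment map
# ---------------------------------------------------------------------------


def set_similarity(a: Iterable[str], b: Iterable[str],
                   combine_k: float = 0.5) -> SimilarityEdge:
    """Jaccard, overlap coefficient and their combination for two sets."""
    sa, sb = _norm(a), _norm(b)
    inter = len(sa & sb)
    union = len(sa | sb)
    j = inter / union if union else 0.0
    o = inter / min(len(sa), len(sb)) if sa and sb else 0.0
    return SimilarityEdge(
        set_a="", set_b="", jaccard=j, overlap=o,
        combined=combine_k * o + (1.0 - combine_k) * j,
    )


def enrichment_map(
    results: Sequence[GseaResult],
    sets: Mapping[str, GeneSet] | Sequence[GeneSet],
    similarity_cutoff: float = 0.375,
    combine_k: float = 0.5,
    p_cut: float = 0.05,
    fdr_cut: float = 0.25,
) -> nx.Graph:
    """Similarity network of significantly enriched gene sets.

    Results are filtered to nominal p < ``p_cut`` and FDR < ``fdr_cut``;
    each surviving set becomes a node (attributes: NES, FDR, size) and
    two nodes are joined when their combined Overlap+Jaccard score
    reaches ``similarity_cutoff`` (inclusive).  Connected components
    are the pathway clusters; component ids are stored on the nodes.
    """
    if not isinstance(sets, Mapping):
        sets = {gs.name: gs for gs in sets}
    g = nx.Graph()
    surviving = [
        r for r in results if r.nominal_p < p_cut and r.FDR < fdr_cut
    ]
    for r in surviving:
        if r.name not in sets:
            raise ValidationError(f"no gene set named {r.name!r}")
        g.add_node(r.name, NES=r.NES, FDR=r.FDR, size=len(sets[r.name]))
    for i, ra in enumerate(surviving):
        for rb in surviving[i + 1 :]:
            sim = set_similarity(
                sets[ra.name].members, sets[rb.name].members, combine_k
            )
            if sim.combined >= similarity_cutoff:
                g.add_edge(
                    ra.name, rb.name,
                    jaccard=sim.jaccard, overlap=sim.overlap,
                    combined=sim.combined,
                )
    for cid, comp in enumerate(sorted(nx.connected_components(g), key=sorted)):
        for node in comp:
            g.nodes[node]["cluster"] = cid
    return g
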