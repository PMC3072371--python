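"""Weighted gene co-expression network construction and module detection.

The adjacency between genes i and j is |cor(x_i, x_j)|^beta (unsigned
network, Pearson correlation), with beta chosen by the scale-free topology
criterion. Topological overlap

    w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu * a_uj,

measures shared neighborhoods; 1 - TOM is the dissimilarity for
average-linkage hierarchical clustering. Modules come from a deterministic
three-stage branch cut: a static cut of the dendrogram, nearest-module
assignment of leftover genes, and iterative merging of modules whose
eigengenes (first principal component of module expression) are highly
correlated. Unassigned genes are labeled "grey".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .types import ExpressionMatrix

log = logging.getLogger("strainmap.coexnet")

MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]
GREY = "grey"


# --------------------------------------------------------------- adjacency

def adjacency_matrix(expr_values: np.ndarray, beta: int,
                     signed: bool = False) -> np.ndarray:
    """Soft-thresholded adjacency from a genes x samples value matrix.

    Unsigned: |cor|^beta; signed variant: ((1 + cor)/2)^beta. The
    self-adjacency a_ii is set to 0 so connectivity sums exclude self.
    """
    C = np.corrcoef(expr_values)
    C = np.nan_to_num(C, nan=0.0)
    A = (((1.0 + C) / 2.0) ** beta) if signed else (np.abs(C) ** beta)
    np.fill_diagonal(A, 0.0)
    return A


def k_total(adjacency: np.ndarray) -> np.ndarray:
    return adjacency.sum(axis=1)


# -------------------------------------------------------------- soft power

@dataclass
class SoftPowerFit:
    beta: int
    table: pd.DataFrame            # power, signed_r2, slope, mean_k
    reached_target: bool


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit of a connectivity vector.

    log10(bin frequency) is regressed on log10(bin mean k) over 10
    equal-width bins of log10(k); returns (signed R^2, slope), the sign
    flipped when the slope is positive (a scale-free degree distribution
    has a negative slope).
    """
    k = np.asarray(k, float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(np.log10(k)) == 0:
        return 0.0, 0.0
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max(), n_bins + 1)
    idx = np.clip(np.digitize(logk, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(np.mean(k[sel])))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    yhat = slope * np.asarray(xs) + intercept
    ss_res = float(np.sum((np.asarray(ys) - yhat) ** 2))
    ss_tot = float(np.sum((np.asarray(ys) - np.mean(ys)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return (-r2 if slope > 0 else r2), float(slope)


def pick_soft_power(expr_values: np.ndarray, powers=range(1, 21),
                    target_r2: float = 0.8,
                    signed: bool = False) -> SoftPowerFit:
    """Smallest power whose signed scale-free fit reaches target_r2;
    falls back to the best fit with a warning when none qualifies."""
    if expr_values.shape[0] < 20:
        raise ValueError("soft-power selection needs >= 20 genes "
                         "(log-binning is unstable below that)")
    C = np.corrcoef(expr_values)
    C = np.nan_to_num(C, nan=0.0)
    base = ((1.0 + C) / 2.0) if signed else np.abs(C)
    np.fill_diagonal(base, 0.0)
    rows = []
    chosen = None
    for b in powers:
        A = base ** b
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=1)
        fit, slope = scale_free_fit(k)
        rows.append((int(b), fit, slope, float(k.mean())))
        if chosen is None and fit >= target_r2:
            chosen = int(b)
    table = pd.DataFrame(rows, columns=["power", "signed_r2", "slope", "mean_k"])
    if chosen is None:
        chosen = int(table.loc[table["signed_r2"].idxmax(), "power"])
        log.warning("no power reached scale-free fit %.2f; using argmax "
                    "beta=%d (fit=%.3f)", target_r2, chosen,
                    table["signed_r2"].max())
        return SoftPowerFit(beta=chosen, table=table, reached_target=False)
    return SoftPowerFit(beta=chosen, table=table, reached_target=True)


# -------------------------------------------------------------------- TOM

def tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix; w_ii := 1 by convention."""
    A = np.asarray(adjacency, float)
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A                       # l_ij over u != i, j since a_ii = 0
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        W = (L + A) / denom
    W = np.nan_to_num(W, nan=0.0)
    np.fill_diagonal(W, 1.0)
    return W


# ----------------------------------------------------------------- modules

def module_eigengene(expr_values: np.ndarray,
                     member_idx: np.ndarray) -> np.ndarray:
    """First principal-component sample score of a module, sign-oriented
    so its mean correlation with member genes is positive."""
    X = expr_values[member_idx]
    Xs = X - X.mean(axis=1, keepdims=True)
    sd = Xs.std(axis=1)
    sd[sd == 0] = 1.0
    Xs = Xs / sd[:, None]
    # samples x genes SVD; first left-singular vector of samples
    U, S, Vt = np.linalg.svd(Xs.T, full_matrices=False)
    e = U[:, 0]
    cors = np.array([np.corrcoef(e, row)[0, 1] for row in Xs])
    if np.nanmean(cors) < 0:
        e = -e
    return e


@dataclass
class ModuleDetection:
    labels: np.ndarray             # color per gene
    dendrogram: np.ndarray         # scipy linkage matrix
    cut_height: float
    eigengenes: dict               # color -> sample score vector
    merge_trace: list = field(default_factory=list)


def detect_modules(d: np.ndarray, expr_values: np.ndarray,
                   min_size: int = 30, cut_height_q: float = 0.99,
                   merge_diss: float = 0.25) -> ModuleDetection:
    """Three-stage deterministic branch cut on a TOM dissimilarity.

    1. average-linkage dendrogram cut at the cut_height_q quantile of merge
       heights; branches below min_size stay unassigned;
    2. each unassigned gene joins the module with the smallest mean
       dissimilarity to its members, provided that mean is below the gene's
       mean dissimilarity to all assigned genes;
    3. modules whose eigengene dissimilarity (1 - correlation) is below
       merge_diss are merged, iterating to a fixed point; labels are
       reassigned by decreasing size along a fixed color list.
    """
    n = d.shape[0]
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity must be symmetric")
    dz = d.copy()
    np.fill_diagonal(dz, 0.0)
    Zlink = linkage(squareform(dz, checks=False), method="average")
    if min_size > n:
        log.warning("min_size %d exceeds gene count %d: all grey", min_size, n)
        return ModuleDetection(labels=np.array([GREY] * n, dtype=object),
                               dendrogram=Zlink, cut_height=np.nan,
                               eigengenes={})
    cut = float(np.quantile(Zlink[:, 2], cut_height_q))
    raw = fcluster(Zlink, t=cut, criterion="distance")

    # stage 1: branches >= min_size become provisional modules
    assign = np.full(n, -1, dtype=int)
    next_id = 0
    for lbl in np.unique(raw):
        members = np.flatnonzero(raw == lbl)
        if members.size >= min_size:
            assign[members] = next_id
            next_id += 1

    # stage 2: nearest-module assignment of leftovers
    assigned = np.flatnonzero(assign >= 0)
    if assigned.size and (assign < 0).any():
        for g in np.flatnonzero(assign < 0):
            means = []
            for m in range(next_id):
                mem = np.flatnonzero(assign == m)
                means.append(d[g, mem].mean())
            best = int(np.argmin(means))
            if means[best] < d[g, assigned].mean():
                assign[g] = best

    # stage 3: eigengene merging to a fixed point
    merge_trace = []
    while True:
        mods = [m for m in np.unique(assign) if m >= 0]
        if len(mods) < 2:
            break
        eig = {m: module_eigengene(expr_values, np.flatnonzero(assign == m))
               for m in mods}
        best_pair, best_diss = None, merge_diss
        for i, a in enumerate(mods):
            for b in mods[i + 1:]:
                diss = 1.0 - float(np.corrcoef(eig[a], eig[b])[0, 1])
                if diss < best_diss:
                    best_pair, best_diss = (a, b), diss
        if best_pair is None:
            break
        a, b = best_pair
        assign[assign == b] = a
        merge_trace.append((int(a), int(b), float(best_diss)))

    # relabel by size with the fixed color list
    mods, counts = np.unique(assign[assign >= 0], return_counts=True)
    order = mods[np.argsort(-counts, kind="stable")]
    labels = np.array([GREY] * n, dtype=object)
    eigengenes = {}
    for rank, m in enumerate(order):
        color = MODULE_COLORS[rank % len(MODULE_COLORS)]
        members = np.flatnonzero(assign == m)
        labels[members] = color
        eigengenes[color] = module_eigengene(expr_values, members)
    return ModuleDetection(labels=labels, dendrogram=Zlink, cut_height=cut,
                           eigengenes=eigengenes, merge_trace=merge_trace)


def connectivities(adjacency: np.ndarray,
                   labels: np.ndarray) -> pd.DataFrame:
    """k_total (all genes) and k_in (same-module partners only); grey
    genes have k_in = 0 by convention."""
    A = np.asarray(adjacency, float)
    labels = np.asarray(labels, dtype=object)
    kt = A.sum(axis=1)
    kin = np.zeros_like(kt)
    for color in np.unique(labels):
        if color == GREY:
            continue
        mem = np.flatnonzero(labels == color)
        sub = A[np.ix_(mem, mem)]
        kin[mem] = sub.sum(axis=1)
    return pd.DataFrame({"module": labels, "k_total": kt, "k_in": kin})


# ----------------------------------------------------------------- network

@dataclass
class CoexpressionNetwork:
    gene_ids: list
    beta: int
    adjacency: np.ndarray
    tom: np.ndarray
    modules: ModuleDetection
    connectivity: pd.DataFrame

    @property
    def labels(self) -> np.ndarray:
        return self.modules.labels

    def module_genes(self, color: str) -> list:
        return [g for g, c in zip(self.gene_ids, self.labels) if c == color]


def build_network(expr: ExpressionMatrix, beta: Optional[int] = None,
                  signed: bool = False, min_size: int = 30,
                  cut_height_q: float = 0.99,
                  merge_diss: float = 0.25) -> CoexpressionNetwork:
    """Adjacency -> TOM -> modules -> connectivities for a (pre-filtered)
    expression matrix; beta is chosen by the scale-free criterion when not
    given."""
    values = expr.values.to_numpy(float)
    if beta is None:
        beta = pick_soft_power(values, signed=signed).beta
    A = adjacency_matrix(values, beta, signed=signed)
    W = tom(A)
    det = detect_modules(1.0 - W, values, min_size=min_size,
                         cut_height_q=cut_height_q, merge_diss=merge_diss)
    conn = connectivities(A, det.labels)
    conn.insert(0, "gene_id", [str(p) for p in expr.probe_ids])
    return CoexpressionNetwork(gene_ids=list(expr.probe_ids), beta=int(beta),
                               adjacency=A, tom=W, modules=det,
                               connectivity=conn)


# ----------------------------------------------------------- probe filters

@dataclass
class ProbeFilterLog:
    n_input: int
    n_detected: int
    n_top_var: int
    beta: int
    n_top_conn: int


def filter_probes(expr: ExpressionMatrix, det_p: float = 0.05,
                  det_frac: float = 0.95, top_var: int = 8000,
                  top_conn: int = 3600,
                  signed: bool = False) -> tuple[ExpressionMatrix, ProbeFilterLog]:
    """Staged probe selection for network construction.

    detection filter (detection P < det_p in >= det_frac of samples; all
    pass when no detection matrix accompanies the data) -> top_var by
    variance -> soft power chosen on that set -> top_conn by k_total, with
    one probe per gene (the most connected one). Caps are clipped to the
    probes available.
    """
    if top_conn > top_var:
        raise ValueError("top_conn cannot exceed top_var")
    values = expr.values
    n_input = len(values)
    if expr.detection is not None:
        frac = (expr.detection < det_p).mean(axis=1)
        detected = frac[frac >= det_frac].index
    else:
        detected = values.index
    e1 = expr.subset_probes(detected)

    variances = e1.values.var(axis=1, ddof=1)
    keep_var = variances.sort_values(ascending=False).index[: min(top_var, len(variances))]
    e2 = e1.subset_probes(keep_var)

    power = pick_soft_power(e2.values.to_numpy(float), signed=signed)
    A = adjacency_matrix(e2.values.to_numpy(float), power.beta, signed=signed)
    kt = pd.Series(k_total(A), index=e2.values.index)

    ann = e2.probe_annotation.set_index("probe_id")
    best_per_gene = (
        kt.rename("k").to_frame()
        .assign(gene=ann.loc[kt.index, "gene_symbol"].values)
        .sort_values("k", ascending=False)
        .drop_duplicates("gene")
    )
    keep_conn = best_per_gene.sort_values("k", ascending=False) \
        .index[: min(top_conn, len(best_per_gene))]
    e3 = e2.subset_probes([p for p in e2.values.index if p in set(keep_conn)])
    logrec = ProbeFilterLog(n_input=n_input, n_detected=len(e1.values),
                            n_top_var=len(e2.values), beta=power.beta,
                            n_top_conn=len(e3.values))
    log.info("probe filter: %d -> detected %d -> top-var %d -> top-conn %d "
             "(beta=%d)", n_input, logrec.n_detected, logrec.n_top_var,
             logrec.n_top_conn, logrec.beta)
    return e3, logrec


# -------------------------------------------------------------- edge views

@dataclass
class EdgeSet:
    edges: pd.DataFrame            # gene_a, gene_b, tom (non-increasing)
    neighbors: dict                # gene -> sorted list of partners
    coverage: float                # fraction of module genes with >= 1 edge


def top_edges(network: CoexpressionNetwork, module: str,
              n_edges: int) -> EdgeSet:
    """The strongest within-module TOM edges (deterministic lexicographic
    tie-break) with neighbor lists for neighborhood analysis."""
    genes = network.module_genes(module)
    if not genes:
        raise ValueError(f"module not present: {module}")
    idx = {g: i for i, g in enumerate(network.gene_ids)}
    pairs = []
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            ga, gb = sorted((a, b))
            pairs.append((float(network.tom[idx[a], idx[b]]), ga, gb))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    kept = pairs[: min(n_edges, len(pairs))]
    edges = pd.DataFrame(kept, columns=["tom", "gene_a", "gene_b"])[
        ["gene_a", "gene_b", "tom"]]
    neighbors: dict = {}
    for _, row in edges.iterrows():
        neighbors.setdefault(row["gene_a"], set()).add(row["gene_b"])
        neighbors.setdefault(row["gene_b"], set()).add(row["gene_a"])
    neighbors = {g: sorted(v) for g, v in neighbors.items()}
    coverage = len(neighbors) / len(genes)
    return EdgeSet(edges=edges, neighbors=neighbors, coverage=coverage)


def second_order_neighborhood(edge_set: EdgeSet, gene: str) -> list:
    """Partners of a gene's partners (excluding the gene itself)."""
    first = edge_set.neighbors.get(gene, [])
    out = set()
    for f in first:
        out.update(edge_set.neighbors.get(f, []))
    out.discard(gene)
    return sorted(out)


def degree_one_genes(edge_set: EdgeSet) -> pd.DataFrame:
    """Genes connected to exactly one partner in the edge view."""
    rows = [(g, nbrs[0]) for g, nbrs in sorted(edge_set.neighbors.items())
            if len(nbrs) == 1]
    return pd.DataFrame(rows, columns=["gene", "partner"])
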