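"""Sparsity-thresholded graph topology of individualized SCNs.

A weighted SCN is binarized over a grid of sparsity levels K (fraction of
the strongest possible edges kept; default 0.14-0.50 in steps of 0.01, 37
levels). Edges are ranked by absolute weight (configurable to positive-only)
with a fixed lexicographic tie-break, so the edge sets are nested along the
grid. At each K the binary graph is summarized by:

* global metrics: clustering coefficient Cp, characteristic path length Lp,
  global efficiency Eg, local efficiency Eloc;
* nodal metrics: nodal Cp / Lp / Eg / Eloc, degree, betweenness centrality
  (unnormalized, each unordered pair counted once).

Unreachable pairs are excluded from Lp (grid validation separately enforces
that networks stay essentially connected); Eg handles them naturally via
1/inf = 0. Each metric-versus-K curve is condensed to its trapezoidal area
under the curve (AUC), the quantity used in group statistics.

Small-worldness sigma = (Cp/Cp_rand)/(Lp/Lp_rand) is measured against
degree-preserving rewired surrogates.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .scn import IndividualSCN

GLOBAL_METRICS = ("Cp", "Lp", "Eg", "Eloc")
NODAL_METRICS = ("nodal_Cp", "nodal_Lp", "nodal_Eg", "nodal_Eloc",
                 "degree", "betweenness")
ALL_METRICS = GLOBAL_METRICS + NODAL_METRICS


@dataclass(frozen=True)
class SparsityGrid:
    """Evenly spaced sparsity levels ``k_min, k_min+step, ..., k_max``."""

    k_min: float = 0.14
    k_max: float = 0.50
    step: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.k_min < self.k_max < 1.0):
            raise ValueError("require 0 < k_min < k_max < 1")
        n_steps = (self.k_max - self.k_min) / self.step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("grid span must be an integer multiple of step")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.k_max - self.k_min) / self.step)) + 1
        return np.linspace(self.k_min, self.k_max, n)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class BinaryNetwork:
    adjacency: np.ndarray
    k: float
    n_edges: int


def _adj(net: "BinaryNetwork | np.ndarray") -> np.ndarray:
    a = net.adjacency if isinstance(net, BinaryNetwork) else np.asarray(net)
    return a.astype(float)


def edge_ranking(matrix: np.ndarray, mode: str = "absolute"
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edge indices ordered strongest-first.

    ``absolute`` ranks by |weight| (negative covariance edges compete on
    magnitude); ``positive`` ranks by signed weight. Ties at any weight are
    broken by (row, col) lexicographic order, making the ranking - and
    therefore every binarization - deterministic and nested across K.
    """
    n = matrix.shape[0]
    ii, jj = np.triu_indices(n, 1)
    w = matrix[ii, jj]
    if mode == "absolute":
        key = np.abs(w)
    elif mode == "positive":
        key = w
    else:
        raise ValueError(f"unknown binarization mode {mode!r}; "
                         "use 'absolute' or 'positive'")
    order = np.lexsort((jj, ii, -key))
    return ii[order], jj[order]


def n_edges_at(k: float, n_nodes: int) -> int:
    """Edge count at sparsity ``k``: round-half-away-from-zero of K*n(n-1)/2."""
    total = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(k * total + 0.5))


def binarize(scn: "IndividualSCN | np.ndarray", k: float,
             mode: str = "absolute") -> BinaryNetwork:
    """Keep the ``round(K * n(n-1)/2)`` strongest edges of a weighted SCN."""
    matrix = scn.matrix if isinstance(scn, IndividualSCN) else np.asarray(scn, float)
    if not (0.0 < k < 1.0):
        raise ValueError(f"sparsity k must be in (0, 1), got {k}")
    n = matrix.shape[0]
    m = n_edges_at(k, n)
    if m == 0:
        raise ValueError(f"sparsity k={k} yields zero edges for {n} nodes")
    ii, jj = edge_ranking(matrix, mode)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[ii[:m], jj[:m]] = 1
    adj[jj[:m], ii[:m]] = 1
    return BinaryNetwork(adjacency=adj, k=k, n_edges=m)


def clustering_coefficient(net: "BinaryNetwork | np.ndarray"
                           ) -> tuple[np.ndarray, float]:
    """Per-node triangle density and its mean (global Cp).

    ``c_i = 2 t_i / (d_i (d_i - 1))`` with ``t_i`` the triangles through
    node i; nodes of degree < 2 contribute 0.
    """
    a = _adj(net)
    deg = a.sum(axis=1)
    tri = np.einsum("ij,ji->i", a @ a, a) / 2.0
    denom = deg * (deg - 1.0)
    nodal = np.divide(2.0 * tri, denom, out=np.zeros_like(denom),
                      where=denom > 0)
    return nodal, float(nodal.mean())


def shortest_path_lengths(net: "BinaryNetwork | np.ndarray") -> np.ndarray:
    """Unweighted all-pairs distances; unreachable pairs are ``inf``."""
    a = _adj(net)
    return shortest_path(csr_matrix(a), method="D", directed=False,
                         unweighted=True)


def characteristic_path_length(net: "BinaryNetwork | np.ndarray"
                               ) -> tuple[float, np.ndarray]:
    """Mean shortest-path length over reachable pairs (global, per-node).

    Unreachable pairs are excluded from both averages; a fully isolated
    node gets nodal Lp 0.
    """
    d = shortest_path_lengths(net)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d)
    counts = finite.sum(axis=1)
    sums = np.where(finite, d, 0.0).sum(axis=1)
    nodal = np.divide(sums, counts, out=np.zeros(n), where=counts > 0)
    total = int(counts.sum())
    global_lp = float(sums.sum() / total) if total > 0 else 0.0
    return global_lp, nodal


def global_efficiency(net: "BinaryNetwork | np.ndarray"
                      ) -> tuple[float, np.ndarray]:
    """Mean inverse shortest-path length (global, per-node); 1/inf = 0."""
    d = shortest_path_lengths(net)
    n = d.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    nodal = inv.sum(axis=1) / (n - 1)
    return float(inv.sum() / (n * (n - 1))), nodal


def local_efficiency(net: "BinaryNetwork | np.ndarray"
                     ) -> tuple[float, np.ndarray]:
    """Global efficiency of each node's neighbor-induced subgraph (0 if < 2
    neighbors); global Eloc is the node average."""
    a = _adj(net)
    n = a.shape[0]
    nodal = np.zeros(n)
    for v in range(n):
        nb = np.flatnonzero(a[v] > 0)
        if len(nb) < 2:
            continue
        sub = a[np.ix_(nb, nb)]
        nodal[v] = global_efficiency(sub)[0]
    return float(nodal.mean()), nodal


def _to_igraph(a: np.ndarray) -> ig.Graph:
    ii, jj = np.nonzero(np.triu(a, 1))
    return ig.Graph(n=a.shape[0], edges=list(zip(ii.tolist(), jj.tolist())))


def degree_and_betweenness(net: "BinaryNetwork | np.ndarray"
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Per-node degree and unnormalized betweenness centrality.

    Betweenness counts, for each unordered pair (s, t) with s != t != v,
    the fraction of shortest s-t paths passing through v.
    """
    a = _adj(net)
    deg = a.sum(axis=1)
    btw = np.asarray(_to_igraph(a).betweenness(directed=False), dtype=float)
    return deg, btw


@dataclass
class SmallWorldResult:
    sigma: float
    cp: float
    lp: float
    cp_rand: float
    lp_rand: float
    valid: bool


def small_world_index(net: "BinaryNetwork | np.ndarray",
                      n_random: int = 100,
                      seed: int = 0,
                      swap_factor: int = 10) -> SmallWorldResult:
    """Small-world sigma against degree-preserving rewired surrogates.

    Each surrogate applies ``swap_factor * n_edges`` random double-edge-swap
    attempts (``swap_factor=0`` leaves the network untouched, so sigma = 1).
    sigma = (Cp/Cp_rand) / (Lp/Lp_rand); if any reference quantity is zero
    the index is undefined and flagged ``valid=False``.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    a = _adj(net)
    m = int(a.sum()) // 2
    if m < 1:
        raise ValueError("network must have at least one edge")
    _, cp = clustering_coefficient(a)
    lp, _ = characteristic_path_length(a)

    g = _to_igraph(a)
    n = a.shape[0]
    ig.set_random_number_generator(_pyrandom.Random(int(seed)))
    cps, lps = [], []
    for _ in range(n_random):
        h = g.copy()
        if swap_factor > 0:
            h.rewire(n=swap_factor * m, mode="simple")
        edges = np.asarray(h.get_edgelist(), dtype=int)
        ra = np.zeros((n, n), dtype=np.int8)
        ra[edges[:, 0], edges[:, 1]] = 1
        ra[edges[:, 1], edges[:, 0]] = 1
        cps.append(clustering_coefficient(ra)[1])
        lps.append(characteristic_path_length(ra)[0])
    cp_rand = float(np.mean(cps))
    lp_rand = float(np.mean(lps))

    valid = cp_rand > 0 and lp_rand > 0 and lp > 0
    sigma = (cp / cp_rand) / (lp / lp_rand) if valid else float("nan")
    return SmallWorldResult(sigma=sigma, cp=cp, lp=lp,
                            cp_rand=cp_rand, lp_rand=lp_rand, valid=valid)


def largest_component_fraction(net: "BinaryNetwork | np.ndarray") -> float:
    a = _adj(net)
    n_comp, labels = connected_components(csr_matrix(a), directed=False)
    return float(np.bincount(labels).max() / a.shape[0])


def validate_sparsity_grid(matrices: list[np.ndarray],
                           grid: SparsityGrid,
                           mode: str = "absolute",
                           n_random: int = 20,
                           seed: int = 0,
                           connectivity_threshold: float = 0.90,
                           sigma_fraction: float = 0.95) -> pd.DataFrame:
    """Screen each sparsity level against the two validity criteria.

    Per K, reports the fraction of networks whose largest connected
    component covers more than ``connectivity_threshold`` of nodes, and the
    fraction with small-world sigma > 1; a K fails (``flagged``) when the
    first fraction is not 1.0 or the second does not exceed
    ``sigma_fraction``.
    """
    if len(matrices) < 1:
        raise ValueError("need at least one network")
    rows = []
    for idx_k, k in enumerate(grid.values):
        conn, sw = [], []
        for idx_m, mat in enumerate(matrices):
            net = binarize(np.asarray(mat, float), float(k), mode)
            conn.append(largest_component_fraction(net) > connectivity_threshold)
            res = small_world_index(net, n_random=n_random,
                                    seed=seed + 1000 * idx_k + idx_m)
            sw.append(bool(res.valid and res.sigma > 1.0))
        frac_conn = float(np.mean(conn))
        frac_sw = float(np.mean(sw))
        rows.append({
            "k": float(k),
            "frac_connected": frac_conn,
            "frac_sigma_gt_1": frac_sw,
            "connected_ok": frac_conn == 1.0,
            "small_world_ok": frac_sw > sigma_fraction,
        })
    report = pd.DataFrame(rows)
    report["flagged"] = ~(report["connected_ok"] & report["small_world_ok"])
    return report


@dataclass
class MetricCurve:
    metric_name: str
    subject_id: str
    values: np.ndarray      # (n_k,) for global metrics, (n_k, n_nodes) nodal


@dataclass
class AUCRecord:
    metric_name: str
    subject_id: str
    auc: float
    node: str | None = None


def metric_curves(matrix: np.ndarray,
                  grid: SparsityGrid,
                  mode: str = "absolute",
                  metrics: tuple[str, ...] = ALL_METRICS,
                  subject_id: str = "") -> dict[str, np.ndarray]:
    """Evaluate the requested metrics at every grid level.

    The edge ranking is computed once; because edge sets are nested in K,
    the adjacency is grown incrementally along the grid.
    """
    unknown = set(metrics) - set(ALL_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    ii, jj = edge_ranking(matrix, mode)
    adj = np.zeros((n, n), dtype=np.int8)
    filled = 0
    out: dict[str, list] = {m: [] for m in metrics}
    for k in grid.values:
        m_edges = n_edges_at(float(k), n)
        if m_edges == 0:
            raise ValueError(f"sparsity k={k} yields zero edges")
        sel = slice(filled, m_edges)
        adj[ii[sel], jj[sel]] = 1
        adj[jj[sel], ii[sel]] = 1
        filled = max(filled, m_edges)

        need_cp = {"Cp", "nodal_Cp"} & set(metrics)
        need_lp = {"Lp", "nodal_Lp"} & set(metrics)
        need_eg = {"Eg", "nodal_Eg"} & set(metrics)
        need_el = {"Eloc", "nodal_Eloc"} & set(metrics)
        if need_cp:
            nodal_cp, cp = clustering_coefficient(adj)
            if "Cp" in metrics:
                out["Cp"].append(cp)
            if "nodal_Cp" in metrics:
                out["nodal_Cp"].append(nodal_cp)
        if need_lp:
            lp, nodal_lp = characteristic_path_length(adj)
            if "Lp" in metrics:
                out["Lp"].append(lp)
            if "nodal_Lp" in metrics:
                out["nodal_Lp"].append(nodal_lp)
        if need_eg:
            eg, nodal_eg = global_efficiency(adj)
            if "Eg" in metrics:
                out["Eg"].append(eg)
            if "nodal_Eg" in metrics:
                out["nodal_Eg"].append(nodal_eg)
        if need_el:
            eloc, nodal_el = local_efficiency(adj)
            if "Eloc" in metrics:
                out["Eloc"].append(eloc)
            if "nodal_Eloc" in metrics:
                out["nodal_Eloc"].append(nodal_el)
        if "degree" in metrics or "betweenness" in metrics:
            deg, btw = degree_and_betweenness(adj)
            if "degree" in metrics:
                out["degree"].append(deg)
            if "betweenness" in metrics:
                out["betweenness"].append(btw)
    return {name: np.asarray(vals) for name, vals in out.items()}


def auc(values: np.ndarray, grid: SparsityGrid) -> "float | np.ndarray":
    """Composite trapezoidal area of a metric curve over the grid.

    ``values`` may be (n_k,) for a global metric or (n_k, n_nodes) for a
    nodal one (integrated per node).
    """
    values = np.asarray(values, dtype=float)
    ks = grid.values
    if len(ks) < 2:
        raise ValueError("grid must contain at least 2 sparsity levels")
    if values.shape[0] != len(ks):
        raise ValueError(
            f"curve has {values.shape[0]} points but grid has {len(ks)}")
    result = np.trapezoid(values, ks, axis=0)
    return float(result) if np.ndim(result) == 0 else result


def cohort_auc_table(scns: "list[IndividualSCN]",
                     groups: dict[str, str],
                     grid: SparsityGrid,
                     mode: str = "absolute",
                     metrics: tuple[str, ...] = ALL_METRICS,
                     region_labels: list[str] | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metric curves and AUCs for a cohort of individualized SCNs.

    Returns two long-format tables: curves (subject_id, group, metric, node,
    k, value) and AUCs (subject_id, group, metric, node, auc). ``node`` is
    empty for global metrics.
    """
    curve_rows, auc_rows = [], []
    ks = grid.values
    for scn in scns:
        labels = region_labels or scn.region_labels
        curves = metric_curves(scn.matrix, grid, mode=mode, metrics=metrics,
                               subject_id=scn.subject_id)
        grp = groups[scn.subject_id]
        for name, vals in curves.items():
            area = auc(vals, grid)
            if vals.ndim == 1:
                for k, v in zip(ks, vals):
                    curve_rows.append((scn.subject_id, grp, name, "", k, v))
                auc_rows.append((scn.subject_id, grp, name, "", area))
            else:
                for node_idx, label in enumerate(labels):
                    for k, v in zip(ks, vals[:, node_idx]):
                        curve_rows.append((scn.subject_id, grp, name, label, k, v))
                    auc_rows.append((scn.subject_id, grp, name, label,
                                     area[node_idx]))
    curves_df = pd.DataFrame(curve_rows, columns=[
        "subject_id", "group", "metric", "node", "k", "value"])
    auc_df = pd.DataFrame(auc_rows, columns=[
        "subject_id", "group", "metric", "node", "auc"])
    return curves_df, auc_df
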