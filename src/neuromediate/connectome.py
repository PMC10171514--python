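"""Weighted brain-network construction, group pruning and efficiency metrics.

Networks are square weighted adjacency matrices over labelled nodes
(``L_<region>`` / ``R_<region>``).  Structural networks carry non-negative
streamline-count-like weights; functional networks carry signed Fisher-z
partial correlations.  Group-level Holm-Bonferroni pruning removes edges whose
weights, pooled over subjects, are not significantly greater than zero; the
surviving network is scored by shortest-path nodal and global efficiency with
edge lengths 1/weight.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import dijkstra as _dijkstra
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_LABEL_RE = re.compile(r"^(?P<hemi>[LR])_(?P<region>.+)$")


def parse_label(label: str) -> tuple[str, str]:
    """Split a node label like ``L_V1`` into (hemisphere, region)."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"node label {label!r} is not of the form L_<region> / R_<region>")
    return m.group("hemi"), m.group("region")


@dataclass
class ConnectivityMatrix:
    """A single subject's weighted network.

    weights must be symmetric with a zero diagonal; labels are unique node
    names encoding hemisphere and region.
    """

    weights: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights)
        if not np.issubdtype(self.weights.dtype, np.floating):
            self.weights = self.weights.astype(float)
        self.labels = list(self.labels)
        n = len(self.labels)
        if self.weights.shape != (n, n):
            raise ValueError(f"weights shape {self.weights.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValueError("node labels must be unique")
        if not np.allclose(self.weights, self.weights.T, equal_nan=True):
            raise ValueError("weights must be symmetric")
        if not np.allclose(np.diag(self.weights), 0.0):
            raise ValueError("diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


@dataclass
class GroupConnectivity:
    """Stack of per-subject networks sharing one node order."""

    subjects: list[str]
    weights: np.ndarray  # (n_subjects, n_nodes, n_nodes)
    labels: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights)
        if not np.issubdtype(self.weights.dtype, np.floating):
            self.weights = self.weights.astype(float)
        self.subjects = [str(s) for s in self.subjects]
        self.labels = list(self.labels)
        s, n = len(self.subjects), len(self.labels)
        if self.weights.shape != (s, n, n):
            raise ValueError(
                f"weights shape {self.weights.shape} inconsistent with "
                f"{s} subjects x {n} nodes"
            )
        if len(set(self.subjects)) != s:
            raise ValueError("subject ids must be unique")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def matrix(self, subject: str) -> ConnectivityMatrix:
        i = self.subjects.index(subject)
        return ConnectivityMatrix(self.weights[i], self.labels)


@dataclass
class PruneConfig:
    """Group pruning parameters: one-tailed test of edge weights against 0."""

    alpha: float = 0.01
    null_value: float = 0.0
    max_iterations: int = 1000
    statistic: str = "z"  # "z": pooled-SD z test; "t": per-edge one-sample t

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.statistic not in ("z", "t"):
            raise ValueError("statistic must be 'z' or 't'")


@dataclass
class EdgeMask:
    """Result of group pruning: which upper-triangle edges survived."""

    mask: np.ndarray  # boolean (n_nodes, n_nodes), symmetric
    labels: list[str]
    removed_edges: int
    removed_nodes: list[str]
    iterations: int

    def retained_edges(self) -> int:
        iu = np.triu_indices(self.mask.shape[0], k=1)
        return int(self.mask[iu].sum())

    def to_edgelist(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(self.mask.shape[0], k=1)
        return pd.DataFrame(
            {
                "node_i": [self.labels[i] for i in iu],
                "node_j": [self.labels[j] for j in ju],
                "retained": self.mask[iu, ju].astype(int),
            }
        )


@dataclass
class DistanceMatrix:
    """Shortest-path lengths; np.inf marks disconnected pairs."""

    dij: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dij = np.asarray(self.dij, dtype=float)


@dataclass
class EfficiencyResult:
    """Per-node efficiencies and their mean, the global efficiency."""

    nodal: np.ndarray
    global_efficiency: float
    labels: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.nodal.size


def fisher_z(r):
    """Fisher z-transformation, ``z = arctanh(r)``.

    Variance-stabilizes correlation coefficients; rejects |r| >= 1.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("Fisher z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def functional_connectivity(
    signals: np.ndarray,
    nuisance: np.ndarray | None = None,
    labels: list[str] | None = None,
) -> ConnectivityMatrix:
    """Nuisance-controlled Fisher-z partial-correlation network.

    Parameters
    ----------
    signals : (n_nodes, n_time) array of node-average time courses.
    nuisance : (n_regressors, n_time) array of nuisance signals (motion
        parameters, white-matter and ventricle averages) regressed out of
        every node series before correlating, or None/empty for plain
        Pearson correlation.
    labels : node labels; defaults to ``L_N1..`` style placeholders.

    Node pairs whose residual series are (near-)constant have no defined
    correlation; those edges are returned as NaN and a warning is logged.
    """
    signals = np.asarray(signals, dtype=float)
    n_nodes, n_time = signals.shape
    if nuisance is None:
        nuisance = np.empty((0, n_time))
    nuisance = np.asarray(nuisance, dtype=float)
    k = nuisance.shape[0]
    if n_time < k + 3:
        raise ValueError(f"need at least {k + 3} time points for {k} nuisance regressors")
    # residualize each node series on [1, nuisance]
    design = np.column_stack([np.ones(n_time), nuisance.T])
    beta, *_ = np.linalg.lstsq(design, signals.T, rcond=None)
    resid = signals.T - design @ beta  # (n_time, n_nodes)

    sd = resid.std(axis=0, ddof=1)
    degenerate = sd < 1e-10 * max(1.0, float(np.abs(signals).max()))
    if degenerate.any():
        logger.warning(
            "%d node series are constant after nuisance removal; their edges are NaN",
            int(degenerate.sum()),
        )
    safe_sd = np.where(degenerate, 1.0, sd)
    zscored = (resid - resid.mean(axis=0)) / safe_sd
    r = (zscored.T @ zscored) / (n_time - 1)
    np.clip(r, -1 + 1e-12, 1 - 1e-12, out=r)
    z = np.arctanh(r)
    z[degenerate, :] = np.nan
    z[:, degenerate] = np.nan
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2
    if labels is None:
        half = n_nodes // 2
        labels = [f"L_N{i + 1}" for i in range(half)] + [
            f"R_N{i + 1}" for i in range(n_nodes - half)
        ]
    return ConnectivityMatrix(z, labels)


def _edge_pvalues(weights_se: np.ndarray, null_value: float, statistic: str) -> np.ndarray:
    """One-tailed (greater) p-values for edge weights against the null.

    weights_se: (n_subjects, n_edges) currently retained upper-triangle
    weights.  The default "z" statistic uses the pooled SD of *all* retained
    weights across subjects and edges, so an edge is judged against the
    dispersion of the whole network; "t" is a conventional per-edge
    one-sample t-test.
    """
    s = weights_se.shape[0]
    means = weights_se.mean(axis=0)
    if statistic == "z":
        pooled_sd = weights_se.std(ddof=1)
        if pooled_sd == 0:
            # all retained weights identical: edges equal to null are spurious
            return np.where(means > null_value, 0.0, 1.0)
        stat = (means - null_value) / (pooled_sd / np.sqrt(s))
        return stats.norm.sf(stat)
    sd = weights_se.std(axis=0, ddof=1)
    sd = np.where(sd == 0, np.finfo(float).tiny, sd)
    stat = (means - null_value) / (sd / np.sqrt(s))
    return stats.t.sf(stat, df=s - 1)


def holm_prune(
    group: GroupConnectivity, config: PruneConfig | None = None
) -> tuple[EdgeMask, GroupConnectivity]:
    """Iterative group-level Holm-Bonferroni pruning of spurious edges.

    Repeats to a fixed point: pool the SD over all currently retained
    upper-triangle weights of all subjects, test every retained edge's
    subject-wise weights against the null (one-tailed, greater), apply the
    Holm step-down at ``alpha``, and drop edges that fail.  When no edge is
    removed, nodes left with zero retained edges are dropped and the common
    mask is applied to every subject.
    """
    if config is None:
        config = PruneConfig()
    if group.n_subjects < 2:
        raise ValueError("group pruning needs at least 2 subjects")
    n = group.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    all_edges = group.weights[:, iu, ju]  # (S, E)
    retained = np.ones(all_edges.shape[1], dtype=bool)

    iterations = 0
    for _ in range(config.max_iterations):
        iterations += 1
        idx = np.flatnonzero(retained)
        if idx.size == 0:
            break
        pvals = _edge_pvalues(all_edges[:, idx], config.null_value, config.statistic)
        keep, *_ = multipletests(pvals, alpha=config.alpha, method="holm")
        if keep.all():
            break
        retained[idx[~keep]] = False
    else:
        logger.warning("holm_prune hit max_iterations=%d before converging", config.max_iterations)

    if not retained.any():
        raise ValueError("pruning removed every edge: empty network")

    mask = np.zeros((n, n), dtype=bool)
    mask[iu[retained], ju[retained]] = True
    mask |= mask.T

    degree = mask.sum(axis=1)
    dead = degree == 0
    removed_nodes = [group.labels[i] for i in np.flatnonzero(dead)]
    if removed_nodes:
        logger.info("pruning removed %d isolated nodes: %s", len(removed_nodes), removed_nodes)

    keep_nodes = ~dead
    new_labels = [lab for lab, k in zip(group.labels, keep_nodes) if k]
    sub_mask = mask[np.ix_(keep_nodes, keep_nodes)]
    pruned_weights = group.weights[:, keep_nodes][:, :, keep_nodes] * sub_mask

    edge_mask = EdgeMask(
        mask=mask,
        labels=list(group.labels),
        removed_edges=int((~retained).sum()),
        removed_nodes=removed_nodes,
        iterations=iterations,
    )
    pruned = GroupConnectivity(group.subjects, pruned_weights, new_labels)
    return edge_mask, pruned


def shortest_path_distances(
    matrix: ConnectivityMatrix, clip_negative: bool = False
) -> DistanceMatrix:
    """Weighted shortest-path distances with edge length 1/weight.

    Strong connections are short: the adjacency matrix is inverted elementwise
    (zero weight = no edge) and Dijkstra's algorithm run from every node.
    Disconnected pairs get np.inf.  Negative weights are rejected by default;
    ``clip_negative=True`` treats them as absent edges — group pruning
    guarantees only the *mean* Fisher-z weight of a retained functional edge
    is positive, so a single subject may still carry a negative value there.
    """
    w = matrix.weights
    if np.any(w < 0):
        if not clip_negative:
            raise ValueError(
                "negative edge weights give negative lengths; prune the network "
                "first or pass clip_negative=True"
            )
        w = np.maximum(w, 0.0)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    d = _dijkstra(lengths, directed=False)
    return DistanceMatrix(d, list(matrix.labels))


def nodal_efficiency(dist: DistanceMatrix) -> np.ndarray:
    """E_i = mean over j != i of 1/d_ij, with 1/inf = 0."""
    d = dist.dij
    n = d.shape[0]
    if n < 2:
        raise ValueError("nodal efficiency needs at least 2 nodes")
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def global_efficiency(nodal: np.ndarray) -> float:
    """Global efficiency E: the arithmetic mean of the nodal efficiencies."""
    nodal = np.asarray(nodal, dtype=float)
    if nodal.size == 0:
        raise ValueError("empty efficiency vector")
    return float(nodal.mean())


def efficiency(matrix: ConnectivityMatrix, clip_negative: bool = False) -> EfficiencyResult:
    """Distance matrix -> nodal efficiencies -> global efficiency, in one call."""
    dist = shortest_path_distances(matrix, clip_negative=clip_negative)
    nodal = nodal_efficiency(dist)
    return EfficiencyResult(nodal, global_efficiency(nodal), list(matrix.labels))


def group_efficiency(
    group: GroupConnectivity, clip_negative: bool = False
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-subject nodal efficiency table and global efficiency series."""
    rows = {}
    glob = {}
    for i, subj in enumerate(group.subjects):
        res = efficiency(
            ConnectivityMatrix(group.weights[i], group.labels), clip_negative=clip_negative
        )
        rows[subj] = res.nodal
        glob[subj] = res.global_efficiency
    nodal = pd.DataFrame.from_dict(rows, orient="index", columns=group.labels)
    nodal.index.name = "subject"
    return nodal, pd.Series(glob, name="global_efficiency")


def average_hemispheres(node_values: pd.DataFrame) -> pd.DataFrame:
    """Average homologous left/right node columns into region columns.

    Columns are node labels (``L_V1``, ``R_V1`` ...); the result has one
    column per region, the mean of whichever hemispheres are present.  A
    region with a single surviving hemisphere uses that value (logged); this
    happens when pruning removed the other node.
    """
    regions: dict[str, list[str]] = {}
    for col in node_values.columns:
        _, region = parse_label(col)
        regions.setdefault(region, []).append(col)
    out = {}
    for region, cols in regions.items():
        if len(cols) == 1:
            logger.warning("region %s present in one hemisphere only (%s)", region, cols[0])
        out[region] = node_values[cols].mean(axis=1)
    return pd.DataFrame(out, index=node_values.index)


# ---------------------------------------------------------------------------
# text I/O: square matrices as TSV with a label header row

def write_matrix_tsv(matrix: ConnectivityMatrix, path) -> None:
    pd.DataFrame(matrix.weights, columns=matrix.labels).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_matrix_tsv(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t")
    return ConnectivityMatrix(df.to_numpy(dtype=float), list(df.columns))
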