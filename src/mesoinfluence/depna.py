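"""Dependency network analysis (DEPNA): correlation-influence graphs.

DEPNA asks, for every ordered node pair, how much of the correlation between
two nodes j and k is carried by a third node i. The correlation influence

    d(j, k | i) = z(C(j, k)) - z(PC(j, k | i)),    z = atanh (Fisher),

is the drop in (Fisher-transformed) correlation when i is partialled out;
negative values are clamped to zero. Averaging d over the remaining partners
gives the average correlation influence D(j, i) of node i on node j, and
summing D over partners gives each node's *influencing* degree (column sum:
influence it exerts) and *influenced* degree (row sum: influence it
receives). With the VTA as hub, D(target, VTA) is read as the directed edge
VTA -> target.

Degenerate correlations of magnitude one (e.g. the matrix diagonal) are
pulled to 0.99 before the Fisher transform so atanh stays finite; diagonal
terms never enter the influence sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .stats import bh_fdr, fit_adjusted_regression

__all__ = [
    "CorrelationMatrix",
    "DependencyMatrix",
    "InfluenceDegrees",
    "correlation_matrix",
    "fisher_z",
    "partial_correlation",
    "correlation_influence",
    "dependency_matrix",
    "influence_degrees",
    "degrees_table",
    "exclude_outliers",
    "influence_regression",
    "edge_graph",
]

CLIP = 0.99  # magnitude-one correlations are pulled here before atanh


class DegenerateInputError(ValueError):
    """A node series or correlation configuration is numerically degenerate."""


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pearson matrix of one subject's node-by-time panel plus its Fisher-z companion.

    ``values`` keeps the conventional unit diagonal; ``z`` is atanh applied
    after the 0.99 diagonal/unit-magnitude adjustment.
    """

    values: np.ndarray
    z: np.ndarray
    node_names: tuple[str, ...] | None = None

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class DependencyMatrix:
    """Average correlation influence D[j, i] of node i on node j's connections."""

    values: np.ndarray
    node_names: tuple[str, ...] | None = None


@dataclass(frozen=True)
class InfluenceDegrees:
    """Per-node influencing (exerted) and influenced (received) degree."""

    influencing: np.ndarray
    influenced: np.ndarray
    node_names: tuple[str, ...] | None = None


def _clip_for_z(r: np.ndarray) -> np.ndarray:
    return np.clip(r, -CLIP, CLIP)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing atanh transform, with |r| = 1 pulled to 0.99."""
    return np.arctanh(_clip_for_z(np.asarray(r, dtype=float)))


def correlation_matrix(
    panel: np.ndarray, node_names: list[str] | tuple[str, ...] | None = None
) -> CorrelationMatrix:
    """Pearson correlation matrix of a node x time panel.

    Raises :class:`DegenerateInputError`, naming the offending node, if any
    series is constant. The Fisher-z companion applies the 0.99 adjustment to
    the diagonal (and any off-diagonal entry of magnitude one); the reported
    correlation diagonal stays exactly one.
    """
    panel = np.asarray(panel, dtype=float)
    if panel.ndim != 2 or panel.shape[1] < 3:
        raise DegenerateInputError("panel must be nodes x timepoints with >= 3 timepoints")
    sd = panel.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        names = [node_names[i] if node_names else str(i) for i in bad]
        raise DegenerateInputError(f"constant time series for node(s): {', '.join(names)}")
    c = np.corrcoef(panel)
    np.fill_diagonal(c, 1.0)
    z = np.arctanh(_clip_for_z(c))
    names = tuple(node_names) if node_names is not None else None
    return CorrelationMatrix(c, z, names)


def partial_correlation(C: np.ndarray | CorrelationMatrix, j: int, k: int, i: int) -> float:
    """First-order partial correlation of j and k controlling for i.

    PC(j,k|i) = [C(j,k) - C(j,i) C(k,i)] / sqrt[(1 - C(j,i)^2)(1 - C(k,i)^2)].
    """
    c = C.values if isinstance(C, CorrelationMatrix) else np.asarray(C)
    if len({j, k, i}) != 3:
        raise ValueError("j, k and i must be distinct nodes")
    denom_sq = (1.0 - c[j, i] ** 2) * (1.0 - c[k, i] ** 2)
    if denom_sq <= 0:
        raise DegenerateInputError(
            f"partial correlation undefined: |C| = 1 between node {i} and node {j} or {k}"
        )
    return float((c[j, k] - c[j, i] * c[k, i]) / np.sqrt(denom_sq))


def correlation_influence(
    C: np.ndarray | CorrelationMatrix, j: int, k: int, i: int, use_fisher: bool = True
) -> float:
    """Influence of node i on the j-k connection: full minus partial correlation.

    Both correlations pass through Fisher-z before differencing (set
    ``use_fisher=False`` for the raw-difference variant); negative influences
    are clamped to zero.
    """
    c = C.values if isinstance(C, CorrelationMatrix) else np.asarray(C)
    pc = partial_correlation(c, j, k, i)
    if use_fisher:
        d = fisher_z(c[j, k]) - fisher_z(pc)
    else:
        d = c[j, k] - pc
    return float(max(0.0, d))


def dependency_matrix(
    C: np.ndarray | CorrelationMatrix,
    use_fisher: bool = True,
    normalization: str = "n-1",
) -> DependencyMatrix:
    """Average correlation influence D[j, i] for every ordered node pair.

    D[j, i] averages d(j, R | i) over partners R outside {i, j}. The printed
    normalization divides by n-1 (default); ``normalization='n-2'`` divides by
    the actual number of summed partners. Group contrasts are invariant to
    this constant.
    """
    names = C.node_names if isinstance(C, CorrelationMatrix) else None
    c = C.values if isinstance(C, CorrelationMatrix) else np.asarray(C, dtype=float)
    n = c.shape[0]
    if n < 3:
        raise ValueError("dependency matrix requires at least 3 nodes")
    if normalization not in ("n-1", "n-2"):
        raise ValueError("normalization must be 'n-1' or 'n-2'")
    zc = np.arctanh(_clip_for_z(c))
    D = np.zeros((n, n))
    for i in range(n):
        ci = c[:, i]
        denom_sq = np.outer(1.0 - ci**2, 1.0 - ci**2)
        # rows/cols j,k != i only; diagonal handled below
        with np.errstate(divide="ignore", invalid="ignore"):
            pc = (c - np.outer(ci, ci)) / np.sqrt(denom_sq)
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if np.any(np.abs(ci[mask]) >= 1.0):
            bad = np.flatnonzero((np.abs(ci) >= 1.0) & mask)[0]
            raise DegenerateInputError(
                f"partial correlation undefined: |C| = 1 between node {i} and node {bad}"
            )
        if use_fisher:
            d = zc - np.arctanh(_clip_for_z(pc))
        else:
            d = c - pc
        d = np.maximum(d, 0.0)
        d[~mask, :] = 0.0
        d[:, ~mask] = 0.0
        np.fill_diagonal(d, 0.0)
        denom = (n - 1) if normalization == "n-1" else (n - 2)
        D[:, i] = d.sum(axis=1) / denom
        D[i, i] = 0.0
    return DependencyMatrix(D, names)


def influence_degrees(D: DependencyMatrix | np.ndarray) -> InfluenceDegrees:
    """Column/row sums of D excluding the self term.

    influencing(i) = sum_{N != i} D[N, i] -- the influence node i exerts;
    influenced(i)  = sum_{N != i} D[i, N] -- the influence it receives.
    """
    names = D.node_names if isinstance(D, DependencyMatrix) else None
    d = D.values if isinstance(D, DependencyMatrix) else np.asarray(D, dtype=float)
    off = d - np.diag(np.diag(d))
    return InfluenceDegrees(off.sum(axis=0), off.sum(axis=1), names)


def degrees_table(
    matrices: list[DependencyMatrix], subject_ids: list[str], hub: int | str = 0
) -> pd.DataFrame:
    """Per-subject influencing/influenced degree of the hub node."""
    rows = []
    for sid, D in zip(subject_ids, matrices, strict=True):
        idx = hub if isinstance(hub, int) else D.node_names.index(hub)
        deg = influence_degrees(D)
        rows.append(
            {
                "subject_id": sid,
                "influencing": deg.influencing[idx],
                "influenced": deg.influenced[idx],
            }
        )
    return pd.DataFrame(rows)


def exclude_outliers(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Inclusion mask dropping values more than k sample SDs from the mean.

    Mean and SD are computed once on the full sample (non-iterative). A
    zero-variance sample keeps everyone.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("outlier exclusion needs at least 3 values")
    sd = values.std(ddof=1)
    if sd == 0:
        return np.ones(values.size, dtype=bool)
    return np.abs(values - values.mean()) <= k * sd


def influence_regression(
    degrees: np.ndarray | pd.Series,
    cohort: pd.DataFrame,
    predictor: str,
    covariates: list[str] = (),
):
    """OLS of a per-subject degree on a predictor plus nuisance covariates.

    Returns an :class:`~mesoinfluence.stats.AssociationResult` with the
    predictor's coefficient, t and two-sided p. The single-hub analysis
    carries no multiple-comparison correction.
    """
    return fit_adjusted_regression(
        np.asarray(degrees, dtype=float), cohort, predictor, list(covariates),
        analysis_id=f"degree~{predictor}",
    )


def edge_graph(
    D_stack: np.ndarray,
    cohort: pd.DataFrame,
    predictor: str,
    covariates: list[str] = (),
    node_names: list[str] | None = None,
    hub: int = 0,
    alpha: float = 0.05,
) -> nx.DiGraph:
    """Directed hub-centered influence graph from a subject stack of D matrices.

    For every ordered hub<->target pair, the per-subject average correlation
    influence is regressed on the predictor (with covariates); pairs with
    uncorrected p below ``alpha`` become edges. Direction convention:
    D[target, hub] is the edge hub -> target. All tested pairs carry a BH-FDR
    q over the 2*(n-1)-pair family, stored on the graph's ``tests`` attribute.
    """
    D_stack = np.asarray(D_stack, dtype=float)
    if D_stack.ndim != 3:
        raise ValueError("D_stack must be subjects x nodes x nodes")
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if len(cohort) != D_stack.shape[0]:
        raise ValueError("cohort rows must match the subject stack")
    n = D_stack.shape[1]
    if node_names is None:
        node_names = [f"node{i}" for i in range(n)]
    tests = []
    for tgt in range(n):
        if tgt == hub:
            continue
        for src, dst in ((hub, tgt), (tgt, hub)):
            # D[j, i] = influence of i on j, so edge src -> dst reads D[dst, src]
            vals = D_stack[:, dst, src]
            res = fit_adjusted_regression(
                vals, cohort, predictor, list(covariates),
                analysis_id=f"{node_names[src]}->{node_names[dst]}~{predictor}",
            )
            tests.append(
                {
                    "source": node_names[src],
                    "target": node_names[dst],
                    "coef": res.coefficient,
                    "p_uncorr": res.p_uncorr,
                }
            )
    table = pd.DataFrame(tests)
    table["q_fdr"] = bh_fdr(table["p_uncorr"].to_numpy())
    g = nx.DiGraph()
    g.add_nodes_from(node_names)
    for _, row in table.iterrows():
        if row["p_uncorr"] < alpha:
            g.add_edge(
                row["source"], row["target"],
                coef=float(row["coef"]),
                p_uncorr=float(row["p_uncorr"]),
                q_fdr=float(row["q_fdr"]),
                significant_fdr=bool(row["q_fdr"] < alpha),
            )
    g.graph["tests"] = table
    g.graph["predictor"] = predictor
    return g
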