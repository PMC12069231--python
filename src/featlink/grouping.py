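"""The two feature-grouping indices and their combinations.

``group`` — relational grouping: connected components of the graph whose
edges are any annotated relation (adduct, isotope, neutral loss, in-source
fragment, shared primary ion).

``corgroup`` — "annotation by perturbation": if a metabolite's abundance
changes x-fold between conditions, every feature it generates changes
x-fold too, so the log10 intensity profiles of its features correlate.
Pairs of features eluting within an rt window (default 2 s) are correlated
(Pearson by default, log10 intensities, pairwise-complete samples) and
features are grouped into cliques in which *every* pair exceeds the
correlation threshold (default 0.8, strict).  Cliques are extracted
greedily by size (ties: higher mean pairwise correlation, then earliest
eluting member), so each feature belongs to at most one corgroup.

Group indices are dense, 1-based, ordered by the earliest-eluting member;
singletons stay unassigned (None).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .core import AnnotationEdge, FeatureTable, ValidationError

__all__ = [
    "CorrelationParams",
    "GroupingResult",
    "relational_groups",
    "correlation_matrix",
    "corgroups",
    "combine_groupings",
    "correlation_test",
    "compute_groupings",
]

_METHODS = ("pearson", "spearman", "kendall")


@dataclass(frozen=True)
class CorrelationParams:
    """Parameters of the correlation-based grouping.

    method : pearson | spearman | kendall
    rt_window : max |Δrt| in seconds for a pair to be considered (default 2)
    threshold : pairwise correlation both features must strictly exceed (default 0.8)
    min_pairs : minimum complete (both detected) sample pairs for a defined
        correlation (default 4); undefined correlations never link features
    """

    method: str = "pearson"
    rt_window: float = 2.0
    threshold: float = 0.8
    min_pairs: int = 4

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValidationError(f"unknown correlation method {self.method!r}")
        if not (0 < self.threshold <= 1):
            raise ValidationError("threshold must be in (0, 1]")
        if self.min_pairs < 3:
            raise ValidationError("min_pairs must be >= 3")


Assignment = dict[str, Optional[int]]


@dataclass
class GroupingResult:
    """Feature → group-index maps for both methods and their combinations."""

    group: Assignment
    corgroup: Assignment
    combined_intersect: Assignment
    combined_union: Assignment


def _sort_key(table: Optional[FeatureTable]):
    if table is None:
        return lambda fid: (np.inf, np.inf, fid)

    def key(fid: str):
        f = table.get(fid)
        return (np.inf if f.rt is None else f.rt, f.mz, fid)

    return key


def _number_components(
    components: Iterable[set[str]],
    table: Optional[FeatureTable],
    all_ids: Iterable[str],
) -> Assignment:
    """Assign dense 1..K indices to size>=2 components, earliest rt first."""
    key = _sort_key(table)
    comps = [c for c in components if len(c) >= 2]
    comps.sort(key=lambda c: min(key(fid) for fid in c))
    assignment: Assignment = {fid: None for fid in all_ids}
    for idx, comp in enumerate(comps, start=1):
        for fid in comp:
            assignment[fid] = idx
    return assignment


def relational_groups(
    edges: Sequence[AnnotationEdge],
    table: Optional[FeatureTable] = None,
) -> Assignment:
    """Merge all related features into groups by connected components.

    Any relation — in-source fragment, adduct, neutral loss, isotope,
    shared primary ion — contributes an undirected edge.  Components of
    size >= 2 get dense indices ordered by earliest-eluting member (ties:
    lowest m/z, then id); isolated features stay unassigned.  ``table`` is
    only used for the ordering and to include edge-less features in the
    returned map.
    """
    g = nx.Graph()
    if table is not None:
        g.add_nodes_from(table.ids)
    for e in edges:
        g.add_edge(e.source_id, e.target_id)
    return _number_components(
        (set(c) for c in nx.connected_components(g)), table, list(g.nodes)
    )


def _log10_missing(x: np.ndarray) -> np.ndarray:
    """log10 with non-detections (zeros, negatives, NaN) as NaN."""
    out = np.full_like(x, np.nan, dtype=float)
    ok = np.isfinite(x) & (x > 0)
    out[ok] = np.log10(x[ok])
    return out


def _pair_correlation(
    xa: np.ndarray, xb: np.ndarray, method: str, min_pairs: int
) -> tuple[Optional[float], Optional[float], int]:
    """(coefficient, p-value, n complete pairs); (None, None, n) when undefined."""
    ok = np.isfinite(xa) & np.isfinite(xb)
    n = int(ok.sum())
    if n < min_pairs:
        return None, None, n
    a, b = xa[ok], xb[ok]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None, None, n
    if method == "pearson":
        r = stats.pearsonr(a, b)
    elif method == "spearman":
        r = stats.spearmanr(a, b)
    else:
        r = stats.kendalltau(a, b)
    coef, p = float(r.statistic), float(r.pvalue)
    if not np.isfinite(coef):
        return None, None, n
    return coef, p, n


def correlation_matrix(
    table: FeatureTable,
    params: CorrelationParams = CorrelationParams(),
) -> dict[tuple[str, str], float]:
    """Pairwise profile correlations restricted to rt-compatible pairs.

    Returns a sparse map {(id_a, id_b): r} with id_a < id_b, containing only
    pairs whose retention times differ by at most ``params.rt_window`` and
    whose correlation is defined (enough complete sample pairs, non-constant
    vectors).  Intensities are log10-transformed; zeros and missing values
    are treated as non-detections and excluded pairwise.
    """
    if len(table.sample_names) < 2:
        raise ValidationError("correlation requires at least 2 samples")
    logx = _log10_missing(table.intensity_matrix())
    rt = table.rt_array()
    order = np.argsort(np.where(np.isfinite(rt), rt, np.inf), kind="stable")
    ids = table.ids
    out: dict[tuple[str, str], float] = {}
    n = len(table)
    for ii in range(n):
        i = order[ii]
        if not np.isfinite(rt[i]):
            continue
        for jj in range(ii + 1, n):
            j = order[jj]
            if not np.isfinite(rt[j]) or rt[j] - rt[i] > params.rt_window:
                break
            coef, _, _ = _pair_correlation(logx[i], logx[j], params.method, params.min_pairs)
            if coef is None:
                continue
            key = (ids[i], ids[j]) if ids[i] < ids[j] else (ids[j], ids[i])
            out[key] = coef
    return out


def _clique_key(clique: frozenset[str], corr, sortkey):
    pairs = list(itertools.combinations(sorted(clique), 2))
    mean_corr = float(np.mean([corr[(a, b) if a < b else (b, a)] for a, b in pairs]))
    return (-len(clique), -mean_corr, min(sortkey(f) for f in clique), tuple(sorted(clique)))


def corgroups(
    table: FeatureTable,
    corr: Mapping[tuple[str, str], float],
    params: CorrelationParams = CorrelationParams(),
) -> Assignment:
    """Partition features into correlation cliques ("corgroup" index).

    Edges connect pairs whose correlation strictly exceeds the threshold.
    Within each component, maximal cliques are extracted greedily — largest
    first, ties broken by highest mean pairwise correlation, then earliest
    eluting member — and removed, so every corgroup is a clique and every
    feature carries at most one corgroup index.
    """
    canonical = {(a, b) if a < b else (b, a): r for (a, b), r in corr.items()}
    corr = canonical
    g = nx.Graph()
    g.add_nodes_from(table.ids)
    for (a, b), r in corr.items():
        if r > params.threshold:
            g.add_edge(a, b)
    sortkey = _sort_key(table)
    groups: list[set[str]] = []
    work = g.copy()
    while work.number_of_edges() > 0:
        cliques = [frozenset(c) for c in nx.find_cliques(work) if len(c) >= 2]
        best = min(cliques, key=lambda c: _clique_key(c, corr, sortkey))
        groups.append(set(best))
        work.remove_nodes_from(best)
    return _number_components(groups, table, table.ids)


def _cogrouped_pairs(assignment: Assignment) -> set[frozenset[str]]:
    groups: dict[int, list[str]] = {}
    for fid, idx in assignment.items():
        if idx is not None:
            groups.setdefault(idx, []).append(fid)
    pairs: set[frozenset[str]] = set()
    for members in groups.values():
        for a, b in itertools.combinations(members, 2):
            pairs.add(frozenset((a, b)))
    return pairs


def combine_groupings(
    group: Assignment,
    corgroup: Assignment,
    mode: str,
    table: Optional[FeatureTable] = None,
) -> Assignment:
    """Combine the two grouping indices pairwise.

    ``intersect`` co-groups a pair iff both assignments co-group it;
    ``union`` iff either does.  The surviving pair set is turned back into
    an assignment via connected components (dense indices, rt-ordered).
    """
    if mode not in ("intersect", "union"):
        raise ValueError(f"unknown combine mode {mode!r}")
    pa = _cogrouped_pairs(group)
    pb = _cogrouped_pairs(corgroup)
    pairs = pa & pb if mode == "intersect" else pa | pb
    g = nx.Graph()
    all_ids = set(group) | set(corgroup)
    g.add_nodes_from(all_ids)
    for pair in pairs:
        a, b = tuple(pair)
        g.add_edge(a, b)
    return _number_components(
        (set(c) for c in nx.connected_components(g)), table, all_ids
    )


def correlation_test(
    table: FeatureTable,
    id_a: str,
    id_b: str,
    params: CorrelationParams = CorrelationParams(),
) -> tuple[Optional[float], Optional[float], int]:
    """Correlation test for one feature pair.

    Returns (coefficient, two-sided p-value, n complete pairs); the
    coefficient and p-value are None when fewer than ``min_pairs`` complete
    observations exist or a vector is constant.
    """
    fa, fb = table.get(id_a), table.get(id_b)
    return _pair_correlation(
        _log10_missing(fa.intensities),
        _log10_missing(fb.intensities),
        params.method,
        params.min_pairs,
    )


def compute_groupings(
    table: FeatureTable,
    edges: Sequence[AnnotationEdge],
    params: CorrelationParams = CorrelationParams(),
) -> tuple[GroupingResult, dict[tuple[str, str], float]]:
    """Run both grouping methods and their combinations in one call."""
    group = relational_groups(edges, table)
    corr = correlation_matrix(table, params)
    cg = corgroups(table, corr, params)
    return (
        GroupingResult(
            group=group,
            corgroup=cg,
            combined_intersect=combine_groupings(group, cg, "intersect", table),
            combined_union=combine_groupings(group, cg, "union", table),
        ),
        corr,
    )
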