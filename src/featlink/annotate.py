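"""MS1-only annotation passes.

Four passes over the feature table, each driven by mass arithmetic within a
paired absolute-Da / ppm tolerance and a retention-time window:

* target matching — primary ions computed from molecular formulas matched
  by m/z (default 0.002 Da or 5 ppm) and rt (default 20 s);
* adduct annotation — expected adduct m/z values derived from matched
  targets, searched near the primary feature (default 0.005 Da or 5 ppm,
  2 s);
* isotope / charge-state annotation — 13C isotopologue chains at spacings
  1.0034 / z for z in {1, 2, 3}, up to order 4 (0.002 Da for the first
  isotope, 0.01 for higher orders, rt window 3 s);
* neutral-loss annotation — pairwise m/z differences compared against a
  neutral-loss table (default 0.002 Da or 5 ppm, rt window 2 s).

The "0.002 or 5 ppm" style tolerance is read as the maximum of the two
widths at the expected m/z, so the absolute floor governs at low mass and
the ppm term at high mass.  An rt window w admits pairs with |Δrt| <= w.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .chem import C13_SPACING, apply_adduct, formula_mass, primary_ion_mz
from .core import (
    AdductRule,
    AnnotationEdge,
    FeatureTable,
    NeutralLossEntry,
    TargetMetabolite,
    ValidationError,
)

__all__ = [
    "ToleranceSpec",
    "within_tolerance",
    "TargetMatch",
    "match_targets",
    "annotate_adducts",
    "IsotopeAnnotation",
    "annotate_isotopes",
    "annotate_neutral_losses",
]


@dataclass(frozen=True)
class ToleranceSpec:
    """Paired absolute (Da) and relative (ppm) m/z tolerance.

    The effective width at an expected m/z x is max(abs_da, ppm * x * 1e-6);
    at least one of the two components must be positive.
    """

    abs_da: float
    ppm: float

    def __post_init__(self) -> None:
        if self.abs_da < 0 or self.ppm < 0:
            raise ValidationError("tolerances must be non-negative")
        if self.abs_da == 0 and self.ppm == 0:
            raise ValidationError("at least one of abs_da, ppm must be positive")

    def width(self, expected_mz: float) -> float:
        return max(self.abs_da, self.ppm * expected_mz * 1e-6)


def within_tolerance(observed: float, expected: float, tol: ToleranceSpec) -> bool:
    """True iff |observed - expected| is within the effective width at ``expected``."""
    return abs(observed - expected) <= tol.width(expected)


@dataclass(frozen=True)
class TargetMatch:
    """One (feature, target) primary-ion match."""

    feature_id: str
    target: TargetMetabolite
    expected_mz: float
    mz_diff: float  # observed - expected, Da
    rt_diff: Optional[float]  # feature rt - target rt, s; None when target rt absent
    best: bool = False  # closest-Δm/z match among a feature's targets


def match_targets(
    table: FeatureTable,
    targets: Sequence[TargetMetabolite],
    ion_mode: str,
    tol: ToleranceSpec = ToleranceSpec(0.002, 5.0),
    rt_window: float = 20.0,
) -> tuple[list[TargetMatch], list[AnnotationEdge]]:
    """Match target primary ions against the feature table.

    A feature matches a target iff its m/z is within ``tol`` of the target's
    primary-ion m/z and, when the target carries a retention time,
    |rt_feature - rt_target| <= ``rt_window``.  All matches are recorded;
    for a feature hit by several targets the closest-Δm/z one is flagged
    ``best`` (ties: smallest |Δrt|, then target name).  When one target is
    hit by several features, the best-matching feature is linked to the
    others by ``primary`` edges so they enter the same relational group.
    """
    mz = table.mz_array()
    rt = table.rt_array()
    matches: list[TargetMatch] = []
    per_target: dict[str, list[TargetMatch]] = {}
    for t in targets:
        expected = primary_ion_mz(t, ion_mode)
        w = tol.width(expected)
        hits = np.flatnonzero(np.abs(mz - expected) <= w)
        for i in hits:
            rt_diff = None
            if t.rt is not None:
                if not np.isfinite(rt[i]) or abs(rt[i] - t.rt) > rt_window:
                    continue
                rt_diff = float(rt[i] - t.rt)
            m = TargetMatch(
                feature_id=table.features[i].id,
                target=t,
                expected_mz=expected,
                mz_diff=float(mz[i] - expected),
                rt_diff=rt_diff,
            )
            matches.append(m)
            per_target.setdefault(t.name, []).append(m)

    # flag best target per feature
    by_feature: dict[str, list[int]] = {}
    for idx, m in enumerate(matches):
        by_feature.setdefault(m.feature_id, []).append(idx)
    flagged: list[TargetMatch] = list(matches)
    for fid, idxs in by_feature.items():
        best_idx = min(
            idxs,
            key=lambda k: (
                abs(matches[k].mz_diff),
                abs(matches[k].rt_diff) if matches[k].rt_diff is not None else np.inf,
                matches[k].target.name,
            ),
        )
        flagged[best_idx] = TargetMatch(**{**matches[best_idx].__dict__, "best": True})

    edges: list[AnnotationEdge] = []
    for name, ms in sorted(per_target.items()):
        if len(ms) < 2:
            continue
        anchor = min(ms, key=lambda m: (abs(m.mz_diff), m.feature_id))
        fa = table.get(anchor.feature_id)
        for m in ms:
            if m.feature_id == anchor.feature_id:
                continue
            fb = table.get(m.feature_id)
            rt_diff = None
            if fa.rt is not None and fb.rt is not None:
                rt_diff = fb.rt - fa.rt
            edges.append(
                AnnotationEdge(
                    source_id=anchor.feature_id,
                    target_id=m.feature_id,
                    relation="primary",
                    detail=f"primary ion of {name}",
                    mz_diff=fb.mz - fa.mz,
                    rt_diff=rt_diff,
                )
            )
    return flagged, edges


def annotate_adducts(
    table: FeatureTable,
    primary_matches: Sequence[TargetMatch],
    adduct_rules: Sequence[AdductRule],
    tol: ToleranceSpec = ToleranceSpec(0.005, 5.0),
    rt_window: float = 2.0,
) -> tuple[list[AnnotationEdge], dict[str, list[str]]]:
    """Annotate adducts and multimers of matched targets.

    For every (primary feature, target) pair and every rule of the matching
    ion mode, the expected adduct m/z is computed from the target's neutral
    mass; features within ``tol`` of it and within ``rt_window`` seconds of
    the primary feature are labelled "<rule> of <target>" and linked to the
    primary feature by an ``adduct_sibling`` edge.  The primary feature is
    never its own adduct; the primary-ion rule itself is skipped.
    """
    mz = table.mz_array()
    rt = table.rt_array()
    edges: list[AnnotationEdge] = []
    labels: dict[str, list[str]] = {}
    neutral_cache: dict[str, float] = {}
    primary_rule = {"positive": "[M+H]+", "negative": "[M-H]-"}

    for match in primary_matches:
        t = match.target
        if t.formula not in neutral_cache:
            neutral_cache[t.formula] = formula_mass(t.formula)
        neutral = neutral_cache[t.formula]
        fp = table.get(match.feature_id)
        fp_idx = table.ids.index(match.feature_id)
        for rule in adduct_rules:
            if rule.name == primary_rule.get(rule.ion_mode):
                continue
            expected = apply_adduct(neutral, rule)
            w = tol.width(expected)
            hits = np.flatnonzero(np.abs(mz - expected) <= w)
            for i in hits:
                if i == fp_idx:
                    continue
                if fp.rt is not None and np.isfinite(rt[i]) and abs(rt[i] - fp.rt) > rt_window:
                    continue
                fb = table.features[i]
                label = f"{rule.name} of {t.name}"
                labels.setdefault(fb.id, []).append(label)
                edges.append(
                    AnnotationEdge(
                        source_id=fp.id,
                        target_id=fb.id,
                        relation="adduct_sibling",
                        detail=label,
                        mz_diff=fb.mz - fp.mz,
                        rt_diff=None if fp.rt is None or fb.rt is None else fb.rt - fp.rt,
                    )
                )
    from .core import dedupe_edges

    return dedupe_edges(edges), labels


@dataclass(frozen=True)
class IsotopeAnnotation:
    """An isotopologue assignment: feature is the [M+order] peak of anchor."""

    feature_id: str
    anchor_id: str
    order: int  # 1..4
    charge: int  # 1 | 2 | 3
    deviation: float  # |observed spacing - expected|, Da


def annotate_isotopes(
    table: FeatureTable,
    rt_window: float = 3.0,
    first_tol: float = 0.002,
    higher_tol: float = 0.01,
    charges: Sequence[int] = (1, 2, 3),
    max_order: int = 4,
) -> tuple[list[IsotopeAnnotation], list[AnnotationEdge], dict[str, int]]:
    """Detect 13C isotopologue chains and assign charge states.

    For each candidate anchor and charge z, satellites are sought at
    ``n * 1.0034 / z`` above the anchor (n = 1..4) within the rt window.
    The first-order spacing must match within ``first_tol`` Da; higher
    orders within ``higher_tol`` Da (wide enough to also capture peaks
    dominated by heavier isotopes of S, Cl or Br).  A chain must be
    contiguous: order n is only considered once order n-1 was found, which
    is what distinguishes a genuine z=2 chain (spacing 0.5017) from the
    even-order subset of a z=1 chain.  A feature claimed by several chains
    keeps the assignment with the smallest spacing deviation (ties: higher
    charge, then lower anchor m/z).  Anchors that are themselves isotopes
    are compressed to the chain root; orders above ``max_order`` after
    compression are dropped.

    Returns the assignments, anchor→satellite ``isotope`` edges with detail
    "[M+n]", and a feature→charge map covering chain members and anchors.
    """
    rt_all = table.rt_array()
    if len(table) and not np.any(np.isfinite(rt_all)):
        raise ValidationError("isotope annotation requires retention times")

    order_idx = np.argsort(table.mz_array(), kind="stable")
    feats = [table.features[i] for i in order_idx]
    mz = np.array([f.mz for f in feats])
    rt = np.array([np.nan if f.rt is None else f.rt for f in feats])
    n = len(feats)

    # candidate per satellite feature index: (deviation, -charge, anchor_mz, anchor_idx, order)
    best: dict[int, tuple] = {}
    for a in range(n):
        if not np.isfinite(rt[a]):
            continue
        for z in charges:
            spacing = C13_SPACING / z
            prev_found = True
            for k in range(1, max_order + 1):
                if not prev_found:
                    break
                tol_k = first_tol if k == 1 else higher_tol
                expected = mz[a] + k * spacing
                lo = np.searchsorted(mz, expected - tol_k, side="left")
                hi = np.searchsorted(mz, expected + tol_k, side="right")
                cand = [
                    j for j in range(lo, hi)
                    if j != a and np.isfinite(rt[j]) and abs(rt[j] - rt[a]) <= rt_window
                    and mz[j] > mz[a]
                ]
                if not cand:
                    prev_found = False
                    continue
                j = min(cand, key=lambda j: (abs(mz[j] - expected), mz[j], feats[j].id))
                dev = abs(mz[j] - expected)
                key = (dev, -z, mz[a], feats[a].id)
                if j not in best or key < best[j][:4]:
                    best[j] = (dev, -z, mz[a], feats[a].id, a, k)

    assigned: dict[int, tuple[int, int, int, float]] = {
        j: (rec[4], rec[5], -rec[1], rec[0]) for j, rec in best.items()
    }  # satellite -> (anchor_idx, order, charge, deviation)

    annotations: list[IsotopeAnnotation] = []
    edges: list[AnnotationEdge] = []
    charge_of: dict[str, int] = {}
    for j in sorted(assigned):
        anchor, order, z, dev = assigned[j]
        seen = {j}
        while anchor in assigned and anchor not in seen:
            seen.add(anchor)
            up_anchor, up_order, _, _ = assigned[anchor]
            order += up_order
            anchor = up_anchor
        if anchor in seen or order > max_order:
            continue
        fa, fj = feats[anchor], feats[j]
        annotations.append(IsotopeAnnotation(fj.id, fa.id, order, z, dev))
        edges.append(
            AnnotationEdge(
                source_id=fa.id,
                target_id=fj.id,
                relation="isotope",
                detail=f"[M+{order}]",
                mz_diff=fj.mz - fa.mz,
                rt_diff=None if fa.rt is None or fj.rt is None else fj.rt - fa.rt,
            )
        )
        charge_of[fj.id] = z
        charge_of.setdefault(fa.id, z)
    return annotations, edges, charge_of


def annotate_neutral_losses(
    table: FeatureTable,
    nl_table: Sequence[NeutralLossEntry],
    rt_window: float = 2.0,
    tol: ToleranceSpec = ToleranceSpec(0.002, 5.0),
) -> list[AnnotationEdge]:
    """Annotate neutral losses between co-eluting feature pairs.

    Every unordered pair with |Δrt| <= ``rt_window`` is checked: if the
    absolute m/z difference is within tolerance of some table entry, a
    ``neutral_loss`` edge runs from the heavier (parent) to the lighter
    feature with the entry name as detail.  When several entries match, the
    closest in mass wins.  Output is independent of input row order.
    """
    if not nl_table or not len(table):
        return []
    nl_masses = np.array([e.mass for e in nl_table])
    nl_order = np.argsort(nl_masses, kind="stable")
    nl_sorted = [nl_table[i] for i in nl_order]
    nl_masses = nl_masses[nl_order]
    max_allow = nl_masses[-1] + tol.width(nl_masses[-1]) + 0.01

    order_idx = np.argsort(table.mz_array(), kind="stable")
    feats = [table.features[i] for i in order_idx]
    mz = np.array([f.mz for f in feats])
    rt = np.array([np.nan if f.rt is None else f.rt for f in feats])
    n = len(feats)

    edges: list[AnnotationEdge] = []
    for i in range(n):  # lighter feature
        for j in range(i + 1, n):  # heavier
            diff = mz[j] - mz[i]
            if diff > max_allow:
                break
            if diff <= 0:
                continue
            if np.isfinite(rt[i]) and np.isfinite(rt[j]) and abs(rt[j] - rt[i]) > rt_window:
                continue
            hits = [
                e for e, m in zip(nl_sorted, nl_masses)
                if within_tolerance(diff, m, tol)
            ]
            if not hits:
                continue
            entry = min(hits, key=lambda e: (abs(diff - e.mass), e.name))
            edges.append(
                AnnotationEdge(
                    source_id=feats[j].id,
                    target_id=feats[i].id,
                    relation="neutral_loss",
                    detail=entry.name,
                    mz_diff=mz[i] - mz[j],
                    rt_diff=None
                    if not (np.isfinite(rt[i]) and np.isfinite(rt[j]))
                    else rt[i] - rt[j],
                )
            )
    from .core import dedupe_edges

    return dedupe_edges(edges)
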