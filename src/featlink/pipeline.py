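"""End-to-end annotation pipeline tying the passes together.

Runs, in order: target matching, adduct annotation, ISF annotation from
MS2, isotope/charge annotation, neutral-loss annotation, and both grouping
methods.  Target-dependent passes are skipped without a target list and the
ISF pass without MS2 spectra, so the pipeline degrades gracefully to an
MS1-only run.  The whole path is deterministic — no randomness anywhere —
so rerunning on the same inputs reproduces outputs exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import annotate as _ann
from . import grouping as _grp
from . import isf as _isf
from .annotate import IsotopeAnnotation, TargetMatch, ToleranceSpec
from .core import (
    AdductRule,
    AnnotationEdge,
    FeatureTable,
    MS2Spectrum,
    NeutralLossEntry,
    TargetMetabolite,
)
from .formats import ANNOTATION_COLUMNS, AnnotatedFeatureTable, read_rule_tables
from .grouping import CorrelationParams, GroupingResult
from .isf import PrecursorMatch

__all__ = ["RunConfig", "PipelineResult", "run_annotation"]


@dataclass
class RunConfig:
    """Every tunable threshold of the pipeline, at its default value.

    m/z tolerances are paired absolute-Da / ppm values (effective width is
    the maximum of the two at the expected m/z); rt windows are maximal
    absolute retention-time differences in seconds.
    """

    ion_mode: str = "positive"
    # step 2: target matching
    target_abs_da: float = 0.002
    target_ppm: float = 5.0
    target_rt_window: float = 20.0
    # step 3: adduct annotation
    adduct_abs_da: float = 0.005
    adduct_ppm: float = 5.0
    adduct_rt_window: float = 2.0
    # step 4: ISF annotation
    precursor_abs_da: float = 0.002
    precursor_ppm: float = 5.0
    precursor_rt_window: float = 20.0
    fragment_abs_da: float = 0.005
    fragment_ppm: float = 10.0
    isf_coelution_window: float = 3.0
    isf_min_rel_intensity: float = 0.01
    # step 5: isotopes / charge states
    isotope_rt_window: float = 3.0
    isotope_first_tol: float = 0.002
    isotope_higher_tol: float = 0.01
    # step 6: neutral losses
    nl_abs_da: float = 0.002
    nl_ppm: float = 5.0
    nl_rt_window: float = 2.0
    # step 7: correlation grouping
    corr_method: str = "pearson"
    corr_threshold: float = 0.8
    corr_rt_window: float = 2.0
    corr_min_pairs: int = 4

    def correlation_params(self) -> CorrelationParams:
        return CorrelationParams(
            method=self.corr_method,
            rt_window=self.corr_rt_window,
            threshold=self.corr_threshold,
            min_pairs=self.corr_min_pairs,
        )


@dataclass
class PipelineResult:
    """Everything one annotation run produces."""

    annotated: AnnotatedFeatureTable
    edges: list[AnnotationEdge]
    grouping: GroupingResult
    correlations: dict[tuple[str, str], float]
    target_matches: list[TargetMatch]
    isotope_annotations: list[IsotopeAnnotation]
    precursor_matches: list[PrecursorMatch]


def _join(parts: Sequence[str]) -> str:
    return "; ".join(parts)


def run_annotation(
    table: FeatureTable,
    targets: Optional[Sequence[TargetMetabolite]] = None,
    spectra: Optional[Sequence[MS2Spectrum]] = None,
    adduct_rules: Optional[Sequence[AdductRule]] = None,
    nl_entries: Optional[Sequence[NeutralLossEntry]] = None,
    config: RunConfig = RunConfig(),
) -> PipelineResult:
    """Annotate a feature table and assign both group indices.

    ``targets`` and ``spectra`` are optional: without targets the target
    and adduct passes are skipped, without spectra the ISF pass.  Rule
    tables default to the bundled ones.
    """
    if adduct_rules is None or nl_entries is None:
        bundled_adducts, bundled_nl = read_rule_tables()
        adduct_rules = bundled_adducts if adduct_rules is None else adduct_rules
        nl_entries = bundled_nl if nl_entries is None else nl_entries

    edges: list[AnnotationEdge] = []
    target_matches: list[TargetMatch] = []
    adduct_labels: dict[str, list[str]] = {}
    if targets:
        target_matches, primary_edges = _ann.match_targets(
            table,
            targets,
            config.ion_mode,
            tol=ToleranceSpec(config.target_abs_da, config.target_ppm),
            rt_window=config.target_rt_window,
        )
        edges.extend(primary_edges)
        adduct_edges, adduct_labels = _ann.annotate_adducts(
            table,
            target_matches,
            [r for r in adduct_rules if r.ion_mode == config.ion_mode],
            tol=ToleranceSpec(config.adduct_abs_da, config.adduct_ppm),
            rt_window=config.adduct_rt_window,
        )
        edges.extend(adduct_edges)

    precursor_matches: list[PrecursorMatch] = []
    isf_edges: list[AnnotationEdge] = []
    if spectra:
        precursor_matches = _isf.align_precursors(
            spectra,
            table,
            tol=ToleranceSpec(config.precursor_abs_da, config.precursor_ppm),
            rt_window=config.precursor_rt_window,
        )
        isf_edges = _isf.annotate_isf(
            precursor_matches,
            spectra,
            table,
            frag_tol=ToleranceSpec(config.fragment_abs_da, config.fragment_ppm),
            coelution_window=config.isf_coelution_window,
            min_rel_intensity=config.isf_min_rel_intensity,
        )
        edges.extend(isf_edges)

    iso_annotations, iso_edges, charge_of = _ann.annotate_isotopes(
        table,
        rt_window=config.isotope_rt_window,
        first_tol=config.isotope_first_tol,
        higher_tol=config.isotope_higher_tol,
    )
    edges.extend(iso_edges)

    nl_edges = _ann.annotate_neutral_losses(
        table,
        nl_entries,
        rt_window=config.nl_rt_window,
        tol=ToleranceSpec(config.nl_abs_da, config.nl_ppm),
    )
    edges.extend(nl_edges)

    group = _grp.relational_groups(edges, table)
    if len(table.sample_names) >= 2:
        corr = _grp.correlation_matrix(table, config.correlation_params())
        cg = _grp.corgroups(table, corr, config.correlation_params())
    else:
        corr = {}
        cg = {fid: None for fid in table.ids}
    grouping = GroupingResult(
        group=group,
        corgroup=cg,
        combined_intersect=_grp.combine_groupings(group, cg, "intersect", table),
        combined_union=_grp.combine_groupings(group, cg, "union", table),
    )

    # assemble per-feature annotation strings
    target_labels: dict[str, list[str]] = {}
    for m in sorted(target_matches, key=lambda m: (not m.best, abs(m.mz_diff))):
        target_labels.setdefault(m.feature_id, []).append(m.target.name)
    iso_labels: dict[str, str] = {
        a.feature_id: f"[M+{a.order}] of {a.anchor_id}" for a in iso_annotations
    }
    nl_labels: dict[str, list[str]] = {}
    for e in nl_edges:
        nl_labels.setdefault(e.target_id, []).append(f"{e.detail} from {e.source_id}")
    isf_labels: dict[str, list[str]] = {}
    for e in isf_edges:
        isf_labels.setdefault(e.target_id, []).append(e.source_id)

    rows = {
        "target": [_join(target_labels.get(fid, [])) for fid in table.ids],
        "adduct": [_join(adduct_labels.get(fid, [])) for fid in table.ids],
        "isotope": [iso_labels.get(fid, "") for fid in table.ids],
        "charge": ["" if fid not in charge_of else str(charge_of[fid]) for fid in table.ids],
        "neutral_loss": [_join(nl_labels.get(fid, [])) for fid in table.ids],
        "isf_parent": [_join(sorted(set(isf_labels.get(fid, [])))) for fid in table.ids],
    }
    for col, assignment in [
        ("group", grouping.group),
        ("corgroup", grouping.corgroup),
        ("group_intersect", grouping.combined_intersect),
        ("group_union", grouping.combined_union),
    ]:
        rows[col] = [
            "" if assignment.get(fid) is None else str(assignment[fid]) for fid in table.ids
        ]
    annotations = pd.DataFrame(rows, index=table.ids)[ANNOTATION_COLUMNS]

    return PipelineResult(
        annotated=AnnotatedFeatureTable(table=table, annotations=annotations),
        edges=edges,
        grouping=grouping,
        correlations=corr,
        target_matches=target_matches,
        isotope_annotations=iso_annotations,
        precursor_matches=precursor_matches,
    )
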