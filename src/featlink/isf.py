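"""In-source-fragment (ISF) annotation from DDA MS2 spectra.

Fragments formed in the ESI source show up as independent MS1 features that
co-elute with their parent ion.  Given DDA MS2 data (ideally from a pool
sample), parents and fragments are linked in two steps: precursor ions are
aligned to MS1 features (default 0.002 Da or 5 ppm, rt window 20 s), then
each aligned spectrum's fragment peaks are matched back to MS1 features
(default 0.005 Da or 10 ppm).  A matched feature is annotated as an ISF of
the precursor feature only if it co-elutes with it (default 3 s) and is
lighter than it; fragment peaks below a relative-intensity floor (default
1% of the base peak) are ignored as noise.  With no spectra the module
emits nothing and the pipeline degrades to an MS1-only run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .annotate import ToleranceSpec
from .core import AnnotationEdge, FeatureTable, MS2Spectrum, dedupe_edges

__all__ = ["PrecursorMatch", "align_precursors", "annotate_isf"]


@dataclass(frozen=True)
class PrecursorMatch:
    """One MS2 spectrum aligned to the MS1 feature its precursor came from."""

    spectrum_index: int
    feature_id: str
    mz_diff: float  # precursor mz - feature mz
    rt_diff: Optional[float]  # precursor rt - feature rt; None when rt unverified


def align_precursors(
    spectra: Sequence[MS2Spectrum],
    table: FeatureTable,
    tol: ToleranceSpec = ToleranceSpec(0.002, 5.0),
    rt_window: float = 20.0,
) -> list[PrecursorMatch]:
    """Align DDA precursor ions to MS1 features.

    Each spectrum is matched to the nearest-m/z feature satisfying both the
    m/z tolerance and the rt window.  Spectra without a recorded precursor
    retention time are matched on m/z alone; unmatched spectra are dropped
    from the downstream ISF search.
    """
    mz = table.mz_array()
    rt = table.rt_array()
    matches: list[PrecursorMatch] = []
    for si, spec in enumerate(spectra):
        w = tol.width(spec.precursor_mz)
        cand = np.flatnonzero(np.abs(mz - spec.precursor_mz) <= w)
        if spec.precursor_rt is not None:
            cand = [
                i for i in cand
                if np.isfinite(rt[i]) and abs(rt[i] - spec.precursor_rt) <= rt_window
            ]
        if len(cand) == 0:
            continue
        i = min(cand, key=lambda i: (abs(mz[i] - spec.precursor_mz), table.features[i].id))
        matches.append(
            PrecursorMatch(
                spectrum_index=si,
                feature_id=table.features[i].id,
                mz_diff=float(spec.precursor_mz - mz[i]),
                rt_diff=None
                if spec.precursor_rt is None or not np.isfinite(rt[i])
                else float(spec.precursor_rt - rt[i]),
            )
        )
    return matches


def annotate_isf(
    matches: Sequence[PrecursorMatch],
    spectra: Sequence[MS2Spectrum],
    table: FeatureTable,
    frag_tol: ToleranceSpec = ToleranceSpec(0.005, 10.0),
    coelution_window: float = 3.0,
    min_rel_intensity: float = 0.01,
) -> list[AnnotationEdge]:
    """Match MS2 fragment peaks to MS1 features as in-source fragments.

    For every aligned spectrum, each fragment peak at or above
    ``min_rel_intensity`` of the base peak is compared to all MS1 features.
    A feature is linked as an ISF of the precursor feature iff its m/z is
    within ``frag_tol`` of the fragment m/z, it elutes within
    ``coelution_window`` seconds of the precursor feature, and it is
    lighter than the precursor feature.  Edges run precursor → fragment
    feature; a feature may be the ISF of several precursors (multimers
    legitimately share fragments).  Precursor matches made without a
    retention time are flagged "rt-unverified" in the edge detail.
    """
    mz = table.mz_array()
    rt = table.rt_array()
    edges: list[AnnotationEdge] = []
    for m in sorted(matches, key=lambda m: (m.feature_id, m.spectrum_index)):
        spec = spectra[m.spectrum_index]
        prec = table.get(m.feature_id)
        prec_idx = table.ids.index(m.feature_id)
        if spec.peaks.shape[0] == 0:
            continue
        base = float(spec.peaks[:, 1].max())
        if base <= 0:
            continue
        flag = "" if m.rt_diff is not None else ", rt-unverified"
        for frag_mz, inten in spec.peaks:
            if inten < min_rel_intensity * base:
                continue
            w = frag_tol.width(frag_mz)
            hits = np.flatnonzero(np.abs(mz - frag_mz) <= w)
            for i in hits:
                if i == prec_idx or mz[i] >= prec.mz:
                    continue
                if (
                    prec.rt is not None
                    and np.isfinite(rt[i])
                    and abs(rt[i] - prec.rt) > coelution_window
                ):
                    continue
                fb = table.features[i]
                edges.append(
                    AnnotationEdge(
                        source_id=prec.id,
                        target_id=fb.id,
                        relation="isf",
                        detail=f"ISF of {prec.id}{flag}",
                        mz_diff=fb.mz - prec.mz,
                        rt_diff=None
                        if prec.rt is None or fb.rt is None
                        else fb.rt - prec.rt,
                    )
                )
    return dedupe_edges(edges)
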