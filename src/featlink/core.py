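"""Core domain types shared by every stage of the annotation workflow.

The unit of analysis is the MS1 *feature*: one chromatographic peak with an
m/z, a retention time and a vector of per-sample intensities.  Everything the
package does — adduct, isotope, neutral-loss and in-source-fragment
annotation, and the two grouping indices — attaches information to features
or draws typed edges between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Feature",
    "FeatureTable",
    "MS2Spectrum",
    "TargetMetabolite",
    "AdductRule",
    "NeutralLossEntry",
    "AnnotationEdge",
    "RELATIONS",
    "ValidationError",
    "FormatError",
]

#: Closed set of relation tokens an AnnotationEdge may carry.
RELATIONS = frozenset({"isotope", "adduct_sibling", "neutral_loss", "isf", "primary"})


class ValidationError(ValueError):
    """An object violates a structural invariant (duplicate ids, bad mass, ...)."""


class FormatError(ValueError):
    """An external file cannot be interpreted (missing column, bad value, ...)."""


@dataclass
class Feature:
    """One MS1 peak.

    Parameters
    ----------
    id : str
        Unique, non-empty identifier.
    mz : float
        Mass-to-charge ratio in Da; must be positive.
    rt : float or None
        Retention time in seconds (canonical unit); ``None`` when the
        upstream table carries no retention times.
    intensities : numpy.ndarray
        Per-sample intensities aligned with the owning table's
        ``sample_names``.  ``NaN`` encodes a missing value; zeros are kept
        as written but are treated as non-detections wherever intensity
        profiles are correlated.
    """

    id: str
    mz: float
    rt: Optional[float]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("feature id must be non-empty")
        if not np.isfinite(self.mz) or self.mz <= 0:
            raise ValidationError(f"feature {self.id!r}: m/z must be positive, got {self.mz}")
        if self.rt is not None and (not np.isfinite(self.rt) or self.rt < 0):
            raise ValidationError(f"feature {self.id!r}: rt must be >= 0 s, got {self.rt}")
        self.intensities = np.asarray(self.intensities, dtype=float)


@dataclass
class FeatureTable:
    """An ordered collection of features sharing one sample panel."""

    features: list[Feature]
    sample_names: list[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dupes: list[str] = []
        for f in self.features:
            if f.id in seen:
                dupes.append(f.id)
            seen.add(f.id)
            if len(f.intensities) != len(self.sample_names):
                raise ValidationError(
                    f"feature {f.id!r}: {len(f.intensities)} intensities for "
                    f"{len(self.sample_names)} samples"
                )
        if dupes:
            raise ValidationError(f"duplicate feature ids: {sorted(set(dupes))}")
        self._index = {f.id: f for f in self.features}

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._index

    def get(self, feature_id: str) -> Feature:
        try:
            return self._index[feature_id]
        except KeyError:
            raise KeyError(f"unknown feature id {feature_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return [f.id for f in self.features]

    def mz_array(self) -> np.ndarray:
        return np.array([f.mz for f in self.features], dtype=float)

    def rt_array(self) -> np.ndarray:
        """Retention times with ``NaN`` where absent."""
        return np.array(
            [np.nan if f.rt is None else f.rt for f in self.features], dtype=float
        )

    def intensity_matrix(self) -> np.ndarray:
        """(n_features, n_samples) matrix; missing values are NaN."""
        if not self.features:
            return np.empty((0, len(self.sample_names)))
        return np.vstack([f.intensities for f in self.features])


@dataclass
class MS2Spectrum:
    """A fragmentation (MS level 2) spectrum from a DDA run.

    ``peaks`` is an (n, 2) array of (fragment m/z, intensity), sorted by
    ascending fragment m/z.  ``precursor_rt`` may be absent for MGF dialects
    that do not record retention times.
    """

    precursor_mz: float
    precursor_rt: Optional[float]
    peaks: np.ndarray
    title: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.precursor_mz) or self.precursor_mz <= 0:
            raise ValidationError(f"precursor m/z must be positive, got {self.precursor_mz}")
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if np.any(peaks[:, 1] < 0):
            raise ValidationError("fragment intensities must be non-negative")
        order = np.argsort(peaks[:, 0], kind="stable")
        self.peaks = peaks[order]


@dataclass
class TargetMetabolite:
    """A metabolite to search for: name, neutral molecular formula, optional rt (s)."""

    name: str
    formula: str
    rt: Optional[float] = None


@dataclass(frozen=True)
class AdductRule:
    """Declarative mass arithmetic for one ESI adduct species.

    The ion m/z for a neutral monoisotopic mass M is

        (multiplicity * M + mass_shift) / |charge|

    ``mass_shift`` already includes charge carriers and electron masses, as
    in common ESI adduct calculators, so no further electron correction is
    applied.
    """

    name: str
    ion_mode: str  # "positive" | "negative"
    multiplicity: int
    charge: int
    mass_shift: float

    def __post_init__(self) -> None:
        if self.ion_mode not in ("positive", "negative"):
            raise ValidationError(f"adduct {self.name!r}: unknown ion_mode {self.ion_mode!r}")
        if self.multiplicity < 1:
            raise ValidationError(f"adduct {self.name!r}: multiplicity must be >= 1")
        if self.charge == 0:
            raise ValidationError(f"adduct {self.name!r}: charge must be nonzero")
        if (self.charge > 0) != (self.ion_mode == "positive"):
            raise ValidationError(
                f"adduct {self.name!r}: charge sign inconsistent with ion_mode"
            )


@dataclass(frozen=True)
class NeutralLossEntry:
    """One neutral moiety whose loss links two co-eluting features."""

    name: str
    mass: float
    formula: Optional[str] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.mass) or self.mass <= 0:
            raise ValidationError(f"neutral loss {self.name!r}: mass must be > 0, got {self.mass}")


@dataclass(frozen=True)
class AnnotationEdge:
    """A typed relation between two features.

    ``relation`` is one of :data:`RELATIONS`; ``detail`` is a free-text
    qualifier (isotope order, adduct species, neutral-loss name, ...).
    ``mz_diff`` is target minus source m/z in Da; ``rt_diff`` likewise in
    seconds when both retention times are known.  ``correlation`` is filled
    in for edges exported from the correlation network.
    """

    source_id: str
    target_id: str
    relation: str
    detail: str = ""
    mz_diff: float = 0.0
    rt_diff: Optional[float] = None
    correlation: Optional[float] = None

    def __post_init__(self) -> None:
        if self.source_id == self.target_id:
            raise ValidationError(f"self-edge on {self.source_id!r}")
        if self.relation not in RELATIONS:
            raise ValidationError(f"unknown relation {self.relation!r}")


def dedupe_edges(edges: Sequence[AnnotationEdge]) -> list[AnnotationEdge]:
    """Drop exact duplicates (same pair, relation and detail), keeping order."""
    seen: set[tuple] = set()
    out: list[AnnotationEdge] = []
    for e in edges:
        key = (e.source_id, e.target_id, e.relation, e.detail)
        if key not in seen:
            seen.add(key)
            out.append(e)
    return out
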