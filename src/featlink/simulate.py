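"""Synthetic-metabolome generator with planted ground truth.

Emulates the structure of a spike-in benchmark: metabolites with known
molecular formulas elute at random retention times and each spawns a family
of redundant MS1 features — the primary ion, sampled adducts/multimers,
13C isotopologue satellites at spacing 1.0034/z, and in-source fragments
obtained by subtracting a bundled neutral-loss mass (so ISF features are
simultaneously annotatable as neutral losses, as real glycoside fragments
are).  A pseudo-DDA MS2 spectrum per fragmenting metabolite carries the ISF
m/z values.

Intensities follow the perturbation model the correlation grouping relies
on: each metabolite draws one log10 abundance shift per condition, and
every feature of that metabolite inherits it, plus a fixed feature offset
and i.i.d. Gaussian replicate noise (log10 scale).  Background features get
independent random profiles.  m/z values carry Gaussian measurement error
and retention times per-feature jitter.  Everything is reproducible from
the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import chem
from .core import AnnotationEdge, Feature, FeatureTable, MS2Spectrum, ValidationError
from .evaluate import BACKGROUND, GroundTruth
from .formats import read_rule_tables

__all__ = ["SimConfig", "SimResult", "simulate_dataset", "write_fixture", "isotope_chain_fixture"]

#: Default per-rule probability that a metabolite shows the adduct species.
DEFAULT_ADDUCT_PROBABILITY = {
    "[M+Na]+": 0.6,
    "[M+K]+": 0.35,
    "[M+NH4]+": 0.35,
    "[2M+H]+": 0.25,
    "[M+H-H2O]+": 0.3,
}


@dataclass
class SimConfig:
    """Conditions of the synthetic spike-in experiment.

    The defaults describe the benchmark scenario the package is tested
    under: 50 metabolites observed across 6 perturbation conditions with 3
    replicates each, 0.05 log10 units of replicate noise, 0.5 mDa m/z
    error, 0.5 s retention-time jitter, and 100 unrelated background
    features.
    """

    n_metabolites: int = 50
    formulas: Optional[Sequence[str]] = None  # sampled CHNO compositions when None
    ion_mode: str = "positive"
    adduct_probability: dict = field(default_factory=lambda: dict(DEFAULT_ADDUCT_PROBABILITY))
    isotope_max_order: int = 2
    isf_mean: float = 1.5  # Poisson mean of in-source fragments per metabolite
    n_conditions: int = 6
    n_replicates: int = 3
    log10_noise_sd: float = 0.05
    condition_effect_sd: float = 0.7  # log10 spread of per-condition abundance shifts
    rt_range: tuple[float, float] = (60.0, 600.0)
    rt_jitter_sd: float = 0.5
    dropout_probability: float = 0.02
    mz_error_sd: float = 0.0005
    background_features: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.n_metabolites < 0 or self.background_features < 0:
            raise ValidationError("feature counts must be non-negative")
        if self.n_conditions * self.n_replicates < 1:
            raise ValidationError("need at least one sample")
        for name, p in [("dropout_probability", self.dropout_probability)] + [
            (k, v) for k, v in self.adduct_probability.items()
        ]:
            if not (0 <= p <= 1):
                raise ValidationError(f"probability {name} out of [0, 1]: {p}")
        for name, sd in [
            ("log10_noise_sd", self.log10_noise_sd),
            ("rt_jitter_sd", self.rt_jitter_sd),
            ("mz_error_sd", self.mz_error_sd),
            ("condition_effect_sd", self.condition_effect_sd),
        ]:
            if sd < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.ion_mode not in ("positive", "negative"):
            raise ValidationError(f"unknown ion mode {self.ion_mode!r}")


@dataclass
class SimResult:
    """Simulated dataset plus its ground truth and planted relation edges."""

    table: FeatureTable
    spectra: list[MS2Spectrum]
    truth: GroundTruth
    planted_edges: list[AnnotationEdge]
    targets: list  # TargetMetabolite per simulated metabolite
    config: SimConfig


def _sample_formula(rng: np.random.Generator) -> str:
    c = int(rng.integers(6, 31))
    h = int(rng.integers(c, 2 * c + 3))
    n = int(rng.integers(0, 4))
    o = int(rng.integers(1, 11))
    parts = [f"C{c}", f"H{h}"]
    if n:
        parts.append(f"N{n}" if n > 1 else "N")
    parts.append(f"O{o}" if o > 1 else "O")
    return "".join(parts)


def simulate_dataset(config: SimConfig = SimConfig()) -> SimResult:
    """Generate one synthetic dataset under ``config``.

    Per metabolite: a retention time and per-condition log10 abundance
    shifts are drawn; the primary ion plus adduct, isotope and ISF
    satellites are emitted with shared perturbation structure; an MS2
    spectrum is produced when the metabolite fragments.  See the module
    docstring for the noise model.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    from .core import TargetMetabolite

    n_samples = config.n_conditions * config.n_replicates
    sample_names = [
        f"cond{c + 1}_rep{r + 1}"
        for c in range(config.n_conditions)
        for r in range(config.n_replicates)
    ]
    cond_of_sample = np.repeat(np.arange(config.n_conditions), config.n_replicates)

    adduct_rules, nl_entries = read_rule_tables()
    rules_by_name = {r.name: r for r in adduct_rules}
    mode_rules = {
        name: rules_by_name[name]
        for name in config.adduct_probability
        if name in rules_by_name and rules_by_name[name].ion_mode == config.ion_mode
    }
    primary_rule = rules_by_name["[M+H]+" if config.ion_mode == "positive" else "[M-H]-"]

    if config.formulas is not None:
        formulas = list(config.formulas)
        if len(formulas) < config.n_metabolites:
            raise ValidationError(
                f"{len(formulas)} formulas for {config.n_metabolites} metabolites"
            )
    else:
        formulas = [_sample_formula(rng) for _ in range(config.n_metabolites)]

    features: list[Feature] = []
    truth: dict[str, str] = {}
    planted: list[AnnotationEdge] = []
    spectra: list[MS2Spectrum] = []
    targets: list[TargetMetabolite] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"F{counter:04d}"

    def profile(base: float, cond_shift: np.ndarray, offset: float) -> np.ndarray:
        log10i = (
            base
            + cond_shift[cond_of_sample]
            + offset
            + rng.normal(0.0, config.log10_noise_sd, n_samples)
        )
        vals = np.power(10.0, log10i)
        drop = rng.random(n_samples) < config.dropout_probability
        vals[drop] = np.nan
        return vals

    def emit(mz_true: float, rt_true: float, base, cond_shift, offset, compound) -> Feature:
        f = Feature(
            id=new_id(),
            mz=mz_true + rng.normal(0.0, config.mz_error_sd),
            rt=max(0.0, rt_true + rng.normal(0.0, config.rt_jitter_sd)),
            intensities=profile(base, cond_shift, offset),
        )
        features.append(f)
        truth[f.id] = compound
        return f

    for mi in range(config.n_metabolites):
        compound = f"M{mi + 1:03d}"
        formula = formulas[mi]
        neutral = chem.formula_mass(formula)
        n_carbons = chem.parse_formula(formula).get("C", 0)
        rt_met = float(rng.uniform(*config.rt_range))
        base = float(rng.normal(6.0, 0.5))
        cond_shift = rng.normal(0.0, config.condition_effect_sd, config.n_conditions)
        targets.append(TargetMetabolite(name=compound, formula=formula, rt=rt_met))

        primary_mz = chem.apply_adduct(neutral, primary_rule)
        fp = emit(primary_mz, rt_met, base, cond_shift, 0.0, compound)

        # isotopologues of the primary ion, crude 13C intensity decay
        iso_ratio = min(0.011 * n_carbons, 0.6)
        for order in range(1, config.isotope_max_order + 1):
            offset = float(np.log10(max(iso_ratio**order, 1e-6)))
            fi = emit(
                primary_mz + order * chem.C13_SPACING, rt_met, base, cond_shift,
                offset, compound,
            )
            planted.append(
                AnnotationEdge(fp.id, fi.id, "isotope", f"[M+{order}]", fi.mz - fp.mz)
            )

        for name, rule in sorted(mode_rules.items()):
            if rng.random() >= config.adduct_probability[name]:
                continue
            amz = chem.apply_adduct(neutral, rule)
            offset = float(rng.normal(-0.7, 0.3))
            fa = emit(amz, rt_met, base, cond_shift, offset, compound)
            planted.append(
                AnnotationEdge(
                    fp.id, fa.id, "adduct_sibling", f"{name} of {compound}", fa.mz - fp.mz
                )
            )

        # in-source fragments: parent minus a neutral-loss mass
        n_isf = int(rng.poisson(config.isf_mean))
        losses = [e for e in nl_entries if primary_mz - e.mass > 60.0]
        frag_peaks: list[tuple[float, float]] = []
        for _ in range(min(n_isf, len(losses))):
            entry = losses[int(rng.integers(len(losses)))]
            fmz = primary_mz - entry.mass
            offset = float(rng.normal(-0.5, 0.3))
            ff = emit(fmz, rt_met, base, cond_shift, offset, compound)
            planted.append(AnnotationEdge(fp.id, ff.id, "isf", f"ISF of {fp.id}", ff.mz - fp.mz))
            planted.append(
                AnnotationEdge(fp.id, ff.id, "neutral_loss", entry.name, ff.mz - fp.mz)
            )
            frag_peaks.append(
                (fmz + rng.normal(0.0, config.mz_error_sd), float(rng.uniform(0.1, 1.0)))
            )
        if frag_peaks:
            # noise fragments that match no MS1 feature
            for _ in range(2):
                frag_peaks.append(
                    (float(rng.uniform(55.0, 70.0)), float(rng.uniform(0.02, 0.08)))
                )
            peaks = np.array(frag_peaks + [(primary_mz, 1.0)])
            spectra.append(
                MS2Spectrum(
                    precursor_mz=primary_mz + rng.normal(0.0, config.mz_error_sd),
                    precursor_rt=rt_met + rng.normal(0.0, config.rt_jitter_sd),
                    peaks=peaks,
                    title=f"pseudoDDA_{compound}",
                )
            )

    for _ in range(config.background_features):
        f = Feature(
            id=new_id(),
            mz=float(rng.uniform(80.0, 900.0)),
            rt=float(rng.uniform(*config.rt_range)),
            intensities=np.power(
                10.0, rng.normal(5.5, 0.8) + rng.normal(0.0, 0.4, n_samples)
            ),
        )
        drop = rng.random(n_samples) < config.dropout_probability
        f.intensities[drop] = np.nan
        features.append(f)
        truth[f.id] = BACKGROUND

    table = FeatureTable(features=features, sample_names=sample_names)
    return SimResult(
        table=table,
        spectra=spectra,
        truth=GroundTruth(compound_of=truth),
        planted_edges=planted,
        targets=targets,
        config=config,
    )


def write_fixture(result: SimResult, out_dir: str | Path) -> None:
    """Write a simulated dataset as the plain-text fixture the readers expect.

    Produces ``feature_table.csv``, ``spectra.mgf``, ``targets.csv``,
    ``truth.csv``, ``planted_edges.csv`` and ``config.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = result.table

    import csv

    with open(out / "feature_table.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["feature", "mz", "rt"] + list(t.sample_names))
        for f in t.features:
            w.writerow(
                [f.id, repr(float(f.mz)), repr(float(f.rt))]
                + ["" if not np.isfinite(v) else repr(float(v)) for v in f.intensities]
            )

    from pyteomics import mgf as _mgf

    entries = []
    for s in result.spectra:
        params = {"title": s.title, "pepmass": s.precursor_mz}
        if s.precursor_rt is not None:
            params["rtinseconds"] = s.precursor_rt
        entries.append(
            {"m/z array": s.peaks[:, 0], "intensity array": s.peaks[:, 1], "params": params}
        )
    _mgf.write(entries, str(out / "spectra.mgf"), file_mode="w")

    with open(out / "targets.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "formula", "rt"])
        for tg in result.targets:
            w.writerow([tg.name, tg.formula, "" if tg.rt is None else repr(float(tg.rt))])

    with open(out / "truth.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["feature", "compound"])
        for f in t.features:
            w.writerow([f.id, result.truth.compound_of[f.id]])

    with open(out / "planted_edges.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target", "relation", "detail", "mz_diff"])
        for e in result.planted_edges:
            w.writerow([e.source_id, e.target_id, e.relation, e.detail, repr(float(e.mz_diff))])

    cfg = asdict(result.config)
    cfg["rt_range"] = list(cfg["rt_range"])
    if cfg["formulas"] is not None:
        cfg["formulas"] = list(cfg["formulas"])
    with open(out / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")


def isotope_chain_fixture(
    seed: int = 0,
    n_chains: int = 60,
    charges: Sequence[int] = (1, 2, 3),
    max_order: int = 4,
    mz_error_sd: float = 0.0003,
) -> tuple[FeatureTable, dict[str, tuple[str, int, int]]]:
    """A table of planted isotopologue chains for charge states 1-3.

    Anchors are spaced >= 8 Da apart so chains cannot interfere; each chain
    carries satellites of order 1..``max_order`` at spacing 1.0034/z with
    small m/z error.  Returns the table and a truth map
    satellite id → (anchor id, order, charge).
    """
    rng = np.random.default_rng(seed)
    features: list[Feature] = []
    truth: dict[str, tuple[str, int, int]] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:04d}"

    for ci in range(n_chains):
        z = charges[ci % len(charges)]
        anchor_mz = 150.0 + 8.0 * ci + float(rng.uniform(0, 2))
        rt = float(rng.uniform(60, 600))
        anchor = Feature(new_id(), anchor_mz, rt, np.array([1e6]))
        features.append(anchor)
        for order in range(1, max_order + 1):
            mz = anchor_mz + order * chem.C13_SPACING / z + rng.normal(0, mz_error_sd)
            sat = Feature(
                new_id(), mz, rt + float(rng.normal(0, 0.2)), np.array([1e6 * 0.2**order])
            )
            features.append(sat)
            truth[sat.id] = (anchor.id, order, z)
    return FeatureTable(features=features, sample_names=["pool"]), truth
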