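"""Seeded synthetic inputs with the statistical structure the analyses assume.

Three generators:

* :func:`simulate_reaction` -- expected species concentrations after a DUB
  acts on a substrate chain with a given per-linkage cleavage fraction
  (edges cut independently; a moiety is released as monoUb exactly when
  all of its edges are cut).
* :func:`simulate_spectrum` -- a reflectron-mode MALDI-TOF trace of the
  released species plus the 15N standard: Gaussian envelopes (FWHM = m/R),
  exponential-decay baseline, additive noise, a constant calibration
  offset, and metastable-ion satellite peaks.
* :func:`simulate_dia_matrix` -- quadruplicate pulldown intensity matrices
  with cluster-structured binding profiles, null (non-differential)
  proteins, intensity-dependent (logistic, left-censored) missingness and
  unique-peptide counts, together with the ground truth.

Every generator is a pure function of its inputs and seed.  Defaults
follow the assay conditions: substrate at 1.2 uM diluted by the stop
solution (10 ul + 2.5 ul) to 0.96 uM final, the 15N standard at 0.8 uM
final, technical duplicates, and a detection window of 7,820-9,200 m/z.
The metastable satellites (one per parent at 0.985 x parent m/z, 5%
relative amplitude) are synthetic placeholders: the real instrument
artifact positions are not specified and the defaults are configurable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chain_model import ChainArchitecture, LinkageEdge, format_architecture, simulate_cleavage
from .mass_engine import MassMode, PROTON, chain_mass, moiety_mz
from .binder_profiling import IntensityMatrix
from .spectral_quant import DEFAULT_WINDOW, Spectrum

__all__ = [
    "SpectrumParams",
    "ReactionSpec",
    "ReactionResult",
    "DIADesign",
    "DEFAULT_METASTABLE",
    "simulate_reaction",
    "simulate_spectrum",
    "simulate_assay_spectrum",
    "simulate_dia_matrix",
    "default_branched_substrate",
]


def default_branched_substrate() -> ChainArchitecture:
    """Default mass-distinguishable branched Ub4: every moiety a distinct variant.

    K48/K63 branch on a K48 trunk; the root is C-terminally truncated
    (1-72), the trunk middle unit is wild type, the K48 arm carries
    K48R+K63R and the K63 arm K48R, so the four released species and the
    15N standard are pairwise separated by >= 28 Da.
    """
    from .chain_model import parse_architecture

    return parse_architecture("(Ub{K48R,K63R})(Ub{K48R})-[48,63]Ub-[48]Ub{1-72}")


# ---------------------------------------------------------------------------
# Reaction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReactionSpec:
    """A DUB reaction on one substrate chain.

    ``cleavage_fractions`` maps each edge to the probability it is cut
    (a scalar applies to all edges).  Concentrations are final, after
    stop-solution dilution: 1.2 uM substrate in 10 ul + 2.5 ul stop with
    4 uM 15N standard gives 0.96 uM substrate and 0.8 uM standard.
    """

    substrate: ChainArchitecture
    cleavage_fractions: Mapping[LinkageEdge, float] | float = 0.0
    substrate_conc: float = 0.96
    standard_conc: float = 0.8
    replicates: int = 2

    def fraction(self, edge: LinkageEdge) -> float:
        f = self.cleavage_fractions
        val = float(f) if isinstance(f, (int, float)) else float(f[edge])
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"cleavage fraction {val} outside [0, 1]")
        return val

    def __post_init__(self):
        if self.substrate_conc <= 0 or self.standard_conc <= 0:
            raise ValueError("concentrations must be positive")


@dataclass(frozen=True)
class ReactionResult:
    """Expected species concentrations (uM) after the reaction."""

    species: tuple[tuple[ChainArchitecture, float], ...]
    released_per_unit: Mapping[str, float]
    undetectable: tuple[str, ...]  # canonical notations outside the m/z window

    def total_ub_units(self) -> float:
        return sum(len(a) * c for a, c in self.species)


def simulate_reaction(
    spec: ReactionSpec,
    seed: int | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
    mode: MassMode = MassMode.AVERAGE,
) -> ReactionResult:
    """Expected product distribution: edges are cut independently.

    Enumerates all cut patterns exactly, so the result is the closed-form
    expectation (``seed`` is accepted for interface symmetry with the other
    generators but the computation is deterministic).  The expected
    released-monoUb concentration of a unit is substrate concentration x
    the product of its incident-edge cleavage fractions; total Ub units
    are conserved across species.
    """
    arch = spec.substrate
    edges = list(arch.edges)
    fr = {e: spec.fraction(e) for e in edges}
    species: dict[str, tuple[ChainArchitecture, float]] = {}
    for pattern in itertools.product([False, True], repeat=len(edges)):
        prob = 1.0
        cut = []
        for e, is_cut in zip(edges, pattern):
            prob *= fr[e] if is_cut else 1.0 - fr[e]
            if is_cut:
                cut.append(e)
        if prob == 0.0:
            continue
        for comp in simulate_cleavage(arch, cut):
            key = format_architecture(comp)
            old = species.get(key)
            species[key] = (comp, (old[1] if old else 0.0) + prob * spec.substrate_conc)
    released = {}
    for u in arch.units:
        incident = [e for e in edges if u.id in (e.distal, e.proximal)]
        released[u.id] = spec.substrate_conc * float(np.prod([fr[e] for e in incident]))
    undetectable = tuple(
        key for key, (comp, _) in sorted(species.items())
        if not window[0] <= chain_mass(comp, mode) + PROTON <= window[1]
    )
    out = tuple(sorted(species.values(), key=lambda sc: format_architecture(sc[0])))
    return ReactionResult(out, released, undetectable)


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumParams:
    """Acquisition model for synthetic reflectron-mode spectra.

    ``resolution`` sets the envelope FWHM (= m/R, ~8.5 Da at 8.5 kDa for
    the default R = 1,000, an unresolved isotope envelope).  The baseline
    is ``offset + amplitude * exp(-(m - window_min)/scale)``; noise is
    additive Gaussian; ``calibration_offset`` shifts every peak (the
    miscalibration the internal standard corrects); each metastable
    artifact is (fractional m/z shift, relative amplitude) applied to
    every parent peak.
    """

    window: tuple[float, float] = DEFAULT_WINDOW
    step: float = 0.2
    resolution: float = 1000.0
    baseline_offset: float = 0.0
    baseline_amplitude: float = 0.0
    baseline_scale: float = 400.0
    noise_sd: float = 0.0
    calibration_offset: float = 0.0
    metastable: tuple[tuple[float, float], ...] = ()
    response_factors: Mapping[str, float] | float = 1.0
    area_per_conc: float = 1000.0  # intensity-units x Da per uM
    seed: int = 0

    def __post_init__(self):
        if self.window[0] >= self.window[1]:
            raise ValueError("window min must be below window max")
        if self.resolution <= 0 or self.step <= 0:
            raise ValueError("resolution and step must be positive")

    def response(self, key: str) -> float:
        rf = self.response_factors
        val = float(rf) if isinstance(rf, (int, float)) else float(rf.get(key, 1.0))
        if val <= 0:
            raise ValueError("response factors must be positive")
        return val


#: Default metastable satellite: one per parent, 1.5% below the parent m/z
#: at 5% relative amplitude (positions on the real instrument are not
#: documented; this is a synthetic stand-in).
DEFAULT_METASTABLE = ((0.985, 0.05),)


def simulate_spectrum(
    species: Sequence[tuple[float, float]] | Mapping[str, tuple[float, float]],
    params: SpectrumParams = SpectrumParams(),
) -> Spectrum:
    """Sum of Gaussian envelopes plus baseline, artifacts and noise.

    ``species`` is a list of ``(mz, concentration)`` pairs or a mapping
    ``name -> (mz, concentration)`` (names select per-species response
    factors).  Peak areas are concentration x response factor x
    ``area_per_conc``; every peak center is shifted by the calibration
    offset.  Reproducible under a fixed seed; an empty species list still
    yields a valid baseline/noise-only trace.
    """
    w0, w1 = params.window
    mz = np.arange(w0, w1 + params.step / 2, params.step)
    y = np.zeros_like(mz)
    if isinstance(species, Mapping):
        items = [(name, m, c) for name, (m, c) in species.items()]
    else:
        items = [(f"s{i + 1}", m, c) for i, (m, c) in enumerate(species)]

    def add_gaussian(center: float, area: float):
        sigma = (center / params.resolution) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        if center + 5 * sigma < w0 or center - 5 * sigma > w1:
            return
        height = area / (sigma * np.sqrt(2.0 * np.pi))
        sel = np.abs(mz - center) <= 6 * sigma
        y[sel] += height * np.exp(-0.5 * ((mz[sel] - center) / sigma) ** 2)

    for name, center, conc in items:
        if conc <= 0:
            continue
        area = conc * params.response(name) * params.area_per_conc
        shifted = center + params.calibration_offset
        add_gaussian(shifted, area)
        for frac, rel in params.metastable:
            add_gaussian(shifted * frac, area * rel)
    y += params.baseline_offset
    if params.baseline_amplitude:
        y += params.baseline_amplitude * np.exp(-(mz - w0) / params.baseline_scale)
    if params.noise_sd:
        rng = np.random.default_rng(params.seed)
        y = y + rng.normal(0.0, params.noise_sd, size=len(mz))
    return Spectrum(mz, y, window=params.window)


def simulate_assay_spectrum(
    spec: ReactionSpec,
    params: SpectrumParams = SpectrumParams(),
    standard_mz: float | None = None,
    mode: MassMode = MassMode.AVERAGE,
) -> tuple[Spectrum, dict[str, float]]:
    """Reaction -> spectrum convenience wrapper.

    Simulates the reaction, places every detectable product species (and
    the 15N standard) in the window, and returns the trace together with
    the ground-truth percent cleaved per moiety
    (100 x released / substrate concentration).
    """
    from .chain_model import UbUnit

    result = simulate_reaction(spec, window=params.window, mode=mode)
    entries: dict[str, tuple[float, float]] = {}
    for arch, conc in result.species:
        mzv = chain_mass(arch, mode) + PROTON
        key = format_architecture(arch)
        if key in entries:
            entries[key] = (mzv, entries[key][1] + conc)
        else:
            entries[key] = (mzv, conc)
    # standard: uniformly 15N-labeled wild-type Ub
    std_mz = standard_mz if standard_mz is not None else moiety_mz(UbUnit("std", isotope="15N"), mode)
    entries["standard"] = (std_mz, spec.standard_conc)
    truth = {uid: 100.0 * conc / spec.substrate_conc for uid, conc in result.released_per_unit.items()}
    return simulate_spectrum(entries, params), truth


# ---------------------------------------------------------------------------
# DIA pulldown matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DIADesign:
    """Design of a synthetic quadruplicate pulldown experiment.

    ``cluster_profiles`` has one row per binding-preference cluster and one
    column per chain-type group, giving the mean log2-intensity shift of a
    differential protein of that cluster in that group.  The default is
    six clusters over four chain types (two K63-preferring, two
    branch-preferring, two K48-preferring patterns) with an effect of
    3 x the between-replicate sd.  Missingness is logistic in the true
    log2 intensity (low-abundance entries are more often missing), which
    is the left-censoring the Gaussian-downshift imputation assumes.
    """

    n_proteins: int = 2000
    groups: tuple[str, ...] = ("48Ub4", "63Ub4", "(Ub)2-[48,63]Ub-[48]Ub", "(Ub)2-[48,63]Ub-[63]Ub")
    replicates: int = 4
    fraction_differential: float = 0.065
    n_clusters: int = 6
    effect_sd_units: float = 6.0
    replicate_sd: float = 0.5
    baseline_mean: float = 26.0
    baseline_sd: float = 1.5
    missing_midpoint: float = 23.0
    missing_scale: float = 0.8
    peptide_lambda: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 2:
            raise ValueError("need at least two replicates per group")
        if not 0.0 <= self.fraction_differential <= 1.0:
            raise ValueError("fraction_differential must be in [0, 1]")

    def profiles(self) -> np.ndarray:
        """Binding-preference patterns (clusters x groups), in sd units."""
        g = len(self.groups)
        base = np.array([
            [0, 1, 0, 1],   # K63 linkages wherever they occur
            [0, 1, 0, 0],   # long unbranched K63 only
            [0, 0, 1, 1],   # branch point specific
            [1, 0, 1, 1],   # K48 plus branched
            [1, 0, 1, 0],   # K48 linkages
            [1, 0, 0, 0],   # long unbranched K48 only
        ], dtype=float)
        if self.n_clusters > len(base) or g != base.shape[1]:
            rng = np.random.default_rng(12345)
            base = rng.integers(0, 2, size=(self.n_clusters, g)).astype(float)
            base[base.sum(axis=1) == 0, 0] = 1.0
        return base[: self.n_clusters] * self.effect_sd_units * self.replicate_sd


def simulate_dia_matrix(design: DIADesign = DIADesign()) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Generate the intensity matrix and its ground truth.

    Returns ``(matrix, truth)``: the matrix holds linear-scale intensities
    with NaN for missing values, unique-peptide counts and group labels;
    ``truth`` has one row per protein with columns ``differential`` (bool)
    and ``cluster`` (1..k, or 0 for null proteins).
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_proteins
    samples = [f"{g}.r{r + 1}" for g in design.groups for r in range(design.replicates)]
    group_of = np.repeat(np.arange(len(design.groups)), design.replicates)
    profiles = design.profiles()

    n_diff = int(round(design.fraction_differential * n))
    clusters = np.zeros(n, dtype=int)
    if n_diff:
        clusters[:n_diff] = 1 + (np.arange(n_diff) % design.n_clusters)
    baseline = rng.normal(design.baseline_mean, design.baseline_sd, size=n)
    true_means = np.tile(baseline[:, None], (1, len(samples)))
    for i in range(n):
        if clusters[i]:
            true_means[i] += profiles[clusters[i] - 1][group_of]
    log2 = true_means + rng.normal(0.0, design.replicate_sd, size=true_means.shape)
    p_missing = 1.0 / (1.0 + np.exp((log2 - design.missing_midpoint) / design.missing_scale))
    missing = rng.random(log2.shape) < p_missing
    linear = np.power(2.0, log2)
    linear[missing] = np.nan
    index = pd.Index([f"P{i + 1:05d}" for i in range(n)], name="protein")
    values = pd.DataFrame(linear, index=index, columns=samples)
    peptides = pd.Series(1 + rng.poisson(design.peptide_lambda, size=n), index=index, name="unique_peptides")
    groups = pd.Series([design.groups[g] for g in group_of], index=pd.Index(samples), name="group")
    truth = pd.DataFrame({"differential": clusters > 0, "cluster": clusters}, index=index)
    matrix = IntensityMatrix(values, peptides, groups, log2_transformed=False)
    return matrix, truth
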