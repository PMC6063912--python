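"""Seeded generators for every input the pipeline consumes.

Each generator returns the data object together with a truth sidecar
(planted effects, ground-truth labels) so downstream stages can be
checked for parameter recovery.  All generators are pure functions of
their arguments and the seed.

Generated conditions mirror a two-arm nutritional-intervention study:
a two-group log-normal expression matrix with disjoint planted up/down
gene sets, term-to-gene collections concentrated on those sets, a
signed directed regulatory network with planted hub regulators whose
targets fall preferentially in the planted DEG sets, and two-class
NMR-like spectra built from Lorentzian multiplets with planted
discriminatory metabolites, per-sample dilution and additive noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .chemometrics import Spectra
from .enrichment import GeneSetCollection
from .network import SIGNS, build_network

__all__ = [
    "ExpressionTruth",
    "Multiplet",
    "SpectraTruth",
    "NetworkTruth",
    "generate_expression",
    "generate_gene_sets",
    "generate_network",
    "generate_spectra",
    "default_spectra_truth",
    "discriminatory_bins",
    "metabolite_bins",
]

#: Log2-intensity range for gene baselines (typical microarray scale).
BASELINE_RANGE = (6.0, 12.0)

#: Fraction of a planted regulator's targets drawn from the planted
#: up/down DEG sets (the rest come from null genes).
TARGET_PURITY = 0.8


@dataclass(frozen=True)
class ExpressionTruth:
    """Planted structure of a synthetic expression matrix."""

    up_genes: frozenset[str]
    down_genes: frozenset[str]
    null_genes: frozenset[str]
    effect_log2: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.up_genes & self.down_genes or self.up_genes & self.null_genes \
                or self.down_genes & self.null_genes:
            raise ValueError("truth gene sets must be pairwise disjoint")

    @property
    def universe(self) -> frozenset[str]:
        return self.up_genes | self.down_genes | self.null_genes


@dataclass(frozen=True)
class Multiplet:
    """One spin-system signal: peak centers (ppm), shared linewidth and
    relative peak heights (e.g. a 1:2:1 triplet)."""

    centers: tuple[float, ...]
    width: float
    heights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.heights):
            raise ValueError("centers and heights must have equal length")
        if self.width <= 0:
            raise ValueError("linewidth must be positive")


@dataclass(frozen=True)
class SpectraTruth:
    """Planted composition of synthetic two-class spectra.

    ``effects`` maps metabolite name -> positive multiplier applied to
    its concentration in class 2; metabolites absent from the map are
    non-discriminatory (multiplier 1).
    """

    metabolites: dict[str, tuple[Multiplet, ...]]
    concentrations: dict[str, float]
    effects: dict[str, float] = field(default_factory=dict)
    conc_log_sd: float = 0.2
    dilution_range: tuple[float, float] = (0.8, 1.2)
    noise_sd: float = 0.05
    baseline: float = 0.3
    lineshape: str = "lorentzian"

    def __post_init__(self) -> None:
        for name, mult in self.effects.items():
            if name not in self.metabolites:
                raise ValueError(f"effect on unknown metabolite {name!r}")
            if mult <= 0:
                raise ValueError("effect multipliers must be positive")
        if self.lineshape not in ("lorentzian", "gaussian"):
            raise ValueError("lineshape must be 'lorentzian' or 'gaussian'")
        if not 0 < self.dilution_range[0] <= self.dilution_range[1]:
            raise ValueError("dilution range must be a positive interval")


@dataclass(frozen=True)
class NetworkTruth:
    """Planted hub structure of a synthetic interaction network."""

    planted_regulators: frozenset[str]
    targets: dict[str, frozenset[str]]
    background_density: float


def generate_expression(
    n_genes: int = 2000,
    n_per_group: int = 8,
    n_up: int = 100,
    n_down: int = 100,
    effect_log2: float = 1.5,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, ExpressionTruth]:
    """Two-group log2 expression with disjoint planted up/down genes.

    Returns ``(matrix, groups, truth)``: a genes x samples DataFrame,
    a sample -> {A, B} Series (A is the reference group) and the truth
    sidecar.  Values are gene baseline (uniform on the microarray-like
    range) plus +/- ``effect_log2`` in group B for planted genes, plus
    Gaussian noise.
    """
    if n_up + n_down > n_genes:
        raise ValueError("n_up + n_down cannot exceed n_genes")
    if n_per_group < 3:
        raise ValueError("need at least 3 samples per group")
    if noise_sd < 0 or effect_log2 < 0:
        raise ValueError("effect_log2 and noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    planted = rng.choice(n_genes, size=n_up + n_down, replace=False)
    up_idx, down_idx = planted[:n_up], planted[n_up:]
    samples = [f"A{i + 1}" for i in range(n_per_group)] + [
        f"B{i + 1}" for i in range(n_per_group)
    ]
    groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=samples)
    baseline = rng.uniform(*BASELINE_RANGE, size=n_genes)
    effect = np.zeros(n_genes)
    effect[up_idx] = effect_log2
    effect[down_idx] = -effect_log2
    values = baseline[:, None] + np.where(
        (groups == "B").to_numpy()[None, :], effect[:, None], 0.0
    )
    values = values + rng.normal(0.0, noise_sd, size=values.shape)
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    truth = ExpressionTruth(
        up_genes=frozenset(genes[i] for i in up_idx),
        down_genes=frozenset(genes[i] for i in down_idx),
        null_genes=frozenset(
            g for i, g in enumerate(genes) if i not in set(planted.tolist())
        ),
        effect_log2=effect_log2,
        noise_sd=noise_sd,
    )
    return matrix, groups, truth


def generate_gene_sets(
    truth: ExpressionTruth,
    n_terms_up: int = 10,
    n_terms_down: int = 10,
    n_terms_null: int = 20,
    term_size: int = 20,
    purity: float = 0.9,
    seed: int = 0,
) -> tuple[GeneSetCollection, dict[str, str]]:
    """Term collection concentrated on the planted up/down gene sets.

    Up-terms draw a fraction ``purity`` of members from the planted up
    genes (the rest from null genes), symmetrically for down-terms;
    null terms sample uniformly from the whole universe.  Returns the
    collection and a term -> {up, down, null} truth label map.
    """
    if not 0.5 < purity <= 1.0:
        raise ValueError("purity must lie in (0.5, 1]")
    if term_size < 5:
        raise ValueError("term_size must be >= 5")
    rng = np.random.default_rng(seed)
    up = sorted(truth.up_genes)
    down = sorted(truth.down_genes)
    nulls = sorted(truth.null_genes)
    universe = sorted(truth.universe)
    n_core = int(round(purity * term_size))
    for pool, need, side in ((up, n_core, "up"), (down, n_core, "down")):
        if need > len(pool):
            raise ValueError(f"term core size {need} exceeds the {side} pool ({len(pool)})")
    if term_size - n_core > len(nulls) or term_size > len(universe):
        raise ValueError("term_size exceeds the available gene pools")
    sets: dict[str, frozenset[str]] = {}
    labels: dict[str, str] = {}

    def draw(pool: list[str], size: int) -> list[str]:
        return [pool[i] for i in rng.choice(len(pool), size=size, replace=False)]

    for kind, n_terms, core_pool in (
        ("up", n_terms_up, up),
        ("down", n_terms_down, down),
        ("null", n_terms_null, None),
    ):
        for j in range(n_terms):
            term = f"{kind}_term_{j:03d}"
            if core_pool is None:
                members = draw(universe, term_size)
            else:
                members = draw(core_pool, n_core) + draw(nulls, term_size - n_core)
            sets[term] = frozenset(members)
            labels[term] = kind
    return GeneSetCollection(sets), labels


def generate_network(
    gene_universe: list[str] | None = None,
    truth: ExpressionTruth | None = None,
    n_regulators: int = 8,
    targets_per_regulator: int = 20,
    background_density: float = 5e-4,
    sign_mix: tuple[float, float, float] = (0.45, 0.45, 0.10),
    seed: int = 0,
) -> tuple[nx.DiGraph, NetworkTruth]:
    """Signed digraph with planted regulator hubs.

    Planted regulators are drawn from the null genes; a fraction
    ``TARGET_PURITY`` of each regulator's targets comes from the planted
    up/down DEG sets, the rest from other genes.  Background edges are
    sampled uniformly at ``background_density`` over all ordered pairs.
    """
    if truth is None:
        raise ValueError("an ExpressionTruth is required to place regulator targets")
    if gene_universe is None:
        gene_universe = sorted(truth.universe)
    if targets_per_regulator < 5:
        raise ValueError("targets_per_regulator must be >= 5")
    if not 0.0 <= background_density <= 0.05:
        raise ValueError("background_density must lie in [0, 0.05]")
    if abs(sum(sign_mix) - 1.0) > 1e-9 or min(sign_mix) < 0:
        raise ValueError("sign_mix must be a probability vector over the 3 signs")
    rng = np.random.default_rng(seed)
    genes = sorted(gene_universe)
    deg_pool = sorted((truth.up_genes | truth.down_genes) & set(genes))
    null_pool = sorted(truth.null_genes & set(genes))
    n_core = int(round(TARGET_PURITY * targets_per_regulator))
    if n_regulators > len(null_pool) or n_core > len(deg_pool):
        raise ValueError("gene universe too small for the requested structure")
    regulators = [null_pool[i] for i in rng.choice(len(null_pool), n_regulators, replace=False)]

    def sign() -> str:
        return SIGNS[rng.choice(3, p=sign_mix)]

    edges: list[tuple[str, str, str]] = []
    targets: dict[str, frozenset[str]] = {}
    for reg in regulators:
        core = [deg_pool[i] for i in rng.choice(len(deg_pool), n_core, replace=False)]
        other_pool = [g for g in genes if g != reg and g not in core]
        rest = [
            other_pool[i]
            for i in rng.choice(len(other_pool), targets_per_regulator - n_core, replace=False)
        ]
        tgts = core + rest
        targets[reg] = frozenset(tgts)
        edges.extend((reg, sign(), t) for t in tgts)
    n_pairs = len(genes) * (len(genes) - 1)
    n_background = rng.binomial(n_pairs, background_density) if background_density else 0
    for _ in range(n_background):
        i, j = rng.choice(len(genes), 2, replace=False)
        edges.append((genes[i], sign(), genes[j]))
    net = build_network(edges)
    return net, NetworkTruth(
        planted_regulators=frozenset(regulators),
        targets=targets,
        background_density=background_density,
    )


def _triplet(c: float, w: float = 0.05, h: float = 1.0) -> Multiplet:
    return Multiplet((c - 0.04, c, c + 0.04), w, (0.5 * h, h, 0.5 * h))


def _doublet(c: float, w: float = 0.05, h: float = 1.0) -> Multiplet:
    return Multiplet((c - 0.02, c + 0.02), w, (h, h))


def _singlet(c: float, w: float = 0.05, h: float = 1.0) -> Multiplet:
    return Multiplet((c,), w, (h,))


def default_spectra_truth(
    effects: dict[str, float] | None = None,
    noise_sd: float = 0.05,
    dilution_range: tuple[float, float] = (0.8, 1.2),
) -> SpectraTruth:
    """A faecal/intestinal-extract-like metabolite panel.

    Peak heights are on a unit scale (max clean peak height ~1 at unit
    concentration), so ``noise_sd = 0.05`` corresponds to noise at 5% of
    a typical peak height.  The default discriminatory species is a
    bile-acid-like metabolite whose signals — steroid methyl singlets
    near 0.7/0.9 ppm, CH/CH2 envelopes between 1.6 and 2.3 ppm and a
    conjugate triplet at 3.08 ppm — are spread across the spectrum, as
    bile-acid signals are in real extracts; its concentration doubles in
    class 2.
    """
    panel: dict[str, tuple[Multiplet, ...]] = {
        "bile_acid": (
            _singlet(0.72, h=0.8),
            _singlet(0.92, h=0.9),
            Multiplet((1.66, 1.76), 0.07, (0.7, 0.7)),
            Multiplet((2.22, 2.30), 0.07, (0.6, 0.6)),
            _triplet(3.08, h=0.8),
        ),
        "lactate": (
            _doublet(1.33, h=1.0),
            Multiplet((4.05, 4.09, 4.13, 4.17), 0.05, (0.25, 0.75, 0.75, 0.25)),
        ),
        "alanine": (_doublet(1.48, h=0.9),),
        "acetate": (_singlet(1.92, h=1.2),),
        "succinate": (_singlet(2.41, h=1.0),),
        "taurine": (_triplet(3.26, h=0.8), _triplet(3.43, h=0.8)),
        "glycine": (_singlet(3.56, h=1.0),),
        "glucose": (
            Multiplet((3.72, 3.78, 3.84, 3.90), 0.06, (0.6, 0.8, 0.8, 0.6)),
            _doublet(5.23, h=0.5),
        ),
        "formate": (_singlet(8.46, h=0.8),),
    }
    concentrations = {name: 1.0 for name in panel}
    if effects is None:
        effects = {"bile_acid": 2.0}
    return SpectraTruth(
        metabolites=panel,
        concentrations=concentrations,
        effects=effects,
        noise_sd=noise_sd,
        dilution_range=dilution_range,
    )


def _lineshape(ppm: np.ndarray, mult: Multiplet, kind: str) -> np.ndarray:
    signal = np.zeros_like(ppm)
    half = mult.width / 2.0
    for center, height in zip(mult.centers, mult.heights):
        if kind == "lorentzian":
            signal += height * half**2 / ((ppm - center) ** 2 + half**2)
        else:
            signal += height * np.exp(-((ppm - center) ** 2) / (2.0 * half**2))
    return signal


def metabolite_bins(
    truth: SpectraTruth, ppm: np.ndarray, name: str, rel_height: float = 0.25
) -> np.ndarray:
    """Boolean mask of bins where ``name``'s clean signal exceeds
    ``rel_height`` of its own maximum.

    The default 0.25 marks the metabolite's core multiplet bins: at the
    default unit peak scale a doubling of concentration shifts such a
    bin by at least 5x the default noise sd, so the mask contains only
    bins where a planted effect is detectable in principle.  Pass a
    smaller ``rel_height`` (e.g. 0.05) to include line tails.
    """
    clean = np.zeros_like(ppm, dtype=float)
    for mult in truth.metabolites[name]:
        clean += _lineshape(ppm, mult, truth.lineshape)
    return clean >= rel_height * clean.max()


def discriminatory_bins(
    truth: SpectraTruth, ppm: np.ndarray, rel_height: float = 0.25
) -> np.ndarray:
    """Union of the discriminatory metabolites' bin masks."""
    mask = np.zeros_like(ppm, dtype=bool)
    for name, mult in truth.effects.items():
        if mult != 1.0:
            mask |= metabolite_bins(truth, ppm, name, rel_height)
    return mask


def generate_spectra(
    n_per_class: int = 10,
    ppm_range: tuple[float, float] = (9.0, 0.5),
    n_bins: int = 400,
    truth: SpectraTruth | None = None,
    seed: int = 0,
) -> tuple[Spectra, SpectraTruth]:
    """Two-class synthetic spectra with planted discriminatory metabolites.

    Each sample is ``dilution x (baseline + sum_m conc_m(sample) x
    lineshape_m)`` plus Gaussian noise; concentrations are log-normal
    across samples and the class-2 concentrations of discriminatory
    metabolites are multiplied by their effect.  The flat positive
    baseline keeps off-peak bins non-negative at the documented noise
    levels.  Class labels are ``class1``/``class2``.
    """
    if n_per_class < 5:
        raise ValueError("need at least 5 samples per class")
    if n_bins < 200:
        raise ValueError("n_bins must be >= 200")
    hi, lo = ppm_range
    if hi <= lo:
        raise ValueError("ppm_range must be (high, low), descending")
    if truth is None:
        truth = default_spectra_truth()
    ppm = np.linspace(hi, lo, n_bins)
    for name, mults in truth.metabolites.items():
        for mult in mults:
            if min(mult.centers) < lo or max(mult.centers) > hi:
                raise ValueError(f"metabolite {name!r} has peaks outside the ppm range")
    rng = np.random.default_rng(seed)
    shapes = {
        name: np.sum(
            [_lineshape(ppm, m, truth.lineshape) for m in mults], axis=0
        )
        for name, mults in truth.metabolites.items()
    }
    n_total = 2 * n_per_class
    samples = [f"c1_s{i + 1}" for i in range(n_per_class)] + [
        f"c2_s{i + 1}" for i in range(n_per_class)
    ]
    labels = pd.Series(
        ["class1"] * n_per_class + ["class2"] * n_per_class, index=samples
    )
    X = np.full((n_total, n_bins), truth.baseline)
    lo_d, hi_d = truth.dilution_range
    dilution = (
        rng.uniform(lo_d, hi_d, size=n_total) if hi_d > lo_d else np.full(n_total, lo_d)
    )
    for name, shape in shapes.items():
        base = truth.concentrations[name]
        conc = base * (
            np.exp(rng.normal(0.0, truth.conc_log_sd, size=n_total))
            if truth.conc_log_sd > 0
            else np.ones(n_total)
        )
        mult = truth.effects.get(name, 1.0)
        conc[n_per_class:] *= mult
        X += conc[:, None] * shape[None, :]
    X *= dilution[:, None]
    if truth.noise_sd > 0:
        X += rng.normal(0.0, truth.noise_sd, size=X.shape)
    intensities = pd.DataFrame(X, index=samples, columns=np.arange(n_bins))
    return Spectra(ppm, intensities, labels), truth
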