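"""Synthetic meta-analysis generator.

One "replicate" is a meta-analysis of k independent primary studies. Each
study draws n i.i.d. mean-zero multivariate-normal vectors on the four
model variables from one of two fixed population correlation matrices
(a fixed-effects heterogeneity mixture) and reports its Pearson sample
correlation matrix.

Study sizes follow one of three allocation designs that hold the total
sample size k*nbar fixed:

    E (equal):             every study has nbar subjects.
    M (moderately unequal): 60% of studies get 0.6*nbar, 40% get 1.6*nbar
                            (large studies ~2.7x the small ones).
    H (highly unequal):     40% get 0.4*nbar, 20% get nbar, 40% get 1.6*nbar
                            (large studies 1.6x medium and 4x small).

Heterogeneous replicates draw a fraction of the studies from the second
population matrix; those studies are the smallest ones (ties broken by
position), reflecting the tendency of small studies to be the deviant ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .model import SIGMA, SIGMA_PRIME

__all__ = [
    "DESIGNS",
    "SampleSizeDesign",
    "SimCellConfig",
    "StudySet",
    "allocate_sizes",
    "assign_populations",
    "simulate_study",
    "simulate_meta",
]


@dataclass(frozen=True)
class SampleSizeDesign:
    """A sample-size allocation: (fraction of studies, size multiplier) tiers."""

    label: str
    tiers: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        fracs = sum(f for f, _ in self.tiers)
        mass = sum(f * m for f, m in self.tiers)
        if not (np.isclose(fracs, 1.0) and np.isclose(mass, 1.0)):
            raise ValueError(
                "design tiers must have fractions summing to 1 and preserve total size"
            )


DESIGNS: dict[str, SampleSizeDesign] = {
    "E": SampleSizeDesign("E", ((1.0, 1.0),)),
    "M": SampleSizeDesign("M", ((0.6, 0.6), (0.4, 1.6))),
    "H": SampleSizeDesign("H", ((0.4, 0.4), (0.2, 1.0), (0.4, 1.6))),
}


def _as_design(design: "SampleSizeDesign | str") -> SampleSizeDesign:
    if isinstance(design, str):
        try:
            return DESIGNS[design.upper()]
        except KeyError:
            raise ValueError(f"unknown design label {design!r}; expected one of E, M, H")
    return design


def allocate_sizes(k: int, nbar: float, design: "SampleSizeDesign | str") -> list[int]:
    """Per-study sample sizes (ascending) for k studies averaging nbar each.

    Every tier's study count k*fraction and size nbar*multiplier must be
    integral; sizes sum to exactly k*nbar.
    """
    design = _as_design(design)
    sizes: list[int] = []
    for frac, mult in design.tiers:
        count = frac * k
        size = mult * nbar
        if not np.isclose(count, round(count)):
            raise ValueError(
                f"design {design.label}: tier (fraction={frac}) gives non-integral "
                f"study count {count} for k={k}"
            )
        if not np.isclose(size, round(size)):
            raise ValueError(
                f"design {design.label}: tier (multiplier={mult}) gives non-integral "
                f"sample size {size} for nbar={nbar}"
            )
        sizes.extend([int(round(size))] * int(round(count)))
    return sorted(sizes)


def assign_populations(sizes: list[int], het_fraction: float, *, round_up: bool = True) -> list[str]:
    """Label each study "sigma" or "sigma_prime"; sizes must be ascending.

    round(het_fraction * k) studies come from the second population, chosen
    as the smallest studies (ties broken by list position). ``round_up``
    selects round-half-up (default) vs round-half-down for odd products
    such as k=5 at 50%.
    """
    k = len(sizes)
    if any(sizes[i] > sizes[i + 1] for i in range(k - 1)):
        raise ValueError("sizes must be sorted ascending")
    x = het_fraction * k
    m = int(np.floor(x + 0.5)) if round_up else int(np.ceil(x - 0.5))
    return ["sigma_prime"] * m + ["sigma"] * (k - m)


def simulate_study(n: int, pop: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Pearson correlation matrix of n draws from N(0, pop)."""
    pop = np.asarray(pop, dtype=float)
    if n < 5:
        raise ValueError("need n >= 5 observations per study")
    try:
        L = np.linalg.cholesky(pop)
    except np.linalg.LinAlgError:
        raise ValueError("population matrix must be positive definite") from None
    X = rng.standard_normal((n, pop.shape[0])) @ L.T
    return np.corrcoef(X, rowvar=False)


@dataclass(frozen=True)
class SimCellConfig:
    """One cell of the simulation grid.

    k            : number of primary studies in the meta-analysis.
    nbar         : average sample size per study.
    design       : allocation design label or object (E / M / H).
    het_fraction : proportion of studies drawn from the second population.
    alpha        : homogeneity-test level.
    replications : Monte Carlo replicate count.
    seed         : base seed; every (cell, replicate) gets its own substream.
    het_round_up : round-half-up for the heterogeneous-study count.
    """

    k: int
    nbar: float
    design: str = "E"
    het_fraction: float = 0.0
    alpha: float = 0.05
    replications: int = 1000
    seed: int = 0
    het_round_up: bool = True

    def __post_init__(self) -> None:
        if self.nbar < 10:
            raise ValueError("nbar must be at least 10")
        if not 0.0 <= self.het_fraction < 1.0:
            raise ValueError("het_fraction must lie in [0, 1)")

    @property
    def cell_id(self) -> str:
        return f"k{self.k}_n{self.nbar:g}_{self.design}_het{self.het_fraction:g}"


@dataclass
class StudySet:
    """k (sample size, sample correlation matrix) pairs forming one meta-analysis."""

    sizes: list[int]
    matrices: list[np.ndarray]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = ["sigma"] * len(self.sizes)
        if not (len(self.sizes) == len(self.matrices) == len(self.labels)):
            raise ValueError("sizes, matrices and labels must have equal length")

    @property
    def k(self) -> int:
        return len(self.sizes)

    @property
    def total_n(self) -> int:
        return int(sum(self.sizes))


def _cell_stream(cfg: SimCellConfig, replicate_index: int) -> np.random.Generator:
    """Independent, reproducible substream for one (cell, replicate)."""
    cell_code = zlib.crc32(
        f"{cfg.k}|{cfg.nbar:g}|{str(cfg.design).upper()}|{cfg.het_fraction:g}".encode()
    )
    ss = np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, cell_code, replicate_index])
    return np.random.default_rng(ss)


def simulate_meta(cfg: SimCellConfig, replicate_index: int = 0) -> StudySet:
    """One replicate: k simulated study correlation matrices with their sizes."""
    sizes = allocate_sizes(cfg.k, cfg.nbar, cfg.design)
    labels = assign_populations(sizes, cfg.het_fraction, round_up=cfg.het_round_up)
    rng = _cell_stream(cfg, replicate_index)
    pops = {"sigma": SIGMA, "sigma_prime": SIGMA_PRIME}
    matrices = [simulate_study(n, pops[lab], rng) for n, lab in zip(sizes, labels)]
    return StudySet(sizes=sizes, matrices=matrices, labels=labels)
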