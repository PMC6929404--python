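"""Synthetic case-control study generators with known truth.

Emulates the data-generating process the random-effects model assumes: each
study i has a true log odds ratio theta_i ~ Normal(ln OR_true, tau^2), a
control-arm C-allele frequency drawn uniformly from a plausible range, and
a case-arm frequency implied by theta_i through the odds transform at the
allele level.  Genotypes are then sampled multinomially under
Hardy-Weinberg equilibrium within each arm at that arm's allele frequency,
so dominant and recessive truths are emergent rather than separately
parameterised.

The roster each study writes (N, combined MAF, empirical OR) is exactly
self-consistent with its genotype counts, closing the loop with the
summary-level reconstruction in ``effect_models``.

Defaults mirror the bundled 37-study roster: k = 37, OR_true = 1.12,
tau^2 = 0.02, 300-3,000 persons per arm, control MAF in 0.2-0.4, and an
11:26 East Asian : Caucasian composition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .study_io import StudyRecord, StudyTable


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth for one simulated study set."""

    true_or: float = 1.12
    tau2: float = 0.02
    k: int = 37
    n_range: tuple[int, int] = (300, 3000)
    p0_range: tuple[float, float] = (0.2, 0.4)
    seed: int = 0
    hwe_disequilibrium: float = 0.0  # within-arm HWE departure coefficient; 0 = HWE

    def __post_init__(self):
        if self.k < 2:
            raise ValidationError("need at least 2 studies")
        if self.true_or <= 0 or self.tau2 < 0:
            raise ValidationError("true_or must be positive and tau2 non-negative")
        lo, hi = self.p0_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError("p0_range must lie within (0,1)")
        if not (0 < self.n_range[0] <= self.n_range[1]):
            raise ValidationError("n_range must be positive and ordered")


def _genotype_probs(p: float, d: float) -> np.ndarray:
    """HWE genotype probabilities at allele frequency p, with optional disequilibrium d."""
    probs = np.array([p * p + d, 2.0 * (p * (1.0 - p) - d), (1.0 - p) ** 2 + d])
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
        raise ValidationError(f"invalid genotype probabilities at p={p}, d={d}")
    return probs


def _odds_transform(p0: float, ln_or: float) -> float:
    odds = p0 / (1.0 - p0) * np.exp(ln_or)
    return float(odds / (1.0 + odds))


def _summarise_counts(gcase, gcontrol) -> tuple[float, float]:
    """Combined C-allele frequency and empirical allelic OR from genotype counts.

    A zero allele cell gets the Haldane-Anscombe 0.5 correction for the OR;
    the MAF is always the raw combined frequency.
    """
    cc1, ct1, tt1 = gcase
    cc0, ct0, tt0 = gcontrol
    a, b = 2 * cc1 + ct1, 2 * tt1 + ct1
    c, d = 2 * cc0 + ct0, 2 * tt0 + ct0
    maf = (a + c) / (a + b + c + d)
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return float(maf), float((a * d) / (b * c))


def simulate_studies(truth: SimulationTruth, rng: np.random.Generator | None = None) -> tuple[StudyTable, list[float]]:
    """Draw one study set; returns (roster with genotype counts, true per-study ln ORs).

    Reproducible: a fresh generator seeded from ``truth.seed`` is used when
    ``rng`` is not supplied.
    """
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    n_east = round(truth.k * 11 / 37)
    records: list[StudyRecord] = []
    true_ln_ors: list[float] = []
    for i in range(truth.k):
        theta = rng.normal(np.log(truth.true_or), np.sqrt(truth.tau2))
        p0 = rng.uniform(*truth.p0_range)
        p1 = _odds_transform(p0, theta)
        n1, n0 = rng.integers(truth.n_range[0], truth.n_range[1] + 1, size=2)
        for _ in range(100):
            gcase = tuple(int(x) for x in rng.multinomial(n1, _genotype_probs(p1, truth.hwe_disequilibrium)))
            gcontrol = tuple(int(x) for x in rng.multinomial(n0, _genotype_probs(p0, truth.hwe_disequilibrium)))
            maf, or_emp = _summarise_counts(gcase, gcontrol)
            if 0.0 < maf < 1.0:
                break
        else:  # pragma: no cover - unreachable at realistic n and MAF
            raise ValidationError("could not draw a polymorphic study")
        records.append(
            StudyRecord(
                label=f"sim {i + 1:02d}",
                group="east_asian" if i < n_east else "caucasian",
                n_case=int(n1),
                n_control=int(n0),
                maf=maf,
                or_reported=or_emp,
                or_allele="C",
                genotype_case=gcase,
                genotype_control=gcontrol,
            )
        )
        true_ln_ors.append(float(theta))
    return StudyTable(records, source=f"simulated(seed={truth.seed})"), true_ln_ors


def simulate_null_funnel(truth: SimulationTruth, rng: np.random.Generator | None = None) -> StudyTable:
    """A homogeneous, unbiased study set (true OR = 1, tau^2 = 0).

    Used for type-I-error checks of the Q test and the funnel-asymmetry
    tests: under this null there is no heterogeneity and no small-study
    effect by construction.
    """
    null_truth = replace(truth, true_or=1.0, tau2=0.0)
    table, _ = simulate_studies(null_truth, rng=rng)
    return table
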