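"""Per-study effect sizes: 2x2 contrasts and log odds ratios.

Every study enters the meta-analysis as a log odds ratio with a standard
error.  Three genetic contrasts are supported for a biallelic SNP with
risk allele C and reference allele T:

* additive  — C allele vs T allele (allele-level 2x2, totals 2N per arm)
* dominant  — CC+CT carriers vs TT (person-level)
* recessive — CC vs CT+TT (person-level)

When a study provides only summary data (N, MAF, OR) the allele table is
*reconstructed*: the pair of case/control C-allele frequencies consistent
with the combined MAF and the reported OR is unique and is found by
root-bracketing on the control frequency.  Reconstructed cells are kept
fractional; rounding would inject avoidable error relative to the reported
OR.  The Woolf estimator gives ln(OR) and its standard error, with the
Haldane-Anscombe 0.5 correction applied to all four cells only when a zero
cell occurs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import DegenerateTableError, PipelineError, ValidationError
from .study_io import StudyRecord, StudyTable

log = logging.getLogger(__name__)

GENETIC_MODELS = ("additive", "dominant", "recessive")

#: Normal 97.5% quantile used for every 95% interval in the package.
Z95 = 1.959964


@dataclass(frozen=True)
class TwoByTwoTable:
    """Exposed/unexposed x case/control counts for one contrast.

    Layout::

                 exposed   unexposed
        case        a          b
        control     c          d

    Cells may be fractional when reconstructed from summary data.
    """

    a: float
    b: float
    c: float
    d: float
    correction_applied: bool = False

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("2x2 cells must be non-negative")
        if (self.a + self.b) == 0 or (self.c + self.d) == 0:
            raise DegenerateTableError("empty case or control arm")

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d

    def corrected(self, correction: float = 0.5) -> "TwoByTwoTable":
        """Return self, or a copy with `correction` added to all cells if any is zero."""
        if min(self.a, self.b, self.c, self.d) > 0:
            return self
        if correction <= 0:
            raise DegenerateTableError("zero cell and continuity correction disabled")
        return TwoByTwoTable(
            self.a + correction, self.b + correction, self.c + correction, self.d + correction,
            correction_applied=True,
        )

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            raise DegenerateTableError("odds ratio undefined (zero in b*c)")
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class EffectEstimate:
    """A study's log odds ratio, its standard error, and how it was obtained."""

    label: str
    group: str
    ln_or: float
    se: float
    source: str  # genotype_counts | reconstructed | summary_ci

    def __post_init__(self):
        if not self.se > 0:
            raise ValidationError(f"standard error must be positive, got {self.se}", label=self.label)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.ln_or))


def contrast_table(
    genotype_case: tuple[int, int, int],
    genotype_control: tuple[int, int, int],
    model: str = "additive",
) -> TwoByTwoTable:
    """Build the 2x2 table for a genetic contrast from (CC, CT, TT) counts."""
    if model not in GENETIC_MODELS:
        raise ValueError(f"unknown genetic model {model!r}")
    if min(*genotype_case, *genotype_control) < 0:
        raise ValidationError("genotype counts must be non-negative")
    cc1, ct1, tt1 = genotype_case
    cc0, ct0, tt0 = genotype_control
    if model == "additive":
        cells = (2 * cc1 + ct1, 2 * tt1 + ct1, 2 * cc0 + ct0, 2 * tt0 + ct0)
    elif model == "dominant":
        cells = (cc1 + ct1, tt1, cc0 + ct0, tt0)
    else:  # recessive
        cells = (cc1, ct1 + tt1, cc0, ct0 + tt0)
    return TwoByTwoTable(*map(float, cells))


def reconstruct_frequencies(
    n_case: int,
    n_control: int,
    maf: float,
    odds_ratio: float,
    maf_scope: str = "combined",
) -> tuple[float, float]:
    """Solve for (p_case, p_control) allele frequencies from summary data.

    Given the C-allele frequency ``maf`` and the allelic ``odds_ratio``
    (C vs T), returns the unique frequency pair with

        p_case = OR * p_control / (1 - p_control + OR * p_control)

    and, for ``maf_scope="combined"``, the sample-size-weighted combined
    frequency equal to ``maf``.  The combined frequency is strictly
    increasing in p_control, so the root is bracketed and found to
    absolute tolerance 1e-12.  With ``maf_scope="control"`` the MAF is
    taken as the control-arm frequency directly.
    """
    if not 0.0 < maf < 1.0:
        raise ValidationError(f"maf must lie in (0,1), got {maf}")
    if odds_ratio <= 0:
        raise ValidationError(f"odds ratio must be positive, got {odds_ratio}")
    if maf_scope not in ("combined", "control"):
        raise ValueError(f"maf_scope must be 'combined' or 'control', got {maf_scope!r}")

    def p_case_of(p0: float) -> float:
        return odds_ratio * p0 / (1.0 - p0 + odds_ratio * p0)

    if maf_scope == "control":
        return p_case_of(maf), maf

    n1, n0 = float(n_case), float(n_control)

    def combined_minus_maf(p0: float) -> float:
        return (n1 * p_case_of(p0) + n0 * p0) / (n1 + n0) - maf

    eps = 1e-15
    p0 = brentq(combined_minus_maf, eps, 1.0 - eps, xtol=1e-12)
    return p_case_of(p0), float(p0)


def allele_table_from_frequencies(
    n_case: int, n_control: int, p_case: float, p_control: float
) -> TwoByTwoTable:
    """Fractional allele-level 2x2 table implied by per-arm frequencies (2N alleles per arm)."""
    return TwoByTwoTable(
        2.0 * n_case * p_case,
        2.0 * n_case * (1.0 - p_case),
        2.0 * n_control * p_control,
        2.0 * n_control * (1.0 - p_control),
    )


def effect_from_table(
    table: TwoByTwoTable,
    correction: float = 0.5,
    label: str = "",
    group: str = "",
    source: str = "genotype_counts",
) -> EffectEstimate:
    """Woolf log odds ratio and SE: ln(ad/bc), sqrt(1/a + 1/b + 1/c + 1/d)."""
    t = table.corrected(correction) if min(table.a, table.b, table.c, table.d) == 0 else table
    if min(t.a, t.b, t.c, t.d) == 0:
        raise DegenerateTableError("zero cell persists; cannot form log odds ratio")
    ln_or = float(np.log((t.a * t.d) / (t.b * t.c)))
    se = float(np.sqrt(1.0 / t.a + 1.0 / t.b + 1.0 / t.c + 1.0 / t.d))
    return EffectEstimate(label=label, group=group, ln_or=ln_or, se=se, source=source)


def effect_from_summary(
    odds_ratio: float, ci_low: float, ci_high: float, label: str = "", group: str = ""
) -> EffectEstimate:
    """Effect from a reported OR with 95% CI: se = (ln hi - ln lo) / (2 * 1.959964)."""
    if not 0 < ci_low < odds_ratio < ci_high:
        raise ValidationError(
            f"need 0 < ci_low < or < ci_high, got ({ci_low}, {odds_ratio}, {ci_high})", label=label
        )
    ln_or = float(np.log(odds_ratio))
    se = float((np.log(ci_high) - np.log(ci_low)) / (2.0 * Z95))
    return EffectEstimate(label=label, group=group, ln_or=ln_or, se=se, source="summary_ci")


def effect_for_study(
    record: StudyRecord,
    model: str = "additive",
    policy: str = "genotype_first",
    maf_scope: str = "combined",
    correction: float = 0.5,
    harmonize: bool = True,
) -> EffectEstimate | None:
    """One study's effect under a genetic model, or None if it cannot contribute.

    ``policy`` decides the source: ``genotype_first`` uses counts when
    available and falls back to reconstruction; ``genotype_only`` and
    ``summary_only`` restrict to one path.  Dominant/recessive contrasts
    require genotype counts regardless.  ``harmonize=True`` aligns every
    effect to the C-vs-T direction using the record's ``or_allele``.
    """
    if policy not in ("genotype_first", "genotype_only", "summary_only"):
        raise ValueError(f"unknown policy {policy!r}")
    use_genotypes = record.has_genotypes and policy != "summary_only"
    if model in ("dominant", "recessive") and not record.has_genotypes:
        return None
    if use_genotypes:
        table = contrast_table(record.genotype_case, record.genotype_control, model)
        return effect_from_table(
            table, correction, label=record.label, group=record.group, source="genotype_counts"
        )
    if policy == "genotype_only":
        return None
    or_ = record.or_c_vs_t if harmonize else record.or_reported
    p_case, p_control = reconstruct_frequencies(
        record.n_case, record.n_control, record.maf, or_, maf_scope=maf_scope
    )
    table = allele_table_from_frequencies(record.n_case, record.n_control, p_case, p_control)
    return effect_from_table(
        table, correction, label=record.label, group=record.group, source="reconstructed"
    )


def build_effects(
    table: StudyTable,
    model: str = "additive",
    policy: str = "genotype_first",
    maf_scope: str = "combined",
    correction: float = 0.5,
    harmonize: bool = True,
) -> list[EffectEstimate]:
    """One :class:`EffectEstimate` per usable study, in roster order.

    Studies that cannot contribute under the requested model/policy are
    dropped with a log message; an empty usable set is a pipeline error.
    """
    if model not in GENETIC_MODELS:
        raise ValueError(f"unknown genetic model {model!r}")
    effects: list[EffectEstimate] = []
    for record in table:
        est = effect_for_study(
            record, model=model, policy=policy, maf_scope=maf_scope,
            correction=correction, harmonize=harmonize,
        )
        if est is None:
            log.info("dropping %r: no usable data for model=%s policy=%s", record.label, model, policy)
            continue
        effects.append(est)
    if not effects:
        raise PipelineError(f"no study usable under model={model!r}, policy={policy!r}")
    return effects
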