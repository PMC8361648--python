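"""Mendelian segregation statistics and genotype–phenotype co-segregation.

A monogenic fully penetrant recessive trait segregates 3:1 (wild type :
mutant) in the F2, 1:1 in a backcross to the mutant, and produces no
mutants in a backcross to the wild type.  Two-class chi-square tests use
the Yates continuity correction by default — the convention under which
counts of 1225:401 against 3:1 give a statistic of 0.08 and 264:272
against 1:1 give 0.09 (plain Pearson gives 0.10 and 0.12).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: conventional 5% critical value for df=1, quoted alongside the verdict
CHI2_CRIT_1DF = 3.84


@dataclass(frozen=True)
class SegregationCount:
    """Observed class counts with the expected segregation ratio."""

    labels: tuple[str, ...]
    observed: tuple[int, ...]
    ratio: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.observed) == len(self.ratio)):
            raise ValueError("labels, observed and ratio must be the same length")
        if len(self.labels) < 2:
            raise ValueError("need at least two classes")
        if any(o < 0 for o in self.observed):
            raise ValueError("observed counts must be non-negative")
        if any(r <= 0 for r in self.ratio):
            raise ValueError("ratio terms must be strictly positive")

    @property
    def total(self) -> int:
        return sum(self.observed)

    @property
    def expected(self) -> tuple[float, ...]:
        rsum = sum(self.ratio)
        return tuple(self.total * r / rsum for r in self.ratio)


@dataclass(frozen=True)
class SegregationTestResult:
    statistic: float
    df: int
    critical_value: float
    p_value: float
    consistent: bool  # statistic below the 5% critical value
    yates: bool


def chi_square_segregation(
    counts: SegregationCount, yates: bool = True
) -> SegregationTestResult:
    """Goodness-of-fit chi-square against the expected ratio.

    With two classes and ``yates`` (the default), the statistic is
    Σ (max(|O−E|−0.5, 0))² / E; the |O−E|−0.5 term is clamped at zero so a
    perfect fit yields 0.  With more classes, or ``yates=False``, the plain
    Pearson Σ (O−E)²/E is used.
    """
    if counts.total == 0:
        raise ValueError("total observed count must be > 0")
    expected = counts.expected
    if any(e == 0 for e in expected):
        raise ValueError("zero expected count")
    obs = np.asarray(counts.observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    use_yates = yates and len(counts.observed) == 2
    if use_yates:
        dev = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
    else:
        dev = np.abs(obs - exp)
    stat = float(np.sum(dev**2 / exp))
    df = len(counts.observed) - 1
    crit = float(stats.chi2.ppf(0.95, df))
    p = float(stats.chi2.sf(stat, df))
    return SegregationTestResult(
        statistic=stat,
        df=df,
        critical_value=crit,
        p_value=p,
        consistent=stat < crit,
        yates=use_yates,
    )


def segregation_ratio(counts: SegregationCount) -> tuple[float, str]:
    """Observed ratio normalized to the second class, e.g. 3.05 → \"3.05: 1\"."""
    if counts.observed[1] == 0:
        raise ZeroDivisionError("second class count is zero")
    r = round(counts.observed[0] / counts.observed[1], 2)
    return r, f"{r:.2f}: 1"


def cosegregation_check(
    table: pd.DataFrame,
    locus: str,
    mutant_allele: str,
    *,
    phenotype_column: str = "phenotype",
    mutant_phenotype: str = "mutant",
) -> tuple[int, bool]:
    """Count recombinants between a marker and the mutant phenotype.

    ``table`` holds one row per individual with a phenotype column and one
    column per locus carrying genotype calls like ``\"T:T\"``.  A
    recombinant is a mutant-phenotype individual that is not homozygous for
    the mutant-associated allele; the marker co-segregates iff there are
    none (for a recessive trait every mutant plant must be homozygous at
    the causal site).
    """
    if locus not in table.columns:
        raise KeyError(f"locus column {locus!r} missing")
    if table[phenotype_column].isna().any():
        raise ValueError("missing phenotype values")
    alleles = set()
    for call in table[locus]:
        alleles.update(str(call).split(":"))
    if mutant_allele not in alleles:
        raise ValueError(
            f"allele {mutant_allele!r} never observed at {locus} (alphabet {sorted(alleles)})"
        )
    hom = f"{mutant_allele}:{mutant_allele}"
    mutants = table[table[phenotype_column] == mutant_phenotype]
    recombinants = int((mutants[locus] != hom).sum())
    return recombinants, recombinants == 0


def phenotype_ratio_simulation(
    n_offspring: int,
    generation: str = "F2",
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> SegregationCount:
    """Simulate phenotype counts for a monogenic fully penetrant recessive.

    The causal genotype is transmitted one gamete per parent: F2 (F1
    selfed) mutants are aa with probability 1/4; a backcross to the mutant
    (``\"BC1_mut\"``) gives 1/2; a backcross to the wild type
    (``\"BC1_wt\"``) gives none.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if generation == "F2":
        p_mutant = 0.25
    elif generation == "BC1_mut":
        p_mutant = 0.5
    elif generation == "BC1_wt":
        p_mutant = 0.0
    else:
        raise ValueError(f"unknown generation {generation!r}")
    mutants = int(rng.binomial(n_offspring, p_mutant))
    return SegregationCount(
        labels=("wild_type", "mutant"),
        observed=(n_offspring - mutants, mutants),
        ratio=(3.0, 1.0) if generation == "F2" else (1.0, 1.0),
    )
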