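#!/usr/bin/env python3
"""Step 3 — segregation statistics and co-segregation.

Tests observed F2 and backcross phenotype counts against the Mendelian
monogenic-recessive expectations (3:1 and 1:1, chi-square with continuity
correction), simulates matched populations as a sanity check, and verifies
that the causal marker co-segregates with the phenotype in the simulated
bulk from step 1.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from mutmapkit.genetics import (
    SegregationCount,
    chi_square_segregation,
    cosegregation_check,
    phenotype_ratio_simulation,
    segregation_ratio,
)

IN = ROOT / "results" / "simulated"
OUT = ROOT / "results" / "segregation.txt"

F2 = SegregationCount(("wild_type", "mutant"), (1225, 401), (3, 1))
BC = SegregationCount(("wild_type", "mutant"), (264, 272), (1, 1))


def describe(name: str, counts: SegregationCount) -> list[str]:
    res = chi_square_segregation(counts)
    _, ratio = segregation_ratio(counts)
    verdict = "consistent" if res.consistent else "inconsistent"
    return [
        f"{name}: observed {counts.observed[0]}:{counts.observed[1]} ({ratio}), "
        f"expected {counts.ratio[0]:g}:{counts.ratio[1]:g}",
        f"  chi2 = {res.statistic:.2f} (Yates, df={res.df}, "
        f"critical {res.critical_value:.2f}, p = {res.p_value:.3f}) -> {verdict}",
    ]


def main() -> None:
    lines = []
    lines += describe("F2 population", F2)
    lines += describe("backcross population", BC)

    for gen, n, label in (("F2", F2.total, "F2"), ("BC1_mut", BC.total, "backcross")):
        sim = phenotype_ratio_simulation(n, gen, seed=0)
        res = chi_square_segregation(sim)
        lines.append(
            f"simulated {label} (n={n}): {sim.observed[0]}:{sim.observed[1]}, "
            f"chi2 = {res.statistic:.2f} -> "
            + ("consistent" if res.consistent else "inconsistent")
        )

    genotypes = pd.read_csv(IN / "bulk_genotypes.tsv", sep="\t")
    causal = (IN / "causal_locus.txt").read_text().strip()
    dosage_col = genotypes[causal]
    # dosage 0/1/2 -> allele-pair strings for the co-segregation table
    calls = dosage_col.map({0: "R:R", 1: "A:R", 2: "A:A"})
    table = pd.DataFrame(
        {
            "individual": genotypes["individual"],
            "phenotype": genotypes["phenotype"],
            "causal": calls,
        }
    )
    recombinants, ok = cosegregation_check(table, "causal", "A")
    lines.append(
        f"co-segregation at {causal}: {recombinants} recombinant(s) among "
        f"{len(table)} bulk plants -> "
        + ("marker co-segregates" if ok else "marker does NOT co-segregate")
    )

    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text("\n".join(lines) + "\n")
    print("\n".join(lines))
    print(f"output: {OUT}")


if __name__ == "__main__":
    main()
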