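#!/usr/bin/env python3
"""Step 1 — simulate one mapping experiment.

Generates a reference genome with gene models, an EMS mutant line and a
sequenced bulk of 15 recessive-phenotype F2 plants, then writes the files a
real experiment would hand to the scan: reference FASTA, gene GFF3, variant
VCF (wild-type parent, mutant parent, bulk) and the bulk genotype table.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from mutmapkit import simdata

OUT = ROOT / "results" / "simulated"


def main() -> None:
    config = simdata.SimulationConfig(seed=0)
    ds = simdata.simulate_dataset(config)
    OUT.mkdir(parents=True, exist_ok=True)
    simdata.write_fasta(ds.sequences, OUT / "reference.fasta")
    simdata.write_gff3(ds.models, OUT / "genes.gff3", config.chrom_lengths)
    simdata.write_vcf(ds.records, OUT / "variants.vcf", config.chrom_lengths)
    simdata.write_genotypes_tsv(ds.cross, OUT / "bulk_genotypes.tsv")
    config.to_file(OUT / "simulation.cfg")
    (OUT / "causal_locus.txt").write_text(f"{ds.causal[0]}:{ds.causal[1]}\n")
    print(f"genome: {config.n_chromosomes} x {config.chrom_length / 1e6:.0f} Mb, "
          f"{len(ds.models)} genes")
    print(f"variants: {len(ds.records)} homozygous mutant-origin SNPs")
    print(f"causal locus: {ds.causal[0]}:{ds.causal[1]} (recorded for step 2's audit)")
    print(f"output: {OUT}")


if __name__ == "__main__":
    main()
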