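"""Synthetic EMS/F2-bulk data with the structure a MutMap analysis assumes.

The simulator emulates the post-variant-calling state of a three-library
design: a wild-type parental line, an EMS mutant line carrying homozygous
mutations (predominantly G→A/C→T transitions), and a pooled bulk of F2
individuals selected for the recessive mutant phenotype.  Selection makes
the bulk homozygous for the causal allele, so the mutant-allele read
fraction is ~1 at the causal locus, decays with map distance under Haldane
recombination (Poisson crossovers, no interference), and is ~0.5 at
unlinked mutant-origin loci.

Randomness: every stage takes an optional numpy Generator.  When omitted,
each stage uses ``default_rng([config.seed, STAGE])`` with STAGE ids
0=genome, 1=mutations, 2=cross, 3=depths, so stages are individually
reproducible.  Draw order within ``simulate_ems_mutations``: the first draw
per chromosome (in name order) is ``rng.binomial(chrom_length, ems_rate)``
for the mutation count, then positions, then per-mutation spectrum and
alternate-base draws.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pysam
from Bio.Seq import Seq

from mutmapkit.variants import GeneModel, VariantRecord, cds_offset_to_residue

_STAGE_GENOME, _STAGE_EMS, _STAGE_CROSS, _STAGE_DEPTHS = 0, 1, 2, 3

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_TRANSITION = {"G": "A", "C": "T"}


class GenePlacementError(RuntimeError):
    """A gene model could not be placed under the genome constraints."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic mapping experiment.

    Defaults mirror a scaled-down version of a single-gene bulked-segregant
    study in a selfing crop: a bulk of 15 recessive-phenotype F2 plants,
    ~21× mean bulk coverage, an EMS spectrum that is 99% canonical
    G→A/C→T transitions, and one crossover per chromosome per gamete
    (≈100 cM chromosomes).
    """

    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    ems_rate: float = 5e-5
    ems_spectrum: float = 0.99
    causal_chrom: str = "chr1"
    causal_pos: int = 5_000_000
    bulk_size: int = 15
    depth_mean: float = 21.0
    error_rate: float = 0.005
    recomb_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("genome dimensions must be strictly positive")
        if self.bulk_size < 1:
            raise ValueError("bulk_size must be strictly positive")
        for name in ("ems_spectrum", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ems_rate < 0 or self.ems_rate > 1:
            raise ValueError("ems_rate must be in [0, 1]")
        if self.depth_mean < 0 or self.recomb_rate < 0:
            raise ValueError("depth_mean and recomb_rate must be non-negative")
        if self.causal_chrom not in self.chromosomes:
            raise ValueError(f"causal chromosome {self.causal_chrom!r} not in genome")
        if not 1 <= self.causal_pos <= self.chrom_length:
            raise ValueError("causal position outside chromosome bounds")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chromosomes}

    def stage_rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])

    def to_file(self, path: str | Path) -> None:
        cp = configparser.ConfigParser()
        cp["simulation"] = {
            "n_chromosomes": str(self.n_chromosomes),
            "chrom_length": str(self.chrom_length),
            "ems_rate": repr(self.ems_rate),
            "ems_spectrum": repr(self.ems_spectrum),
            "causal_locus": f"{self.causal_chrom}:{self.causal_pos}",
            "bulk_size": str(self.bulk_size),
            "depth_mean": repr(self.depth_mean),
            "error_rate": repr(self.error_rate),
            "recomb_rate": repr(self.recomb_rate),
            "seed": str(self.seed),
        }
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        s = cp["simulation"]
        chrom, pos = s["causal_locus"].split(":")
        return cls(
            n_chromosomes=s.getint("n_chromosomes"),
            chrom_length=s.getint("chrom_length"),
            ems_rate=s.getfloat("ems_rate"),
            ems_spectrum=s.getfloat("ems_spectrum"),
            causal_chrom=chrom,
            causal_pos=int(pos),
            bulk_size=s.getint("bulk_size"),
            depth_mean=s.getfloat("depth_mean"),
            error_rate=s.getfloat("error_rate"),
            recomb_rate=s.getfloat("recomb_rate"),
            seed=s.getint("seed"),
        )


@dataclass
class SimulatedCross:
    """F2 individuals (rows) genotyped at all mutant-origin loci (columns).

    Dosages count mutant-origin (alt) alleles: 0, 1 or 2.  Phenotype is
    fully penetrant monogenic recessive: mutant iff causal dosage is 2.
    """

    loci: list[tuple[str, int]]
    genotypes: np.ndarray
    phenotypes: list[str]
    causal_index: int

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.phenotypes), len(self.loci)):
            raise ValueError("genotype matrix shape mismatch")


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    sequences: dict[str, str]
    models: list[GeneModel]
    records: list[VariantRecord]
    causal: tuple[str, int]
    cross: SimulatedCross


# ---------------------------------------------------------------------------
# genome


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def _random_gene_structure(
    rng: np.random.Generator,
    exon_count_range: tuple[int, int],
    exon_len_range: tuple[int, int],
    intron_len_range: tuple[int, int],
) -> tuple[list[int], list[int]]:
    """Exon and intron lengths; total exon length is trimmed to a codon multiple."""
    n_exons = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
    exon_lens = [int(rng.integers(exon_len_range[0], exon_len_range[1] + 1)) for _ in range(n_exons)]
    intron_lens = [
        int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
        for _ in range(n_exons - 1)
    ]
    rem = sum(exon_lens) % 3
    exon_lens[-1] -= rem
    return exon_lens, intron_lens


def _gene_from_structure(
    gene_id: str,
    chrom: str,
    strand: str,
    start: int,
    exon_lens: Sequence[int],
    intron_lens: Sequence[int],
) -> GeneModel:
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el - 1))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    exons_t = tuple(exons)
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons_t, cds=exons_t)


def simulate_genome(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    *,
    n_genes_per_chrom: int = 100,
    exon_count_range: tuple[int, int] = (2, 8),
    exon_len_range: tuple[int, int] = (120, 400),
    intron_len_range: tuple[int, int] = (80, 300),
    max_retries: int = 50,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random reference sequence plus non-overlapping multi-exon gene models.

    One gene is guaranteed to span the configured causal locus with the
    causal position inside a coding exon, so nonsynonymous/splice
    annotation is exercised downstream.  Deterministic given the seed.
    """
    rng = rng if rng is not None else config.stage_rng(_STAGE_GENOME)
    sequences = {c: _random_sequence(rng, config.chrom_length) for c in config.chromosomes}
    models: list[GeneModel] = []

    # the gene harbouring the causal locus: place so a middle exon covers it
    causal_gene = None
    for _ in range(max_retries):
        exon_lens, intron_lens = _random_gene_structure(
            rng, exon_count_range, exon_len_range, intron_len_range
        )
        k = len(exon_lens) // 2  # exon index that will contain the causal position
        offset_in_exon = int(rng.integers(3, exon_lens[k] - 3))
        upstream = sum(exon_lens[:k]) + sum(intron_lens[:k])
        start = config.causal_pos - upstream - offset_in_exon
        total_span = sum(exon_lens) + sum(intron_lens)
        if start >= 1 and start + total_span - 1 <= config.chrom_length:
            strand = "+" if rng.random() < 0.5 else "-"
            causal_gene = _gene_from_structure(
                "gene_causal", config.causal_chrom, strand, start, exon_lens, intron_lens
            )
            break
    if causal_gene is None:
        raise GenePlacementError(
            "could not place a multi-exon gene spanning the causal locus "
            f"within a {config.chrom_length} bp chromosome"
        )

    for chrom in config.chromosomes:
        placed = 0
        cursor = 1
        if chrom == config.causal_chrom:
            models.append(causal_gene)
        while placed < n_genes_per_chrom:
            cursor += int(rng.integers(2_000, 50_000))
            exon_lens, intron_lens = _random_gene_structure(
                rng, exon_count_range, exon_len_range, intron_len_range
            )
            span = sum(exon_lens) + sum(intron_lens)
            if chrom == config.causal_chrom and not (
                cursor + span - 1 < causal_gene.start or cursor > causal_gene.end
            ):
                cursor = causal_gene.end + 1
                continue
            if cursor + span - 1 > config.chrom_length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            models.append(
                _gene_from_structure(
                    f"gene_{chrom}_{placed:03d}", chrom, strand, cursor, exon_lens, intron_lens
                )
            )
            cursor += span
            placed += 1

    models.sort(key=lambda m: (m.chrom, m.start))
    return sequences, models


# ---------------------------------------------------------------------------
# EMS mutagenesis


def _nonsynonymous_transition(
    model: GeneModel, pos: int, sequences: Mapping[str, str]
) -> Optional[tuple[str, str]]:
    """(ref, alt) for a canonical transition at pos if it is nonsynonymous."""
    ref = sequences[model.chrom][pos - 1]
    if ref not in _TRANSITION:
        return None
    alt = _TRANSITION[ref]
    offset = model.genomic_to_cds(pos)
    if offset is None:
        return None
    residue, codon_pos = cds_offset_to_residue(offset)
    start = 3 * (residue - 1) + 1
    codon = []
    for off in (start, start + 1, start + 2):
        g = model.cds_to_genomic(off)
        b = sequences[model.chrom][g - 1]
        codon.append(b if model.strand == "+" else _COMPLEMENT[b])
    ref_codon = "".join(codon)
    alt_t = alt if model.strand == "+" else _COMPLEMENT[alt]
    alt_codon = ref_codon[: codon_pos - 1] + alt_t + ref_codon[codon_pos:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa != alt_aa and "*" not in (ref_aa, alt_aa):
        return ref, alt
    return None


def _seat_causal_mutation(
    config: SimulationConfig,
    sequences: Mapping[str, str],
    models: Sequence[GeneModel],
) -> tuple[int, str, str]:
    """Choose the realized causal site: a coding C/G whose canonical
    transition is nonsynonymous, as close as possible to the configured
    position within the causal gene."""
    gene = next(
        (
            m
            for m in models
            if m.chrom == config.causal_chrom and m.contains(config.causal_pos)
        ),
        None,
    )
    if gene is None:
        raise GenePlacementError("no gene model spans the configured causal locus")
    coding = [
        gene.cds_to_genomic(off) for off in range(1, gene.cds_length + 1)
    ]
    coding.sort(key=lambda p: abs(p - config.causal_pos))
    for pos in coding:
        hit = _nonsynonymous_transition(gene, pos, sequences)
        if hit is not None:
            return pos, hit[0], hit[1]
    raise GenePlacementError(
        "no coding G/C with a nonsynonymous transition in the causal gene"
    )


def simulate_ems_mutations(
    config: SimulationConfig,
    sequences: Mapping[str, str],
    models: Sequence[GeneModel],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[VariantRecord], tuple[str, int]]:
    """Homozygous mutant-origin SNPs, plus the forced causal lesion.

    A fraction ``ems_spectrum`` of mutations are canonical G→A/C→T
    transitions.  The causal site is always present and is forced to be a
    canonical transition in a coding exon producing an amino-acid change.
    Parental calls are hard: wild type hom-ref, mutant hom-alt.
    """
    rng = rng if rng is not None else config.stage_rng(_STAGE_EMS)
    causal_pos, causal_ref, causal_alt = _seat_causal_mutation(config, sequences, models)
    causal = (config.causal_chrom, causal_pos)

    records: list[VariantRecord] = []
    for chrom in config.chromosomes:
        seq = sequences[chrom]
        n = int(rng.binomial(config.chrom_length, config.ems_rate))
        taken = {causal_pos} if chrom == config.causal_chrom else set()
        positions: list[int] = []
        raw = rng.choice(config.chrom_length, size=min(n, config.chrom_length), replace=False) + 1
        for pos in raw.tolist():
            if pos not in taken:
                positions.append(pos)
                taken.add(pos)
        for pos in positions:
            canonical = rng.random() < config.ems_spectrum
            ref = seq[pos - 1]
            if canonical:
                # a canonical lesion needs a G or C; re-seat the site if not
                guard = 0
                while ref not in _TRANSITION:
                    guard += 1
                    if guard > 10_000:  # pragma: no cover
                        raise GenePlacementError("no G/C base available for EMS transition")
                    cand = int(rng.integers(1, config.chrom_length + 1))
                    if cand in taken:
                        continue
                    pos, ref = cand, seq[cand - 1]
                taken.add(pos)
                alt = _TRANSITION[ref]
            else:
                choices = [b for b in "ACGT" if b != ref and (ref, b) not in (("G", "A"), ("C", "T"))]
                alt = choices[int(rng.integers(len(choices)))]
            records.append(
                VariantRecord(
                    chrom=chrom, pos=pos, ref=ref, alt=alt,
                    wt_call="hom_ref", mut_call="hom_alt",
                )
            )
        if chrom == config.causal_chrom:
            records.append(
                VariantRecord(
                    chrom=chrom, pos=causal_pos, ref=causal_ref, alt=causal_alt,
                    wt_call="hom_ref", mut_call="hom_alt",
                )
            )
    records.sort(key=lambda r: (r.chrom, r.pos))
    # positions may have been re-drawn onto duplicates across the loop; dedupe
    seen: set[tuple[str, int]] = set()
    unique = []
    for r in records:
        key = (r.chrom, r.pos)
        if key not in seen:
            seen.add(key)
            unique.append(r)
    return unique, causal


# ---------------------------------------------------------------------------
# F2 cross


def _gamete(
    rng: np.random.Generator, length: int, positions: np.ndarray, recomb_rate: float
) -> np.ndarray:
    """Alleles (0=wild-type homolog, 1=mutant homolog) transmitted at loci.

    Crossover count is Poisson(recomb_rate) with uniform positions — the
    Haldane no-interference model; the starting homolog is fair-coin.
    """
    phase = int(rng.integers(2))
    k = int(rng.poisson(recomb_rate))
    if k == 0:
        return np.full(positions.shape, phase, dtype=np.int8)
    xo = np.sort(rng.uniform(0.0, float(length), size=k))
    return ((phase + np.searchsorted(xo, positions)) % 2).astype(np.int8)


def _f2_individual(
    rng: np.random.Generator,
    config: SimulationConfig,
    chrom_positions: dict[str, np.ndarray],
) -> np.ndarray:
    parts = []
    for chrom in config.chromosomes:
        pos = chrom_positions[chrom]
        if pos.size == 0:
            continue
        g1 = _gamete(rng, config.chrom_length, pos, config.recomb_rate)
        g2 = _gamete(rng, config.chrom_length, pos, config.recomb_rate)
        parts.append(g1 + g2)
    return np.concatenate(parts) if parts else np.zeros(0, dtype=np.int8)


def simulate_f2_bulk(
    config: SimulationConfig,
    records: Sequence[VariantRecord],
    causal: tuple[str, int],
    rng: Optional[np.random.Generator] = None,
) -> SimulatedCross:
    """Bulk of ``bulk_size`` recessive-phenotype F2 individuals.

    The F1 is uniformly heterozygous at every mutant-origin locus; selfed
    offspring are rejection-sampled until the bulk contains only
    causal-homozygous (mutant-phenotype) plants.
    """
    loci = [(r.chrom, r.pos) for r in records]
    if causal not in loci:
        raise ValueError("variant list must include the causal locus")
    rng = rng if rng is not None else config.stage_rng(_STAGE_CROSS)
    chrom_positions = {
        chrom: np.array([p for c, p in loci if c == chrom], dtype=float)
        for chrom in config.chromosomes
    }
    causal_index = loci.index(causal)
    rows = []
    while len(rows) < config.bulk_size:
        geno = _f2_individual(rng, config, chrom_positions)
        if geno[causal_index] == 2:
            rows.append(geno)
    genotypes = np.stack(rows)
    return SimulatedCross(
        loci=loci,
        genotypes=genotypes,
        phenotypes=["mutant"] * config.bulk_size,
        causal_index=causal_index,
    )


# ---------------------------------------------------------------------------
# sequencing


def simulate_allele_depths(
    config: SimulationConfig,
    records: Sequence[VariantRecord],
    cross: SimulatedCross,
    rng: Optional[np.random.Generator] = None,
) -> list[VariantRecord]:
    """Depth-sample the bulk at every variant.

    Per site, total depth ~ Poisson(depth_mean); each read comes from a
    random bulk individual's genotype and is miscalled with probability
    ``error_rate`` to one of the three other bases uniformly.  Reads
    matching neither ref nor alt are excluded from the allele depths, as a
    caller's AD field would.  Zero-depth sites are retained with (0, 0)
    counts, leaving their SNP index undefined rather than silently dropped.
    """
    rng = rng if rng is not None else config.stage_rng(_STAGE_DEPTHS)
    n = len(records)
    if cross.genotypes.shape[1] != n:
        raise ValueError("cross and record list disagree on locus count")
    q = cross.genotypes.mean(axis=0) / 2.0  # P(a read carries the alt allele)
    depth = rng.poisson(config.depth_mean, size=n)
    alt_true = rng.binomial(depth, q)
    ref_true = depth - alt_true
    e = config.error_rate
    alt_mis = rng.binomial(alt_true, e)
    ref_mis = rng.binomial(ref_true, e)
    alt_to_ref = rng.binomial(alt_mis, 1.0 / 3.0)
    ref_to_alt = rng.binomial(ref_mis, 1.0 / 3.0)
    alt_count = alt_true - alt_mis + ref_to_alt
    ref_count = ref_true - ref_mis + alt_to_ref
    out = []
    for i, r in enumerate(records):
        c = r.copy()
        c.bulk_ref_depth = int(ref_count[i])
        c.bulk_alt_depth = int(alt_count[i])
        out.append(c)
    return out


def simulate_dataset(
    config: SimulationConfig,
    *,
    sequences: Optional[dict[str, str]] = None,
    models: Optional[list[GeneModel]] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedDataset:
    """Run all stages; a pre-built reference genome may be reused across
    replicate experiments (mutagenesis, cross and sequencing are redrawn)."""
    if sequences is None or models is None:
        sequences, models = simulate_genome(
            config, rng=None if rng is None else rng
        )
    muts, causal = simulate_ems_mutations(config, sequences, models, rng=rng)
    cross = simulate_f2_bulk(config, muts, causal, rng=rng)
    records = simulate_allele_depths(config, muts, cross, rng=rng)
    return SimulatedDataset(
        config=config, sequences=sequences, models=models,
        records=records, causal=causal, cross=cross,
    )


# ---------------------------------------------------------------------------
# writers

#: fixed parental library depths used when emitting VCF (hard calls)
WT_PARENT_DEPTH = 48
MUT_PARENT_DEPTH = 22


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(
    models: Sequence[GeneModel], path: str | Path, chrom_lengths: Mapping[str, int]
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for m in models:
            attrs = f"ID={m.gene_id}"
            if m.product:
                attrs += f";product={m.product}"
            fh.write(
                f"{m.chrom}\tmutmapkit\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            mrna = f"{m.gene_id}.t1"
            fh.write(
                f"{m.chrom}\tmutmapkit\tmRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={mrna};Parent={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, start=1):
                fh.write(
                    f"{m.chrom}\tmutmapkit\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )
            phase = 0
            cds_iter = m.cds if m.strand == "+" else tuple(reversed(m.cds))
            phases = {}
            for s, e in cds_iter:
                phases[(s, e)] = phase
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
            for i, (s, e) in enumerate(m.cds, start=1):
                fh.write(
                    f"{m.chrom}\tmutmapkit\tCDS\t{s}\t{e}\t.\t{m.strand}\t{phases[(s, e)]}\t"
                    f"ID={mrna}.cds{i};Parent={mrna}\n"
                )


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    chrom_lengths: Mapping[str, int],
    wt_sample: str = "wt",
    mut_sample: str = "mut",
    bulk_sample: str = "bulk",
) -> None:
    """Emit a VCF v4.2 with GT/AD/DP for the two parents and the bulk."""
    header = pysam.VariantHeader()
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for s in (wt_sample, mut_sample, bulk_sample):
        header.add_sample(s)
    gt_of = {"hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1), "missing": (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in records:
            rec = vf.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos, alleles=(r.ref, r.alt)
            )
            rec.samples[wt_sample]["GT"] = gt_of[r.wt_call or "missing"]
            rec.samples[wt_sample]["AD"] = (
                (WT_PARENT_DEPTH, 0) if r.wt_call == "hom_ref" else (0, WT_PARENT_DEPTH)
            )
            rec.samples[wt_sample]["DP"] = WT_PARENT_DEPTH
            rec.samples[mut_sample]["GT"] = gt_of[r.mut_call or "missing"]
            rec.samples[mut_sample]["AD"] = (
                (0, MUT_PARENT_DEPTH) if r.mut_call == "hom_alt" else (MUT_PARENT_DEPTH, 0)
            )
            rec.samples[mut_sample]["DP"] = MUT_PARENT_DEPTH
            rd = 0 if r.bulk_ref_depth is None else r.bulk_ref_depth
            ad = 0 if r.bulk_alt_depth is None else r.bulk_alt_depth
            rec.samples[bulk_sample]["GT"] = (None, None)
            rec.samples[bulk_sample]["AD"] = (rd, ad)
            rec.samples[bulk_sample]["DP"] = rd + ad
            vf.write(rec)


def write_genotypes_tsv(cross: SimulatedCross, path: str | Path) -> None:
    import pandas as pd

    cols = [f"{c}:{p}" for c, p in cross.loci]
    df = pd.DataFrame(cross.genotypes, columns=cols)
    df.insert(0, "phenotype", cross.phenotypes)
    df.insert(0, "individual", [f"F2_{i + 1:03d}" for i in range(len(cross.phenotypes))])
    df.to_csv(path, sep="\t", index=False)
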