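"""Variant records, gene models, coordinate arithmetic and effect annotation.

The unit of analysis is a biallelic SNP with per-library allele depths: a
wild-type parental library, a mutant parental library, and a pooled F2 bulk.
Gene models carry ordered exon/CDS intervals (1-based inclusive, the
VCF/GFF3 convention) and support strand-aware genomic ↔ CDS ↔ residue
mapping, which is what turns a genomic substitution into an amino-acid
change such as S→F.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd
import pysam
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

CallClass = Literal["hom_ref", "het", "hom_alt", "missing"]

#: effect classes expected to alter protein function
LARGE_EFFECT = frozenset({"nonsynonymous", "stop_gain", "stop_loss", "splicing"})

#: canonical EMS lesions: G→A and C→T transitions
EMS_CHANGES = frozenset({("G", "A"), ("C", "T")})

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class VariantFileError(ValueError):
    """Malformed or incompatible variant input."""


class ReferenceMismatchError(ValueError):
    """VCF REF allele disagrees with the reference sequence."""


@dataclass
class VariantRecord:
    """One biallelic SNP with library calls, bulk depths and annotations."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    wt_call: Optional[CallClass] = None
    mut_call: Optional[CallClass] = None
    bulk_ref_depth: Optional[int] = None
    bulk_alt_depth: Optional[int] = None
    effect: Optional[str] = None
    gene_id: Optional[str] = None
    aa_change: Optional[tuple[str, int, str]] = None
    ems_typical: Optional[bool] = None
    snp_index: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"SNPs only: got ref={self.ref!r} alt={self.alt!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        for d in (self.bulk_ref_depth, self.bulk_alt_depth):
            if d is not None and d < 0:
                raise ValueError("allele depths must be non-negative")

    @property
    def bulk_depth(self) -> Optional[int]:
        if self.bulk_ref_depth is None or self.bulk_alt_depth is None:
            return None
        return self.bulk_ref_depth + self.bulk_alt_depth

    def copy(self) -> "VariantRecord":
        return replace(self)


@dataclass(frozen=True)
class GeneModel:
    """A transcript model: ordered exons and CDS intervals on one strand.

    Intervals are 1-based inclusive and sorted in genomic order regardless
    of strand; transcript order is derived from ``strand``.  A model with
    17 exons necessarily has 16 introns.
    """

    gene_id: str
    chrom: str
    strand: Literal["+", "-"]
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        for name, ivals in (("exons", self.exons), ("cds", self.cds)):
            if not ivals:
                raise ValueError(f"{name} must be non-empty")
            for s, e in ivals:
                if s > e or s < 1:
                    raise ValueError(f"bad {name} interval ({s}, {e})")
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise ValueError(f"{name} intervals must be sorted, non-overlapping")
        if self.cds_length % 3 != 0:
            raise ValueError(f"CDS length {self.cds_length} not divisible by 3")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """1-based CDS offset of a genomic position, or None if non-coding."""
        ivals = self.cds if self.strand == "+" else tuple(reversed(self.cds))
        offset = 0
        for s, e in ivals:
            if s <= pos <= e:
                return offset + (pos - s + 1 if self.strand == "+" else e - pos + 1)
            offset += e - s + 1
        return None

    def cds_to_genomic(self, offset: int) -> int:
        """Genomic position of a 1-based CDS offset (inverse of genomic_to_cds)."""
        if offset < 1 or offset > self.cds_length:
            raise ValueError(f"CDS offset {offset} outside [1, {self.cds_length}]")
        ivals = self.cds if self.strand == "+" else tuple(reversed(self.cds))
        for s, e in ivals:
            n = e - s + 1
            if offset <= n:
                return s + offset - 1 if self.strand == "+" else e - offset + 1
            offset -= n
        raise AssertionError("unreachable")

    def exon_boundary_distance(self, pos: int) -> int:
        """Distance from an intronic position to the nearest exon edge.

        The first intron base next to an exon has distance 1 (the canonical
        GT/AG splice dinucleotides are distances 1 and 2).
        """
        best = None
        for (s, e) in self.exons:
            for b in (s, e):
                d = abs(pos - b)
                if best is None or d < best:
                    best = d
        if best is None:  # pragma: no cover
            raise AssertionError("gene without exons")
        return best

    def coding_sequence(self, reference: Mapping[str, str]) -> str:
        """Spliced CDS in transcript orientation."""
        parts = [fetch_sequence(reference, self.chrom, s, e) for s, e in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def fetch_sequence(reference: Mapping[str, str], chrom: str, start: int, end: int) -> str:
    """Fetch reference bases (1-based inclusive) from a dict-of-strings or pyfaidx.Fasta."""
    seq = reference[chrom]
    out = seq[start - 1 : end]
    return str(out).upper()


def map_genomic_to_cds(model: GeneModel, pos: int) -> tuple[str, Optional[int]]:
    """Locate a position relative to a gene model.

    Returns one of ``("cds", offset)``, ``("utr", None)`` (exonic but outside
    the CDS), ``("intronic", distance-to-nearest-exon-boundary)`` or
    ``("intergenic", None)``.
    """
    if not model.contains(pos):
        return ("intergenic", None)
    offset = model.genomic_to_cds(pos)
    if offset is not None:
        return ("cds", offset)
    if any(s <= pos <= e for s, e in model.exons):
        return ("utr", None)
    return ("intronic", model.exon_boundary_distance(pos))


def cds_offset_to_residue(offset: int) -> tuple[int, int]:
    """Residue index and codon position (both 1-based) of a CDS offset.

    Offset 2297 → residue 766, codon position 2.
    """
    if offset < 1:
        raise ValueError("CDS offset must be >= 1")
    return ((offset - 1) // 3 + 1, (offset - 1) % 3 + 1)


def translate_cds(cds: str, allow_internal_stop: bool = False) -> str:
    """Translate a CDS with the standard genetic code.

    A terminal stop codon is removed (a 2,715-bp CDS with terminal stop
    yields 904 residues).  An internal stop raises unless
    ``allow_internal_stop`` is set, in which case the protein is truncated
    at the first stop — useful for reasoning about loss-of-function alleles.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        if allow_internal_stop:
            return protein[: protein.index("*")]
        raise ValueError(f"internal stop codon at residue {protein.index('*') + 1}")
    return protein


def ems_typical(ref: str, alt: str) -> bool:
    """True iff the change is a canonical EMS lesion (G→A or C→T)."""
    return (ref.upper(), alt.upper()) in EMS_CHANGES


def _codon_for_offset(
    model: GeneModel, offset: int, reference: Mapping[str, str]
) -> tuple[str, int, int]:
    """Ref codon (transcript orientation), residue index and codon position."""
    residue, codon_pos = cds_offset_to_residue(offset)
    start = 3 * (residue - 1) + 1
    bases = []
    for off in (start, start + 1, start + 2):
        gpos = model.cds_to_genomic(off)
        b = fetch_sequence(reference, model.chrom, gpos, gpos)
        bases.append(b if model.strand == "+" else _COMPLEMENT[b])
    return "".join(bases), residue, codon_pos


def annotate_effect(
    record: VariantRecord,
    models: Sequence[GeneModel],
    reference: Mapping[str, str],
    splice_margin: int = 2,
) -> VariantRecord:
    """Annotate effect class (and amino-acid change when coding) in place.

    Coding SNPs are translated ref-codon vs alt-codon; intronic SNPs within
    ``splice_margin`` bases of an exon boundary (default 2, the canonical
    donor/acceptor dinucleotides) are classed as splicing.  The EMS-typical
    flag is set as a side effect.
    """
    record.ems_typical = ems_typical(record.ref, record.alt)
    ref_base = fetch_sequence(reference, record.chrom, record.pos, record.pos)
    if ref_base != record.ref.upper():
        raise ReferenceMismatchError(
            f"{record.chrom}:{record.pos} REF {record.ref} != reference {ref_base}"
        )
    hit = None
    for model in models:
        if model.chrom == record.chrom and model.contains(record.pos):
            hit = model
            break
    if hit is None:
        record.effect = "intergenic"
        return record
    record.gene_id = hit.gene_id
    kind, detail = map_genomic_to_cds(hit, record.pos)
    if kind == "utr":
        record.effect = "UTR"
        return record
    if kind == "intronic":
        record.effect = "splicing" if detail <= splice_margin else "intronic"
        return record
    # coding: substitute within the codon, strand-aware
    offset = detail
    ref_codon, residue, codon_pos = _codon_for_offset(hit, offset, reference)
    alt_base = record.alt.upper() if hit.strand == "+" else _COMPLEMENT[record.alt.upper()]
    alt_codon = ref_codon[: codon_pos - 1] + alt_base + ref_codon[codon_pos:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        record.effect = "synonymous"
        record.aa_change = None
    elif alt_aa == "*":
        record.effect = "stop_gain"
        record.aa_change = (ref_aa, residue, alt_aa)
    elif ref_aa == "*":
        record.effect = "stop_loss"
        record.aa_change = (ref_aa, residue, alt_aa)
    else:
        record.effect = "nonsynonymous"
        record.aa_change = (ref_aa, residue, alt_aa)
    return record


def homozygous_differences(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Sites where the mutant library is hom-alt and the wild type hom-ref.

    These are the candidate mutant-origin loci; everything else (shared
    polymorphism against the reference, heterozygous or missing calls) is
    background and dropped.
    """
    kept = []
    for r in records:
        if r.wt_call is None or r.mut_call is None:
            raise ValueError(f"{r.chrom}:{r.pos} lacks parental calls")
        if r.mut_call == "hom_alt" and r.wt_call == "hom_ref":
            kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# readers / writers


def _call_class(gt: Optional[tuple]) -> CallClass:
    if gt is None or any(a is None for a in gt):
        return "missing"
    alleles = set(gt)
    if alleles == {0}:
        return "hom_ref"
    if 0 in alleles:
        return "het"
    return "hom_alt"


def read_variants(
    path: str | Path,
    wt_sample: str,
    mut_sample: str,
    bulk_sample: str,
) -> list[VariantRecord]:
    """Read biallelic SNPs from a VCF with per-sample AD.

    Indels and multi-allelic sites are skipped (count logged).  Raises if a
    named sample is absent or the bulk sample lacks AD.
    """
    path = Path(path)
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    for s in (wt_sample, mut_sample, bulk_sample):
        if s not in samples:
            raise VariantFileError(f"sample {s!r} not in VCF (has {samples})")
    records: list[VariantRecord] = []
    skipped = 0
    for i, rec in enumerate(vf, start=1):
        try:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or alt == "*":
                skipped += 1
                continue
            bulk = rec.samples[bulk_sample]
            ad = bulk.get("AD")
            if ad is None or any(a is None for a in ad):
                raise VariantFileError(
                    f"record {rec.chrom}:{rec.pos}: bulk sample {bulk_sample!r} lacks AD"
                )
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    wt_call=_call_class(rec.samples[wt_sample].get("GT")),
                    mut_call=_call_class(rec.samples[mut_sample].get("GT")),
                    bulk_ref_depth=int(ad[0]),
                    bulk_alt_depth=int(ad[1]),
                )
            )
        except VariantFileError:
            raise
        except Exception as exc:  # malformed record
            raise VariantFileError(f"malformed VCF record #{i}: {exc}") from exc
    if skipped:
        logger.info("skipped %d non-SNP/multi-allelic records", skipped)
    read_variants.last_skipped = skipped  # type: ignore[attr-defined]
    return records


#: documented column order of the plain-TSV allele-count dialect
TSV_COLUMNS = ["chrom", "pos", "ref", "alt", "wt_gt", "mut_gt", "bulk_ref", "bulk_alt"]


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    """Read the TSV allele-count dialect (columns: chrom, pos, ref, alt,
    wt_gt, mut_gt, bulk_ref, bulk_alt; genotype classes as text)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise VariantFileError(f"TSV lacks columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            VariantRecord(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                wt_call=row.wt_gt,
                mut_call=row.mut_gt,
                bulk_ref_depth=int(row.bulk_ref),
                bulk_alt_depth=int(row.bulk_alt),
            )
        )
    return out


def write_variants_tsv(records: Sequence[VariantRecord], path: str | Path) -> None:
    rows = [
        {
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "wt_gt": r.wt_call,
            "mut_gt": r.mut_call,
            "bulk_ref": r.bulk_ref_depth,
            "bulk_alt": r.bulk_alt_depth,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def write_annotated_tsv(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Annotated variant table (adds gene, effect, aa change, flags, index)."""
    rows = []
    for r in records:
        aa = "" if r.aa_change is None else f"{r.aa_change[0]}{r.aa_change[1]}{r.aa_change[2]}"
        rows.append(
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "gene_id": r.gene_id or "",
                "effect": r.effect or "",
                "aa_change": aa,
                "ems_typical": r.ems_typical,
                "snp_index": "" if r.snp_index is None else f"{r.snp_index:.6g}",
                "bulk_ref": r.bulk_ref_depth,
                "bulk_alt": r.bulk_alt_depth,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon/CDS features)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (f.start, f.end) for f in db.children(gene, featuretype="exon")
        )
        cds = sorted((f.start, f.end) for f in db.children(gene, featuretype="CDS"))
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=tuple(exons),
                cds=tuple(cds) if cds else tuple(exons),
                product=gene.attributes.get("product", [""])[0],
            )
        )
    models.sort(key=lambda m: (m.chrom, m.start))
    return models


def read_fasta(path: str | Path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}
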