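"""SNP-index computation, filter cascade and sliding-window scan.

In a bulk of recessive-phenotype F2 plants the SNP index — the fraction of
bulk reads carrying the mutant allele — is ~0.5 at mutant-origin loci
unlinked to the selected mutation and approaches 1 in the causal region.
The scan averages the index in overlapping windows (default 1 Mb window,
10 kb step); the candidate screen keeps index-1, EMS-typical, large-effect
variants, in that order.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from mutmapkit.variants import (
    LARGE_EFFECT,
    GeneModel,
    VariantRecord,
    annotate_effect,
    homozygous_differences,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 1_000_000
DEFAULT_STEP = 10_000
DEFAULT_MIN_INDEX = 0.3

EmsFilterMode = Literal["strict", "permissive", "off"]
IndexMode = Literal["tolerance", "exact"]


@dataclass(frozen=True)
class WindowStat:
    """Mean SNP index of the variants falling in one window."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_variants: int
    mean_index: Optional[float]

    def __post_init__(self) -> None:
        if self.n_variants < 0:
            raise ValueError("n_variants must be >= 0")
        if self.mean_index is not None and not 0.0 <= self.mean_index <= 1.0:
            raise ValueError("mean_index must lie in [0, 1]")


@dataclass
class CandidateReport:
    """Survivors of the candidate screen plus per-stage retention counts."""

    candidates: list[VariantRecord]
    stage_counts: dict[str, int]
    parameters: dict[str, object] = field(default_factory=dict)


def snp_index(record: VariantRecord) -> Optional[float]:
    """Bulk alt-read fraction: alt / (alt + ref); None when depth is zero."""
    if record.bulk_ref_depth is None or record.bulk_alt_depth is None:
        raise ValueError(f"{record.chrom}:{record.pos} lacks bulk depths")
    if record.bulk_ref_depth < 0 or record.bulk_alt_depth < 0:
        raise ValueError("negative allele depth")
    total = record.bulk_ref_depth + record.bulk_alt_depth
    if total == 0:
        return None
    return record.bulk_alt_depth / total


def attach_snp_index(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    out = []
    for r in records:
        r.snp_index = snp_index(r)
        out.append(r)
    return out


def filter_low_index(
    records: Sequence[VariantRecord], threshold: float = DEFAULT_MIN_INDEX
) -> list[VariantRecord]:
    """Drop records with SNP index below the threshold (boundary kept).

    Undefined-index records (zero depth) are dropped with a logged count —
    they carry no evidence either way.
    """
    undefined = sum(1 for r in records if r.snp_index is None)
    if undefined:
        logger.info("dropping %d zero-depth (undefined index) records", undefined)
    return [r for r in records if r.snp_index is not None and r.snp_index >= threshold]


def sliding_window_scan(
    records: Sequence[VariantRecord],
    chrom_lengths: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list[WindowStat]:
    """Mean SNP index in overlapping windows along each chromosome.

    Windows start at 1, 1+step, … while the start is within the chromosome;
    terminal windows are truncated at the chromosome end.  Input must be
    sorted by (chrom, pos) — unsorted input raises rather than being
    silently reordered.  Empty windows get an undefined mean.
    """
    if not (window >= step > 0):
        raise ValueError("need window >= step > 0")
    keys = [(r.chrom, r.pos) for r in records]
    if keys != sorted(keys):
        raise ValueError("records must be sorted by (chrom, pos)")
    for r in records:
        if r.snp_index is None:
            raise ValueError(f"{r.chrom}:{r.pos} has undefined SNP index")
    out: list[WindowStat] = []
    by_chrom: dict[str, list[VariantRecord]] = {c: [] for c in chrom_lengths}
    for r in records:
        if r.chrom not in by_chrom:
            raise ValueError(f"record on unknown chromosome {r.chrom!r}")
        by_chrom[r.chrom].append(r)
    for chrom, length in chrom_lengths.items():
        rs = by_chrom[chrom]
        pos = np.array([r.pos for r in rs], dtype=np.int64)
        idx = np.array([r.snp_index for r in rs], dtype=float)
        csum = np.concatenate([[0.0], np.cumsum(idx)])
        starts = np.arange(1, length + 1, step, dtype=np.int64)
        ends = np.minimum(starts + window - 1, length)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        for s, e, a, b in zip(starts, ends, lo, hi):
            n = int(b - a)
            # cumulative-sum roundoff can push an all-ones mean past 1.0
            mean = min(max((csum[b] - csum[a]) / n, 0.0), 1.0) if n else None
            out.append(WindowStat(chrom, int(s), int(e), n, mean))
    return out


def _passes_index_one(record: VariantRecord, mode: IndexMode) -> bool:
    total = record.bulk_depth
    if total is None or total == 0 or record.snp_index is None:
        return False
    if mode == "exact":
        return record.snp_index == 1.0
    eps = 1.0 / (2.0 * total)  # "within half a read" of 1
    return record.snp_index >= 1.0 - eps


def candidate_screen(
    records: Sequence[VariantRecord],
    *,
    index_mode: IndexMode = "tolerance",
    ems_filter: EmsFilterMode = "strict",
) -> CandidateReport:
    """Apply the candidate filter cascade, in order:

    1. retain loci with SNP index = 1 (exactly, or within half a read of 1);
    2. filter out non-typical EMS loci (``strict``), or only flag them
       (``permissive``/``off`` keep them — some published candidate lists
       retain a transversion, so the stage is configurable);
    3. retain large-effect loci (nonsynonymous, stop gain/loss, splicing).

    Survivors are ordered by (chrom, pos); per-stage retention counts are
    reported so the cascade's monotonicity can be audited.
    """
    for r in records:
        if r.effect is None or r.ems_typical is None:
            raise ValueError(f"{r.chrom}:{r.pos} lacks annotation for the screen")
    stage0 = list(records)
    stage1 = [r for r in stage0 if _passes_index_one(r, index_mode)]
    if ems_filter == "strict":
        stage2 = [r for r in stage1 if r.ems_typical]
    else:
        stage2 = list(stage1)
    stage3 = [r for r in stage2 if r.effect in LARGE_EFFECT]
    stage3.sort(key=lambda r: (r.chrom, r.pos))
    return CandidateReport(
        candidates=stage3,
        stage_counts={
            "input": len(stage0),
            "snp_index_1": len(stage1),
            "ems_typical": len(stage2),
            "large_effect": len(stage3),
        },
        parameters={"index_mode": index_mode, "ems_filter": ems_filter},
    )


@dataclass
class PipelineResult:
    """Everything one MutMap run produces."""

    homdiff: list[VariantRecord]
    annotated: list[VariantRecord]
    scan_input: list[VariantRecord]
    windows: list[WindowStat]
    preselected: list[VariantRecord]
    report: CandidateReport
    counts: dict[str, int]

    def top_window(self) -> WindowStat:
        """Non-empty window with the highest mean index (first on ties)."""
        best = None
        for w in self.windows:
            if w.mean_index is None:
                continue
            if best is None or w.mean_index > best.mean_index:
                best = w
        if best is None:
            raise ValueError("no non-empty windows")
        return best

    def max_mean_index(self) -> float:
        return self.top_window().mean_index  # type: ignore[return-value]


def run_pipeline(
    records: Sequence[VariantRecord],
    models: Sequence[GeneModel],
    reference: Mapping[str, str],
    chrom_lengths: Mapping[str, int],
    *,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_index: float = DEFAULT_MIN_INDEX,
    splice_margin: int = 2,
    index_mode: IndexMode = "tolerance",
    ems_filter: EmsFilterMode = "strict",
) -> PipelineResult:
    """Full scan: parental homozygous differences → effect annotation →
    SNP index → low-index filter → sliding-window track, with the candidate
    cascade run on the large-effect preselection.

    The window track is computed over all homozygous-difference SNPs with a
    defined index ≥ ``min_index`` (the usual MutMap plotting convention);
    the candidate cascade additionally restricts to large-effect loci first.
    """
    homdiff = homozygous_differences(records)
    annotated = [
        annotate_effect(r, models, reference, splice_margin=splice_margin)
        for r in homdiff
    ]
    attach_snp_index(annotated)
    scan_input = filter_low_index(annotated, min_index)
    windows = sliding_window_scan(scan_input, chrom_lengths, window, step)
    preselected = [r for r in annotated if r.effect in LARGE_EFFECT]
    kept = filter_low_index(preselected, min_index)
    report = candidate_screen(kept, index_mode=index_mode, ems_filter=ems_filter)
    counts = {
        "input": len(list(records)),
        "homozygous_diff": len(homdiff),
        "large_effect_preselect": len(preselected),
        "index_ge_threshold": len(kept),
        **{f"screen_{k}": v for k, v in report.stage_counts.items()},
    }
    return PipelineResult(
        homdiff=homdiff,
        annotated=annotated,
        scan_input=scan_input,
        windows=windows,
        preselected=preselected,
        report=report,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# report output


def write_candidates_tsv(report: CandidateReport, path: str | Path) -> None:
    """Candidate table: gene id, position, alleles, index, class, change."""
    rows = []
    for r in report.candidates:
        aa = "" if r.aa_change is None else f"{r.aa_change[0]}{r.aa_change[1]}{r.aa_change[2]}"
        rows.append(
            {
                "gene_id": r.gene_id or "",
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "snp_index": f"{r.snp_index:.6g}" if r.snp_index is not None else "",
                "variant": r.effect,
                "aa_change": aa,
            }
        )
    cols = ["gene_id", "chrom", "pos", "ref", "alt", "snp_index", "variant", "aa_change"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_windows_bed(windows: Sequence[WindowStat], path: str | Path) -> None:
    """Window track as BED-like TSV.

    BED is 0-based half-open: a 1-based inclusive window [s, e] is written
    as (s-1, e).  Empty windows write '.' for the mean.
    """
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tn_variants\tmean_index\n")
        for w in windows:
            mean = "." if w.mean_index is None else f"{w.mean_index:.6g}"
            fh.write(f"{w.chrom}\t{w.start - 1}\t{w.end}\t{w.n_variants}\t{mean}\n")


def read_windows_bed(path: str | Path) -> list[WindowStat]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, start, end, n, mean = line.rstrip("\n").split("\t")
            out.append(
                WindowStat(
                    chrom,
                    int(start) + 1,
                    int(end),
                    int(n),
                    None if mean == "." else float(mean),
                )
            )
    return out


def write_run_log(result: PipelineResult, path: str | Path) -> None:
    payload = {"counts": result.counts, "parameters": result.report.parameters}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_report(
    result: PipelineResult,
    out_dir: str | Path,
    *,
    prefix: str = "mutmap",
) -> dict[str, Path]:
    """Write candidate TSV, window BED track and a JSON run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "candidates": out / f"{prefix}_candidates.tsv",
        "windows": out / f"{prefix}_windows.bed",
        "log": out / f"{prefix}_run_log.json",
    }
    write_candidates_tsv(result.report, paths["candidates"])
    write_windows_bed(result.windows, paths["windows"])
    write_run_log(result, paths["log"])
    return paths
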