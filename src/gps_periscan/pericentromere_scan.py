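"""Candidate pericentromeric locus discovery.

A candidate locus is an H3K27ac peak intersected with annotated repeats and a
pericentromeric window (the centromere flank, excluding the centromere
itself). Joint H3K27ac/H3K27me3 strength marks the locus as
transcription-competent pericentromeric chromatin; competence is reported as
a flag rather than used as a filter, because a locus can be competent in one
cell line and silent in another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .config import PipelineConfig
from .core_io import GenomicInterval, SignalTrack, intersect, merge_intervals

logger = logging.getLogger("gps_periscan")


@dataclass(frozen=True)
class CandidateLocus:
    interval: GenomicInterval
    distance_to_centromere: int  # bp, 0 if abutting
    h3k27ac_max: float
    h3k27me3_max: float
    in_repeat: bool
    competent: bool  # both marks reach their thresholds over the interval


def pericentromeric_windows(
    centromeres: list[GenomicInterval],
    flank: int,
    chrom_sizes: dict[str, int],
) -> list[GenomicInterval]:
    """Up to two flank windows per centromere, clipped to the chromosome.

    Chromosomes present in ``chrom_sizes`` but lacking a centromere are
    skipped with a warning.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    by_chrom = {c.chrom: c for c in centromeres}
    for chrom in chrom_sizes:
        if chrom not in by_chrom:
            logger.warning("pericentromeric_windows: no centromere for %s; skipped", chrom)
    windows: list[GenomicInterval] = []
    for cen in centromeres:
        chrom_len = chrom_sizes.get(cen.chrom)
        if chrom_len is None:
            raise ValueError(f"centromere chromosome {cen.chrom} missing from chrom_sizes")
        left_start = max(0, cen.start - flank)
        if left_start < cen.start:
            windows.append(GenomicInterval(cen.chrom, left_start, cen.start))
        right_end = min(chrom_len, cen.end + flank)
        if cen.end < right_end:
            windows.append(GenomicInterval(cen.chrom, cen.end, right_end))
    return windows


def call_peaks(
    track: SignalTrack,
    threshold: float,
    min_width: int = 200,
    merge_gap: int = 100,
) -> list[GenomicInterval]:
    """Threshold-based peak calling on a fold-change track.

    Maximal runs of signal >= threshold are taken; runs on one chromosome
    separated by < merge_gap bp are merged; merged runs narrower than
    min_width are dropped.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    runs: list[GenomicInterval] = []
    for iv, value in track.records:
        if value >= threshold:
            if runs and runs[-1].chrom == iv.chrom and iv.start - runs[-1].end < merge_gap:
                runs[-1] = GenomicInterval(iv.chrom, runs[-1].start, iv.end)
            else:
                runs.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    peaks = [p for p in runs if len(p) >= min_width]
    logger.info("call_peaks: threshold=%g min_width=%d merge_gap=%d -> %d peaks",
                threshold, min_width, merge_gap, len(peaks))
    return peaks


def scan_candidates(
    windows: list[GenomicInterval],
    repeats: list[GenomicInterval],
    h3k27ac_peaks: list[GenomicInterval],
    h3k27ac_track: SignalTrack,
    h3k27me3_track: SignalTrack,
    centromeres: list[GenomicInterval],
    config: PipelineConfig | None = None,
) -> list[CandidateLocus]:
    """Intersect peaks, repeats and pericentromeric windows into candidates.

    Each candidate is clipped to peak ∩ repeat ∩ window. Competence requires
    the maximum H3K27me3 over the candidate to reach its threshold as well.
    Candidates are sorted by h3k27ac_max descending.
    """
    config = config or PipelineConfig()
    qualifying = intersect(intersect(h3k27ac_peaks, repeats), windows)
    cen_by_chrom: dict[str, list[GenomicInterval]] = {}
    for cen in centromeres:
        cen_by_chrom.setdefault(cen.chrom, []).append(cen)

    candidates: list[CandidateLocus] = []
    for iv in qualifying:
        cens = cen_by_chrom.get(iv.chrom, [])
        distance = min((iv.distance_to(c) for c in cens), default=0)
        ac_max = h3k27ac_track.max_over(iv)
        me3_max = h3k27me3_track.max_over(iv)
        candidates.append(
            CandidateLocus(
                interval=iv,
                distance_to_centromere=distance,
                h3k27ac_max=ac_max,
                h3k27me3_max=me3_max,
                in_repeat=True,
                competent=(ac_max >= config.h3k27ac_threshold
                           and me3_max >= config.h3k27me3_threshold),
            )
        )
    candidates.sort(key=lambda c: (-c.h3k27ac_max, c.interval.chrom, c.interval.start))
    logger.info("scan_candidates: %d windows, %d peaks -> %d candidates",
                len(windows), len(h3k27ac_peaks), len(candidates))
    return candidates


def candidate_search_region(
    candidate: CandidateLocus,
    chrom_sizes: dict[str, int],
    padding: int = 1_000,
) -> GenomicInterval:
    """Candidate interval padded for ORF search, so peak edges do not truncate ORFs."""
    iv = candidate.interval
    return GenomicInterval(
        iv.chrom,
        max(0, iv.start - padding),
        min(chrom_sizes[iv.chrom], iv.end + padding),
    )
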