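"""Transcript-to-genome alignment, intronless determination, and codon-level
mutation calling with truncation-consequence reporting.

A transcript is intronless when its global alignment to the genomic
reference shows no genome-side gap at or above the intron threshold; smaller
gaps are treated as ordinary indels. Substitutions inside the reference ORF
are grouped per codon and named refAA + codon index + altAA ("F42V"),
with "(silent)" appended for synonymous changes and "Stop" for stop-gains
("G132Stop"). Codon 1 is the initiator Met.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align
from Bio.Seq import Seq

from .config import PipelineConfig
from .core_io import GenomicInterval, SequenceRecord
from .family_homology import MotifHit, alignment_identity
from .orf_annotation import STOP_CODONS, OpenReadingFrame

logger = logging.getLogger("gps_periscan")


class AlignmentError(ValueError):
    """No confident transcript-to-genome alignment."""


class FrameshiftError(ValueError):
    """An indel inside the ORF; outside the substitution nomenclature."""


@dataclass
class TranscriptAlignment:
    transcript_id: str
    reference_id: str
    aligned_transcript: str  # gapped
    aligned_reference: str  # gapped
    gaps_in_genome: list[GenomicInterval] = field(default_factory=list)
    identity_pct: float = 0.0

    @property
    def intronless(self) -> bool:
        return not self.gaps_in_genome


@dataclass(frozen=True)
class MutationCall:
    gene: str
    codon_index: int  # 1-based, initiator Met = 1
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str  # '*' for stop

    def __post_init__(self) -> None:
        if self.ref_codon == self.alt_codon:
            raise ValueError("ref and alt codons identical")

    @property
    def mclass(self) -> str:
        if self.alt_aa == "*":
            return "stop-gain"
        if self.ref_aa == self.alt_aa:
            return "silent"
        return "missense"

    @property
    def name(self) -> str:
        if self.mclass == "stop-gain":
            return f"{self.ref_aa}{self.codon_index}Stop"
        if self.mclass == "silent":
            return f"{self.ref_aa}{self.codon_index}{self.alt_aa} (silent)"
        return f"{self.ref_aa}{self.codon_index}{self.alt_aa}"

    @property
    def key(self) -> tuple[int, str]:
        """Two calls are identical iff codon index and alt codon match."""
        return (self.codon_index, self.alt_codon)


@dataclass
class MutationComparison:
    shared: list[MutationCall]
    unique_per_sample: dict[str, list[MutationCall]]


def align_transcript(
    transcript: SequenceRecord,
    genome_region: SequenceRecord,
    config: PipelineConfig | None = None,
) -> TranscriptAlignment:
    """Global transcript-to-genome alignment with free genomic end gaps.

    Genome-side gaps (transcript deletions) of at least ``intron_min_gap``
    bases are recorded as candidate introns in genome-region coordinates.
    Identity below ``alignment_identity_floor`` raises AlignmentError.
    """
    if transcript.mode != "nucleotide" or genome_region.mode != "nucleotide":
        raise ValueError("both sequences must be nucleotide mode")
    config = config or PipelineConfig()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = config.nt_match
    aligner.mismatch_score = config.nt_mismatch
    aligner.open_gap_score = config.nt_gap_open
    aligner.extend_gap_score = config.nt_gap_extend
    aligner.end_deletion_score = 0.0  # transcript may land anywhere in the region

    alignment = aligner.align(genome_region.sequence, transcript.sequence)[0]
    aligned_ref, aligned_tx = str(alignment[0]), str(alignment[1])

    identity = alignment_identity(aligned_ref, aligned_tx)
    if identity < config.alignment_identity_floor:
        raise AlignmentError(
            f"{transcript.identifier} vs {genome_region.identifier}: identity "
            f"{identity:.1f}% below floor {config.alignment_identity_floor}%"
        )

    # candidate introns: runs of '-' in the transcript row against reference bases,
    # excluding the terminal overhang of the genomic region
    n = len(aligned_ref)
    tx_core_lo = n - len(aligned_tx.lstrip("-"))
    tx_core_hi = len(aligned_tx.rstrip("-"))
    gaps: list[GenomicInterval] = []
    ref_pos = 0
    run_start: int | None = None
    for col in range(n):
        in_core = tx_core_lo <= col < tx_core_hi
        if aligned_tx[col] == "-" and aligned_ref[col] != "-" and in_core:
            if run_start is None:
                run_start = ref_pos
        else:
            if run_start is not None and ref_pos - run_start >= config.intron_min_gap:
                gaps.append(GenomicInterval(genome_region.identifier, run_start, ref_pos))
            run_start = None
        if aligned_ref[col] != "-":
            ref_pos += 1
    if run_start is not None and ref_pos - run_start >= config.intron_min_gap:
        gaps.append(GenomicInterval(genome_region.identifier, run_start, ref_pos))

    result = TranscriptAlignment(
        transcript_id=transcript.identifier,
        reference_id=genome_region.identifier,
        aligned_transcript=aligned_tx,
        aligned_reference=aligned_ref,
        gaps_in_genome=gaps,
        identity_pct=identity,
    )
    logger.info(
        "align_transcript: %s vs %s identity=%.1f%% introns=%d",
        transcript.identifier, genome_region.identifier, identity, len(gaps),
    )
    return result


def _codon_aa(codon: str) -> str:
    return "*" if codon in STOP_CODONS else str(Seq(codon).translate(table=1))


def call_mutations(
    alignment: TranscriptAlignment,
    reference_orf: OpenReadingFrame,
    orf_offset: int,
    gene: str | None = None,
) -> list[MutationCall]:
    """Codon-level substitution calls over the ORF span of an alignment.

    ``orf_offset`` is the 0-based position of the ORF's first base within the
    aligned genome region (sense strand). Any indel inside the ORF raises
    FrameshiftError; multiple substitutions in one codon collapse into a
    single codon-level call. Initiator-codon substitutions are named from the
    Met convention (codon 1 reference amino acid is M).
    """
    if alignment.gaps_in_genome:
        raise ValueError("mutation calling requires an intronless alignment over the ORF")
    gene = gene or reference_orf.protein.identifier
    orf_len = reference_orf.nt_length
    ref_row, tx_row = alignment.aligned_reference, alignment.aligned_transcript

    ref_codons: dict[int, list[str]] = {}
    alt_codons: dict[int, list[str]] = {}
    ref_pos = 0  # index of the current reference base when ref_row[col] != '-'
    for col in range(len(ref_row)):
        r, t = ref_row[col], tx_row[col]
        within = orf_offset <= ref_pos < orf_offset + orf_len
        if r == "-":
            if orf_offset < ref_pos < orf_offset + orf_len:  # insertion inside the ORF
                raise FrameshiftError(
                    f"{alignment.transcript_id}: insertion before reference position {ref_pos} inside ORF"
                )
            continue
        if within:
            if t == "-":  # deleted or uncovered ORF base
                raise FrameshiftError(
                    f"{alignment.transcript_id}: deletion/uncovered base at reference position {ref_pos} inside ORF"
                )
            idx = (ref_pos - orf_offset) // 3  # 0-based codon
            ref_codons.setdefault(idx, []).append(r)
            alt_codons.setdefault(idx, []).append(t)
        ref_pos += 1

    calls: list[MutationCall] = []
    protein = reference_orf.protein.sequence
    for idx in sorted(ref_codons):
        ref_c = "".join(ref_codons[idx])
        alt_c = "".join(alt_codons[idx])
        if len(ref_c) != 3 or len(alt_c) != 3 or ref_c == alt_c:
            continue
        # reference amino acid uses the annotated protein (initiator-Met convention)
        ref_aa = protein[idx] if idx < len(protein) else _codon_aa(ref_c)
        alt_aa = _codon_aa(alt_c)
        calls.append(MutationCall(gene, idx + 1, ref_c, alt_c, ref_aa, alt_aa))
    logger.info("call_mutations: %s on %s -> %d calls",
                alignment.transcript_id, gene, len(calls))
    return calls


def truncation_consequence(
    calls: list[MutationCall],
    motif_hits: list[MotifHit],
) -> list[tuple[MotifHit, bool]]:
    """Flag motif hits lost by the earliest stop-gain truncation.

    Returns (hit, lost) pairs: a hit starting at or after the earliest
    stop-gain codon is absent from the truncated translation product.
    """
    stop_codons = [c.codon_index for c in calls if c.mclass == "stop-gain"]
    if not stop_codons:
        return [(hit, False) for hit in motif_hits]
    earliest = min(stop_codons)
    return [(hit, hit.start >= earliest) for hit in motif_hits]


def compare_samples(per_sample: dict[str, list[MutationCall]]) -> MutationComparison:
    """Partition per-sample mutation catalogues into shared and unique calls.

    A call is shared when its (codon_index, alt_codon) key occurs in every
    sample. All samples must cover the same gene.
    """
    if len(per_sample) < 2:
        raise ValueError("need at least 2 samples")
    genes = {call.gene for calls in per_sample.values() for call in calls}
    if len(genes) > 1:
        raise ValueError(f"samples cover different genes: {sorted(genes)}")
    key_sets = {sample: {c.key for c in calls} for sample, calls in per_sample.items()}
    shared_keys = set.intersection(*key_sets.values())
    first_sample = next(iter(per_sample))
    shared = sorted(
        (c for c in per_sample[first_sample] if c.key in shared_keys),
        key=lambda c: c.codon_index,
    )
    unique = {
        sample: sorted((c for c in calls if c.key not in shared_keys), key=lambda c: c.codon_index)
        for sample, calls in per_sample.items()
    }
    return MutationComparison(shared=shared, unique_per_sample=unique)
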