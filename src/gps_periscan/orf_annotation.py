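"""Six-frame ORF discovery and protein-level annotation.

An ORF is a start-to-stop reading segment (stop codon included in the
nucleotide length), so a reported ORF always satisfies
``nt_length == 3 * (protein_length + 1)`` — the relation behind the
624 nt ↔ 207 aa and 792 nt ↔ 263 aa pairs for the two most expressed
family members. Within each stop-delimited segment the longest ORF is
reported: the most upstream qualifying start codon wins, mirroring the
"maximum ORF length" convention of six-frame ORF finders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq

from .config import PipelineConfig
from .core_io import GenomicInterval, SequenceRecord, reverse_complement

logger = logging.getLogger("gps_periscan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# EMBOSS pKa values for ionizable groups (Henderson-Hasselbalch charge model).
EMBOSS_PKA = {
    "N_term": 8.6,
    "C_term": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}
_POSITIVE_GROUPS = ("N_term", "H", "K", "R")
_NEGATIVE_GROUPS = ("C_term", "C", "D", "E", "Y")

# Average exact residue masses (Da), for the auxiliary exact-mass column.
_AVG_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER_MASS = 18.0153

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class OpenReadingFrame:
    """A start-to-stop ORF located on a genomic (or candidate) sequence."""

    locus: GenomicInterval  # start codon first base .. stop codon last base
    strand: str
    frame: int  # 0-2 relative to the locus start on its strand
    nt_length: int
    start_codon: str
    protein: SequenceRecord  # stop excluded

    def __post_init__(self) -> None:
        if self.nt_length != 3 * (len(self.protein) + 1):
            raise ValueError(
                f"nt_length {self.nt_length} != 3*(protein {len(self.protein)} + 1)"
            )
        if self.nt_length != len(self.locus):
            raise ValueError("locus length disagrees with nt_length")


@dataclass(frozen=True)
class ProteinAnnotation:
    length_aa: int
    approx_mw_kda: float  # 110 Da per residue rule
    exact_mw_kda: float  # average-mass sum, auxiliary
    pI: float
    composition: dict[str, float]
    enriched_residues: list[tuple[str, float]]  # (residue, ratio), ratio descending


def translate(orf_seq: str, start_codons: tuple[str, ...] = ("ATG",)) -> str:
    """Translate a start-to-stop ORF with the standard code, stop excluded.

    Alternative initiation codons are translated as Met at position 1
    (initiator-tRNA convention). An internal stop raises with its codon index.
    """
    orf_seq = orf_seq.upper()
    if len(orf_seq) % 3:
        raise ValueError(f"ORF length {len(orf_seq)} is not a multiple of 3")
    if orf_seq[-3:] not in STOP_CODONS:
        raise ValueError(f"ORF does not end in a stop codon ({orf_seq[-3:]})")
    protein = str(Seq(orf_seq[:-3]).translate(table=1))
    if "*" in protein:
        raise ValueError(f"internal stop at codon {protein.index('*') + 1}")
    if orf_seq[:3] in start_codons:
        protein = "M" + protein[1:]
    return protein


def find_orfs(record: SequenceRecord, config: PipelineConfig | None = None) -> list[OpenReadingFrame]:
    """Six-frame ORF scan of a nucleotide sequence.

    Within each stop-bounded segment of a reading frame the most upstream
    qualifying start codon defines the single reported ORF. ORFs containing N
    or shorter than ``min_orf_length`` (stop included) are dropped. Results
    are sorted by nt_length descending, then leftmost genomic start, then
    strand (+ before -).
    """
    config = config or PipelineConfig()
    if record.mode != "nucleotide":
        raise ValueError("find_orfs requires a nucleotide sequence")
    seq = record.sequence
    n = len(seq)
    starts = set(config.start_codons)
    orfs: list[OpenReadingFrame] = []

    for strand in ("+", "-"):
        s = seq if strand == "+" else reverse_complement(seq)
        for frame in range(3):
            segment_start_idx: int | None = None  # index of first start codon in segment
            i = frame
            while i + 3 <= n:
                codon = s[i : i + 3]
                if codon in STOP_CODONS:
                    if segment_start_idx is not None:
                        orf = _build_orf(record, s, segment_start_idx, i + 3, strand, frame, config)
                        if orf is not None:
                            orfs.append(orf)
                    segment_start_idx = None
                elif segment_start_idx is None and codon in starts and "N" not in codon:
                    segment_start_idx = i
                i += 3

    orfs.sort(key=lambda o: (-o.nt_length, o.locus.start, 0 if o.strand == "+" else 1))
    logger.info("find_orfs: %s (%d nt) -> %d ORFs >= %d nt",
                record.identifier, n, len(orfs), config.min_orf_length)
    return orfs


def _build_orf(
    record: SequenceRecord,
    stranded_seq: str,
    start: int,
    end: int,
    strand: str,
    frame: int,
    config: PipelineConfig,
) -> OpenReadingFrame | None:
    nt = stranded_seq[start:end]
    if len(nt) < config.min_orf_length or "N" in nt:
        return None
    protein = translate(nt, config.start_codons)
    n = len(record.sequence)
    if strand == "+":
        g_start, g_end = start, end
    else:  # mirror stranded coordinates back onto the forward sequence
        g_start, g_end = n - end, n - start
    return OpenReadingFrame(
        locus=GenomicInterval(record.identifier, g_start, g_end, strand),
        strand=strand,
        frame=frame,
        nt_length=len(nt),
        start_codon=nt[:3],
        protein=SequenceRecord(f"{record.identifier}_orf_{g_start}_{strand}", protein, "protein"),
    )


def orf_nucleotide_sequence(orf: OpenReadingFrame, genome_seq: str) -> str:
    """Sense-strand nucleotide sequence of an ORF given its host sequence."""
    sub = genome_seq[orf.locus.start : orf.locus.end]
    return sub if orf.strand == "+" else reverse_complement(sub)


def approx_molecular_weight(length_aa: int) -> float:
    """Approximate protein mass in kDa at 110 Da per residue, 2 decimals."""
    if length_aa < 0:
        raise ValueError("length_aa must be non-negative")
    return round(110 * length_aa / 1000, 2)


def exact_molecular_weight(protein: str) -> float:
    """Average-mass protein weight in kDa (auxiliary to the 110-Da rule)."""
    return round((sum(_AVG_RESIDUE_MASS[aa] for aa in protein) + _WATER_MASS) / 1000, 3)


def net_charge(composition_counts: dict[str, int], ph: float, pka: dict[str, float]) -> float:
    """Henderson-Hasselbalch net charge of a protein at a given pH."""
    charge = 0.0
    for group in _POSITIVE_GROUPS:
        count = 1 if group == "N_term" else composition_counts.get(group, 0)
        charge += count / (1 + 10 ** (ph - pka[group]))
    for group in _NEGATIVE_GROUPS:
        count = 1 if group == "C_term" else composition_counts.get(group, 0)
        charge -= count / (1 + 10 ** (pka[group] - ph))
    return charge


def isoelectric_point(protein: SequenceRecord | str, pka: dict[str, float] | None = None) -> float:
    """pI by bisection on [0, 14] to 0.01 pH: the root of the net-charge curve.

    Depends only on residue composition; net charge is strictly decreasing in
    pH so the root is unique.
    """
    seq = protein.sequence if isinstance(protein, SequenceRecord) else protein
    if not seq:
        raise ValueError("empty protein")
    pka = pka or EMBOSS_PKA
    counts = {aa: seq.count(aa) for aa in "CDEHKRY"}
    lo, hi = 0.0, 14.0
    while hi - lo > 0.01:
        mid = (lo + hi) / 2
        if net_charge(counts, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return round((lo + hi) / 2, 3)


def residue_enrichment(
    protein: SequenceRecord | str,
    background: dict[str, float] | None = None,
    cutoff: float = 1.5,
) -> tuple[dict[str, float], list[tuple[str, float]]]:
    """Per-residue composition and residues enriched over a background.

    Background defaults to uniform (0.05 per residue). Returns the fraction
    table (summing to 1) and the enriched list [(residue, ratio)] with ratio
    >= cutoff, sorted by ratio descending then residue.
    """
    seq = protein.sequence if isinstance(protein, SequenceRecord) else protein
    if not seq:
        raise ValueError("empty protein")
    background = background or {aa: 1 / 20 for aa in AMINO_ACIDS}
    total = sum(background.values())
    if abs(total - 1) > 1e-9:
        raise ValueError(f"background frequencies sum to {total}, not 1")
    composition = {aa: seq.count(aa) / len(seq) for aa in AMINO_ACIDS}
    enriched = [
        (aa, composition[aa] / background[aa])
        for aa in AMINO_ACIDS
        if background[aa] > 0 and composition[aa] / background[aa] >= cutoff
    ]
    enriched.sort(key=lambda pair: (-pair[1], pair[0]))
    return composition, enriched


def annotate_protein(
    protein: SequenceRecord,
    background: dict[str, float] | None = None,
    cutoff: float = 1.5,
    pka: dict[str, float] | None = None,
) -> ProteinAnnotation:
    """Full protein annotation: length, approximate and exact MW, pI, enrichment."""
    composition, enriched = residue_enrichment(protein, background, cutoff)
    return ProteinAnnotation(
        length_aa=len(protein),
        approx_mw_kda=approx_molecular_weight(len(protein)),
        exact_mw_kda=exact_molecular_weight(protein.sequence),
        pI=isoelectric_point(protein, pka),
        composition=composition,
        enriched_residues=enriched,
    )
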