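"""Synthetic multi-chromosome genome, signal tracks, transcripts, coverage and
expression matrices with a recorded truth ledger.

The generator emulates the study substrate: each toy chromosome carries a
central centromere flanked by satellite-like repeat blocks built from tandem
copies of a monomer selected to contain stop codons in all six frames (as
real higher-order satellite arrays do), so the ORFs planted inside the
repeats are the only long reading frames there. Planted pericentromeric ORFs
receive H3K27ac and H3K27me3 peaks; a decoy ORF outside the pericentromeric
flank receives none. Transcript copies carry planted silent, missense and
stop-gain mutations (shared and sample-unique), one decoy gene is spliced,
and a 100-cell-line expression matrix embeds a C19MC-high/GPS-high block, a
double-zero block, and background genes with planted log2 fold changes.

Every expectation a downstream test needs is recorded in the
:class:`TruthLedger`, never re-derived from the generated data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .core_io import (
    GenomicInterval,
    SequenceRecord,
    SignalTrack,
    reverse_complement,
    write_bed,
    write_bedgraph,
    write_fasta,
)
from .orf_annotation import STOP_CODONS

logger = logging.getLogger("gps_periscan")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# codon table for building nucleotide sequences from fixed proteins
_CODONS_FOR_AA: dict[str, list[str]] = {}
for _c in ("".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT"):
    if _c in STOP_CODONS:
        continue
    from Bio.Seq import Seq as _Seq

    _CODONS_FOR_AA.setdefault(str(_Seq(_c).translate(table=1)), []).append(_c)

CONSERVED_MOTIF = "NQSFPFPTDKWLR"  # 13-mer carrying the FPFP motif at offset 3


@dataclass(frozen=True)
class PlantedMutation:
    gene: str
    sample: str
    codon_index: int  # 1-based
    ref_codon: str
    alt_codon: str
    expected_name: str
    expected_class: str
    shared: bool


@dataclass
class PlantedOrf:
    gene: str
    chrom: str
    start: int
    end: int
    strand: str
    nt_length: int
    orf_seq: str  # sense strand, start..stop
    protein: str
    pericentromeric: bool
    motif_start: int | None  # 1-based protein position of the conserved 13-mer

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass
class TruthLedger:
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    centromeres: list[dict] = field(default_factory=list)
    repeats: list[dict] = field(default_factory=list)
    planted_orfs: list[PlantedOrf] = field(default_factory=list)
    planted_peaks: list[dict] = field(default_factory=list)
    planted_mutations: list[PlantedMutation] = field(default_factory=list)
    planted_intron: dict | None = None
    spliced_gene: dict | None = None
    expression: dict = field(default_factory=dict)

    def pericentromeric_orfs(self) -> list[PlantedOrf]:
        return [o for o in self.planted_orfs if o.pericentromeric]

    def decoy_orfs(self) -> list[PlantedOrf]:
        return [o for o in self.planted_orfs if not o.pericentromeric]

    def orf(self, gene: str) -> PlantedOrf:
        for o in self.planted_orfs:
            if o.gene == gene:
                return o
        raise KeyError(gene)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1,
                      default=lambda o: o.item() if hasattr(o, "item") else str(o))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        with open(path) as fh:
            payload = json.load(fh)
        payload["planted_orfs"] = [PlantedOrf(**o) for o in payload["planted_orfs"]]
        payload["planted_mutations"] = [PlantedMutation(**m) for m in payload["planted_mutations"]]
        return cls(**payload)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _max_stop_free_run(seq: str) -> int:
    """Longest stop-free codon run (nt) over all 6 frames of a sequence."""
    best = 0
    for s in (seq, reverse_complement(seq)):
        for frame in range(3):
            run = 0
            for i in range(frame, len(s) - 2, 3):
                if s[i : i + 3] in STOP_CODONS:
                    run = 0
                else:
                    run += 3
                    best = max(best, run)
    return best


def _longest_run(seq: str) -> tuple[int, int, str]:
    """(length, forward position of a mid-run codon) of the longest stop-free run.

    Both strands and all three frames of each are scanned; the returned
    position is forward-strand and marks the first base of a codon sitting
    near the middle of the run on its own strand.
    """
    n = len(seq)
    best_len, best_pos, best_strand = 0, 0, "+"
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            run_start = frame
            for i in range(frame, n - 2 + 1, 3):
                is_stop = s[i : i + 3] in STOP_CODONS
                end_of_seq = i + 3 > n - 3
                if is_stop or end_of_seq:
                    run_len = i - run_start
                    if run_len > best_len:
                        mid = run_start + 3 * ((run_len // 3) // 2)
                        fwd = mid if strand == "+" else n - mid - 3
                        best_len, best_pos, best_strand = run_len, fwd, strand
                    run_start = i + 3
    return best_len, best_pos, best_strand


# (TTAA)x3 is its own reverse complement and carries TAA in all three frames
# of both strands, so planting it guarantees nearby stops in all six frames.
_ALL_FRAME_STOP = "TTAA" * 3


def _satellite_monomer(rng: np.random.Generator, length: int = 171, max_run: int = 120) -> str:
    """A monomer whose tandem array is stop-dense in all six frames.

    An all-frame stop cassette is planted at two phases of the monomer so that
    no stop-free codon run in a tandem array can reach ``max_run`` nt.
    """
    monomer = list(_random_bases(rng, length))
    step = (length // 2) + 1  # two cassettes per monomer, out of phase
    for at in (0, step):
        monomer[at : at + len(_ALL_FRAME_STOP)] = _ALL_FRAME_STOP
    seq = "".join(monomer)
    run_len, _, _ = _longest_run(seq * 3)
    if run_len >= max_run:
        raise RuntimeError("satellite monomer construction failed")
    return seq


def _repeat_fill(rng: np.random.Generator, monomer: str, n: int, mutation_rate: float = 0.01) -> str:
    reps = (n // len(monomer)) + 1
    arr = np.frombuffer((monomer * reps)[:n].encode(), dtype=np.uint8).copy()
    hits = rng.random(n) < mutation_rate
    arr[hits] = _BASES[rng.integers(0, 4, size=int(hits.sum()))]
    return arr.tobytes().decode()


def _protein_to_nt(rng: np.random.Generator, protein: str, forced_codons: dict[int, str] | None = None) -> str:
    """Random synonymous codons for a protein plus a random stop codon.

    ``forced_codons`` maps 1-based codon indices to required reference codons.
    """
    forced_codons = forced_codons or {}
    codons = []
    for i, aa in enumerate(protein, start=1):
        if i in forced_codons:
            codons.append(forced_codons[i])
        else:
            options = _CODONS_FOR_AA[aa]
            codons.append(options[rng.integers(0, len(options))])
    codons.append(("TAA", "TAG", "TGA")[rng.integers(0, 3)])
    return "".join(codons)


def _random_protein(rng: np.random.Generator, length: int, sty_rich: bool = False) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    if sty_rich:
        weights = np.array([3.0 if aa in "STY" else 1.0 for aa in aas])
    else:
        weights = np.ones(len(aas))
    weights = weights / weights.sum()
    idx = rng.choice(len(aas), size=length, p=weights)
    prot = list(aas[i] for i in idx)
    prot[0] = "M"
    return "".join(prot)


def _plant(chrom_arr: np.ndarray, pos: int, insert: str) -> None:
    chrom_arr[pos : pos + len(insert)] = np.frombuffer(insert.encode(), dtype=np.uint8)


# default mutation plan for the longest planted gene: the shared catalogue
# carries a missense, a silent and the G132Stop truncation; each sample adds
# one unique call.
DEFAULT_MUTATION_PLAN = {
    "samples": ("mcf7", "hep3b"),
    "shared": [
        (42, "F", "TTT", "GTT", "V", "missense"),
        (129, "P", "CCA", "CCG", "P", "silent"),
        (132, "G", "GGA", "TGA", "*", "stop-gain"),
    ],
    "unique": {
        "mcf7": [(153, "N", "AAT", "AAA", "K", "missense")],
        "hep3b": [(13, "F", "TTT", "GTT", "V", "missense")],
    },
}


def _mutation_name(ref_aa: str, index: int, alt_aa: str, mclass: str) -> str:
    if mclass == "stop-gain":
        return f"{ref_aa}{index}Stop"
    if mclass == "silent":
        return f"{ref_aa}{index}{alt_aa} (silent)"
    return f"{ref_aa}{index}{alt_aa}"


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_genome(
    config: PipelineConfig | None = None, seed: int = 0
) -> tuple[dict[str, str], list[GenomicInterval], list[GenomicInterval], TruthLedger]:
    """Toy genome with centromeres, repeat flanks and planted ORFs.

    Returns (chromosome sequences, centromere intervals, repeat intervals,
    ledger). Each planted pericentromeric ORF sits inside a repeat block
    within the configured flank of its centromere, guarded by an upstream
    in-frame stop so its coordinates are exactly recoverable; one decoy ORF
    and one spliced decoy gene are placed outside the flank.
    """
    config = config or PipelineConfig()
    if config.n_chromosomes < 2:
        raise ValueError("need at least 2 chromosomes")
    if config.chromosome_length < 200_000:
        raise ValueError("chromosome_length must be at least 200 kb")
    if not config.orf_lengths:
        raise ValueError("need at least one planted ORF")
    for L in config.orf_lengths:
        if L % 3 or L < config.min_orf_length:
            raise ValueError(f"planted ORF length {L} invalid (multiple of 3, >= min length)")

    rng = np.random.default_rng([1, seed])
    ledger = TruthLedger()
    clen = config.chromosome_length
    cen_start = (clen - config.centromere_length) // 2
    cen_end = cen_start + config.centromere_length
    rep_left = GenomicInterval("x", max(0, cen_start - config.repeat_flank_length), cen_start)
    monomer = _satellite_monomer(rng)

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome: dict[str, np.ndarray] = {}
    centromeres: list[GenomicInterval] = []
    repeats: list[GenomicInterval] = []
    for chrom in chrom_names:
        arr = np.frombuffer(_random_bases(rng, clen).encode(), dtype=np.uint8).copy()
        left = (max(0, cen_start - config.repeat_flank_length), cen_start)
        right = (cen_end, min(clen, cen_end + config.repeat_flank_length))
        _plant(arr, left[0], _repeat_fill(rng, monomer, left[1] - left[0]))
        _plant(arr, right[0], _repeat_fill(rng, monomer, right[1] - right[0]))
        genome[chrom] = arr
        centromeres.append(GenomicInterval(chrom, cen_start, cen_end))
        repeats.append(GenomicInterval(chrom, *left))
        repeats.append(GenomicInterval(chrom, *right))
        ledger.chrom_sizes[chrom] = clen
        ledger.centromeres.append({"chrom": chrom, "start": cen_start, "end": cen_end})
    ledger.repeats = [{"chrom": r.chrom, "start": r.start, "end": r.end} for r in repeats]

    # slots alternate (chromosome, side); ORFs are centered in their half-block
    slots = [(chrom, side) for chrom in chrom_names for side in ("L", "R")]
    if len(config.orf_lengths) > len(slots):
        raise ValueError("more planted ORFs than available repeat slots")
    margin = config.peak_padding + config.candidate_padding + 200
    # interleave so consecutive ORFs land on different chromosomes
    slots = sorted(slots, key=lambda s: (s[1], s[0]))

    gene_counts: dict[str, int] = {}
    mutated_idx = int(np.argmax(config.orf_lengths))
    for idx, orf_len in enumerate(config.orf_lengths):
        chrom, side = slots[idx]
        block = (
            (max(0, cen_start - config.repeat_flank_length), cen_start)
            if side == "L"
            else (cen_end, min(clen, cen_end + config.repeat_flank_length))
        )
        if orf_len + 3 + 2 * margin > block[1] - block[0]:
            raise ValueError(f"planted ORF of {orf_len} nt does not fit its host repeat block")
        gene_counts[chrom] = gene_counts.get(chrom, 0) + 1
        gene = f"C{chrom[3:]}GPS" + ("" if gene_counts[chrom] == 1 else str(gene_counts[chrom]))

        protein_len = orf_len // 3 - 1
        forced: dict[int, str] = {}
        if idx == mutated_idx:
            plan = DEFAULT_MUTATION_PLAN
            for entries in [plan["shared"], *plan["unique"].values()]:
                for (ci, ref_aa, ref_codon, *_rest) in entries:
                    if ci > protein_len:
                        raise ValueError(
                            f"planted mutation at codon {ci} beyond protein length {protein_len}"
                        )
                    forced[ci] = ref_codon
        protein = list(_random_protein(rng, protein_len, sty_rich=(idx == 0)))
        for ci, codon in forced.items():
            protein[ci - 1] = str(_Seq(codon).translate(table=1))
        motif_start = None
        if protein_len >= len(CONSERVED_MOTIF) + 20:
            # keep the motif downstream of any planted truncation and clear of forced codons
            motif_start = max(160, protein_len - len(CONSERVED_MOTIF) - 5) if idx == mutated_idx else protein_len // 2
            motif_start = min(motif_start, protein_len - len(CONSERVED_MOTIF) + 1)
            protein[motif_start - 1 : motif_start - 1 + len(CONSERVED_MOTIF)] = CONSERVED_MOTIF
        protein_str = "".join(protein)
        nt = _protein_to_nt(rng, protein_str, forced)

        strand = "+" if idx % 2 == 0 else "-"
        center = (block[0] + block[1]) // 2
        pos = center - (orf_len + 3) // 2
        insert = "TAA" + nt if strand == "+" else reverse_complement("TAA" + nt)
        _plant(genome[chrom], pos, insert)
        orf_start = pos + 3 if strand == "+" else pos
        ledger.planted_orfs.append(
            PlantedOrf(
                gene=gene,
                chrom=chrom,
                start=orf_start,
                end=orf_start + orf_len,
                strand=strand,
                nt_length=orf_len,
                orf_seq=nt,
                protein=protein_str,
                pericentromeric=True,
                motif_start=motif_start,
            )
        )

    # decoy ORF far from any centromere, in plain background, no peak
    decoy_len = config.decoy_orf_length
    decoy_protein = _random_protein(rng, decoy_len // 3 - 1)
    decoy_nt = _protein_to_nt(rng, decoy_protein)
    decoy_pos = 20_000
    _plant(genome["chr2"], decoy_pos, "TAA" + decoy_nt)
    ledger.planted_orfs.append(
        PlantedOrf(
            gene="DECOY",
            chrom="chr2",
            start=decoy_pos + 3,
            end=decoy_pos + 3 + decoy_len,
            strand="+",
            nt_length=decoy_len,
            orf_seq=decoy_nt,
            protein=decoy_protein,
            pericentromeric=False,
            motif_start=None,
        )
    )

    # spliced decoy gene: ORF split by an intron in the genomic source
    e1, e2 = config.spliced_exon_lengths
    sp_len = e1 + e2
    sp_protein = _random_protein(rng, sp_len // 3 - 1)
    sp_nt = _protein_to_nt(rng, sp_protein)
    intron = "GT" + _random_bases(rng, config.spliced_intron_length - 4) + "AG"
    # unique intron placement: exon boundary bases must differ from intron ends
    split = e1
    while sp_nt[split - 1] == intron[-1] or sp_nt[split] == intron[0]:
        split += 1
    sp_chrom = chrom_names[-1]
    sp_pos = 20_000
    genomic_gene = "TAA" + sp_nt[:split] + intron + sp_nt[split:]
    _plant(genome[sp_chrom], sp_pos, genomic_gene)
    gene_start = sp_pos + 3
    intron_start = gene_start + split
    ledger.spliced_gene = {
        "gene": "SPLICED",
        "chrom": sp_chrom,
        "gene_start": gene_start,
        "gene_end": gene_start + sp_len + len(intron),
        "transcript_orf": sp_nt,
        "exon1_len": split,
    }
    ledger.planted_intron = {
        "gene": "SPLICED",
        "chrom": sp_chrom,
        "start": intron_start,
        "end": intron_start + len(intron),
    }

    genome_str = {chrom: arr.tobytes().decode() for chrom, arr in genome.items()}
    logger.info(
        "generate_genome: seed=%d, %d chromosomes x %d bp, %d pericentromeric ORFs, 1 decoy, 1 spliced",
        seed, config.n_chromosomes, clen, len(ledger.pericentromeric_orfs()),
    )
    return genome_str, centromeres, repeats, ledger


def generate_signal_tracks(
    ledger: TruthLedger, config: PipelineConfig | None = None, seed: int = 0
) -> tuple[SignalTrack, SignalTrack]:
    """H3K27ac and H3K27me3 fold-change tracks with peaks at planted ORFs.

    Both marks peak over every planted pericentromeric ORF (amplitude above
    threshold, width at least the ORF plus padding); background bins carry
    uniform noise strictly below half the calling threshold, or exact zero in
    noise-free mode. The decoy ORF receives no qualifying H3K27ac peak.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng([2, seed])
    ledger.planted_peaks = []
    tracks = []
    for mark, threshold in (("H3K27ac", config.h3k27ac_threshold), ("H3K27me3", config.h3k27me3_threshold)):
        records: list[tuple[GenomicInterval, float]] = []
        peak_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for orf in ledger.pericentromeric_orfs():
            lo = orf.start - config.peak_padding
            hi = orf.end + config.peak_padding
            peak_by_chrom.setdefault(orf.chrom, []).append((lo, hi))
            ledger.planted_peaks.append(
                {"chrom": orf.chrom, "start": lo, "end": hi, "mark": mark,
                 "amplitude": config.peak_amplitude, "gene": orf.gene}
            )
        for chrom, clen in ledger.chrom_sizes.items():
            peaks = sorted(peak_by_chrom.get(chrom, []))
            edges = sorted({0, clen, *[e for p in peaks for e in p],
                            *range(0, clen, config.noise_bin)})
            for lo, hi in zip(edges, edges[1:]):
                in_peak = any(p_lo <= lo and hi <= p_hi for p_lo, p_hi in peaks)
                if in_peak:
                    value = config.peak_amplitude
                elif config.noise_free:
                    value = 0.0
                else:
                    value = round(float(rng.uniform(0, 0.5 * threshold)), 3)
                records.append((GenomicInterval(chrom, lo, hi), value))
        tracks.append(SignalTrack(records))
    logger.info("generate_signal_tracks: seed=%d, %d planted peaks per mark",
                seed, len(ledger.pericentromeric_orfs()))
    return tracks[0], tracks[1]


def generate_transcripts(
    genome: dict[str, str],
    ledger: TruthLedger,
    config: PipelineConfig | None = None,
    seed: int = 0,
    mutation_plan: dict | None = None,
) -> list[SequenceRecord]:
    """Per-sample transcript copies of each planted gene, mutations applied.

    The longest planted gene carries the plan's shared and sample-unique
    mutations; all other transcripts are exact genomic copies. The spliced
    decoy contributes one transcript whose genomic source retains the intron.
    Transcripts carry ``transcript_flank`` nt of genomic context on each side.
    """
    config = config or PipelineConfig()
    plan = mutation_plan or DEFAULT_MUTATION_PLAN
    samples = plan["samples"]
    mutated_gene = max(ledger.pericentromeric_orfs(), key=lambda o: o.nt_length).gene
    transcripts: list[SequenceRecord] = []
    ledger.planted_mutations = []

    for orf in ledger.pericentromeric_orfs():
        chrom_seq = genome[orf.chrom]
        flank = config.transcript_flank
        if orf.strand == "+":
            up = chrom_seq[orf.start - flank : orf.start]
            down = chrom_seq[orf.end : orf.end + flank]
        else:
            up = reverse_complement(chrom_seq[orf.end : orf.end + flank])
            down = reverse_complement(chrom_seq[orf.start - flank : orf.start])
        for sample in samples:
            orf_nt = orf.orf_seq
            if orf.gene == mutated_gene:
                entries = list(plan["shared"]) + list(plan["unique"].get(sample, []))
                codons = [orf_nt[i : i + 3] for i in range(0, len(orf_nt), 3)]
                for (ci, ref_aa, ref_codon, alt_codon, alt_aa, mclass) in entries:
                    if ci > len(orf.protein):
                        raise ValueError(f"mutation at codon {ci} beyond protein length")
                    if codons[ci - 1] != ref_codon:
                        raise ValueError(f"reference codon mismatch at {ci}")
                    codons[ci - 1] = alt_codon
                    ledger.planted_mutations.append(
                        PlantedMutation(
                            gene=orf.gene,
                            sample=sample,
                            codon_index=ci,
                            ref_codon=ref_codon,
                            alt_codon=alt_codon,
                            expected_name=_mutation_name(ref_aa, ci, alt_aa, mclass),
                            expected_class=mclass,
                            shared=(ci, alt_codon) in {(e[0], e[3]) for e in plan["shared"]},
                        )
                    )
                orf_nt = "".join(codons)
            transcripts.append(SequenceRecord(f"{orf.gene}|{sample}", up + orf_nt + down))

    if ledger.spliced_gene is not None:
        sp = ledger.spliced_gene
        chrom_seq = genome[sp["chrom"]]
        flank = config.transcript_flank
        up = chrom_seq[sp["gene_start"] - flank : sp["gene_start"]]
        down = chrom_seq[sp["gene_end"] : sp["gene_end"] + flank]
        transcripts.append(SequenceRecord(f"{sp['gene']}|{samples[0]}", up + sp["transcript_orf"] + down))

    logger.info("generate_transcripts: seed=%d, %d transcripts, %d planted mutations",
                seed, len(transcripts), len(ledger.planted_mutations))
    return transcripts


def generate_coverage(
    ledger: TruthLedger,
    config: PipelineConfig | None = None,
    seed: int = 0,
    cell_lines: tuple[str, ...] = ("covA", "covB", "zero_line"),
) -> dict[str, SignalTrack]:
    """Per-cell-line read-depth tracks over planted gene ORFs.

    Each (gene, line) gets a piecewise-constant depth profile whose maximum
    single-base depth equals the ledger's recorded MRSP truth; the designated
    zero-expression line is flat 0 everywhere.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng([3, seed])
    truth: dict[str, dict[str, int]] = {}
    tracks: dict[str, SignalTrack] = {}
    for line in cell_lines:
        records: list[tuple[GenomicInterval, float]] = []
        truth[line] = {}
        for orf in ledger.pericentromeric_orfs():
            if line == "zero_line":
                truth[line][orf.gene] = 0
                continue
            peak = int(rng.integers(5, 51))
            truth[line][orf.gene] = peak
            pos = orf.start
            apex = int(rng.integers(orf.start, orf.end))
            while pos < orf.end:
                seg_end = min(orf.end, pos + int(rng.integers(10, 40)))
                if pos <= apex < seg_end:
                    if apex > pos:
                        records.append((GenomicInterval(orf.chrom, pos, apex),
                                        float(rng.integers(0, peak))))
                    records.append((GenomicInterval(orf.chrom, apex, apex + 1), float(peak)))
                    if apex + 1 < seg_end:
                        records.append((GenomicInterval(orf.chrom, apex + 1, seg_end),
                                        float(rng.integers(0, peak))))
                else:
                    records.append((GenomicInterval(orf.chrom, pos, seg_end),
                                    float(rng.integers(0, peak))))
                pos = seg_end
        tracks[line] = SignalTrack(records)
    ledger.expression["coverage_mrsp"] = truth
    logger.info("generate_coverage: seed=%d, %d lines x %d genes",
                seed, len(cell_lines), len(ledger.pericentromeric_orfs()))
    return tracks


C19MC_MEMBERS = ["MIR519D", "MIR520G", "MIR526B"]
_OTHER_MIRNAS = ["MIR100", "MIR200A"]

# planted log2 fold changes for background genes (positive vs negative group);
# the remainder of the background panel is null.
DEFAULT_EFFECTS = [4.0, 5.0, -4.0, -5.0, 1.5, -1.5]


def generate_expression_matrix(
    ledger: TruthLedger,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene (MRSP) and miRNA expression matrices over synthetic cell lines.

    Exactly ``n_per_group`` lines are double-positive (GPS score > 0 and the
    highest cumulative C19MC) and ``n_per_group`` are double-zero; remaining
    lines are single-positive for one axis only, so the grouping rule has a
    unique answer. Background genes carry the planted log2 fold changes
    between the two groups on a log2(x+1) scale with within-group sd
    ``background_sd``.
    """
    config = config or PipelineConfig()
    if config.n_cell_lines < 2 * config.n_per_group:
        raise ValueError("fewer than 2*n_per_group cell lines requested")
    rng = np.random.default_rng([4, seed])
    n = config.n_cell_lines
    lines = [f"L{i + 1:03d}" for i in range(n)]
    order = rng.permutation(n)
    npos = config.n_per_group
    positive = sorted(lines[i] for i in order[:npos])
    negative = sorted(lines[i] for i in order[npos : 2 * npos])
    rest = [lines[i] for i in order[2 * npos :]]
    gps_only = sorted(rest[: len(rest) // 2])
    mirna_only = sorted(rest[len(rest) // 2 :])

    gps_genes = [o.gene for o in ledger.pericentromeric_orfs()]
    top2 = [o.gene for o in sorted(ledger.pericentromeric_orfs(), key=lambda o: -o.nt_length)[:2]]
    gene_rows: dict[str, dict[str, float]] = {g: {} for g in gps_genes}
    for line in lines:
        active = line in positive or line in gps_only
        for g in gps_genes:
            if not active:
                gene_rows[g][line] = 0
            elif g in top2:
                gene_rows[g][line] = int(rng.integers(30, 81))
            else:
                gene_rows[g][line] = int(rng.integers(1, 20))

    # background genes with planted effects on the log2(x+1) scale
    effects = list(DEFAULT_EFFECTS) + [0.0] * max(0, config.n_background_genes - len(DEFAULT_EFFECTS))
    effects = effects[: config.n_background_genes]
    planted_effects: dict[str, float] = {}
    for i, effect in enumerate(effects):
        gene = f"BG{i + 1:03d}"
        planted_effects[gene] = effect
        mu = float(rng.uniform(6, 8))
        row = {}
        for line in lines:
            center = mu + effect if line in positive else mu
            v = rng.normal(center, config.background_sd)
            row[line] = max(0, int(round(2 ** v - 1)))
        gene_rows[gene] = row
    gene_matrix = pd.DataFrame(gene_rows).T[lines]

    mirna_rows: dict[str, dict[str, float]] = {}
    for m in C19MC_MEMBERS:
        row = {}
        for line in lines:
            if line in positive:
                row[line] = round(float(rng.uniform(30, 60)), 2)
            elif line in mirna_only:
                row[line] = round(float(rng.uniform(1, 9)), 2)
            else:
                row[line] = 0.0
        mirna_rows[m] = row
    for m in _OTHER_MIRNAS:
        mirna_rows[m] = {line: round(float(rng.uniform(0, 5)), 2) for line in lines}
    mirna_matrix = pd.DataFrame(mirna_rows).T[lines]

    cumulative = mirna_matrix.loc[C19MC_MEMBERS].sum(axis=0)
    ledger.expression.update(
        {
            "gene_matrix": {g: dict(gene_matrix.loc[g]) for g in gene_matrix.index},
            "mirna_matrix": {m: dict(mirna_matrix.loc[m]) for m in mirna_matrix.index},
            "gps_genes": gps_genes,
            "top2_combined": top2,
            "c19mc_members": list(C19MC_MEMBERS),
            "c19mc_cumulative": dict(cumulative),
            "positive_group": positive,
            "negative_group": negative,
            "planted_log2fc": planted_effects,
            "de_truth": [g for g, e in planted_effects.items() if abs(e) > config.log2fc_threshold],
        }
    )
    logger.info(
        "generate_expression_matrix: seed=%d, %d lines, %d GPS genes, %d background genes",
        seed, n, len(gps_genes), config.n_background_genes,
    )
    return gene_matrix, mirna_matrix


# ---------------------------------------------------------------------------
# one-call simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    genome: dict[str, str]
    centromeres: list[GenomicInterval]
    repeats: list[GenomicInterval]
    h3k27ac: SignalTrack
    h3k27me3: SignalTrack
    transcripts: list[SequenceRecord]
    coverage: dict[str, SignalTrack]
    gene_matrix: pd.DataFrame
    mirna_matrix: pd.DataFrame
    ledger: TruthLedger


def simulate(config: PipelineConfig | None = None, seed: int = 0) -> SimulatedDataset:
    """Run every generator with one seed and return the full in-memory dataset."""
    config = config or PipelineConfig()
    genome, centromeres, repeats, ledger = generate_genome(config, seed)
    h3k27ac, h3k27me3 = generate_signal_tracks(ledger, config, seed)
    transcripts = generate_transcripts(genome, ledger, config, seed)
    coverage = generate_coverage(ledger, config, seed)
    gene_matrix, mirna_matrix = generate_expression_matrix(ledger, config, seed)
    return SimulatedDataset(
        genome, centromeres, repeats, h3k27ac, h3k27me3,
        transcripts, coverage, gene_matrix, mirna_matrix, ledger,
    )


def simulate_to_dir(out_dir: str | Path, config: PipelineConfig | None = None, seed: int = 0) -> SimulatedDataset:
    """Simulate and write FASTA/BED/bedGraph/TSV outputs plus truth_ledger.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate(config, seed)
    write_fasta(
        [SequenceRecord(chrom, seq) for chrom, seq in ds.genome.items()],
        out / "genome.fa",
    )
    write_bed(ds.centromeres, out / "centromeres.bed",
              names=[f"cen_{c.chrom}" for c in ds.centromeres])
    write_bed(ds.repeats, out / "repeats.bed",
              names=[f"rep_{i + 1}" for i in range(len(ds.repeats))])
    write_bedgraph(ds.h3k27ac, out / "h3k27ac.bedGraph")
    write_bedgraph(ds.h3k27me3, out / "h3k27me3.bedGraph")
    write_fasta(ds.transcripts, out / "transcripts.fa")
    for line, track in ds.coverage.items():
        write_bedgraph(track, out / f"coverage_{line}.bedGraph")
    ds.gene_matrix.to_csv(out / "gene_expression.tsv", sep="\t")
    ds.mirna_matrix.to_csv(out / "mirna_expression.tsv", sep="\t")
    (out / "c19mc_members.txt").write_text("\n".join(C19MC_MEMBERS) + "\n")
    ds.ledger.to_json(out / "truth_ledger.json")
    return ds
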