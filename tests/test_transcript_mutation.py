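import numpy as np
import pytest

from gps_periscan.config import PipelineConfig
from gps_periscan.core_io import GenomicInterval, SequenceRecord, reverse_complement
from gps_periscan.family_homology import MotifHit
from gps_periscan.orf_annotation import OpenReadingFrame, translate
from gps_periscan.transcript_mutation import (
    AlignmentError,
    FrameshiftError,
    MutationCall,
    align_transcript,
    call_mutations,
    compare_samples,
    truncation_consequence,
)


def _toy_reference(rng=None):
    """A 60-codon reference ORF embedded in 200 nt of random context."""
    rng = rng or np.random.default_rng(0)
    protein = "M" + "".join("ACDEFGHIKLNPQRSTVWY"[i] for i in rng.integers(0, 19, 59))
    from gps_periscan.synthetic_data import _protein_to_nt

    orf_nt = _protein_to_nt(rng, protein)
    ctx = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
    region_seq = ctx[:100] + orf_nt + ctx[100:]
    region = SequenceRecord("region", region_seq)
    orf = OpenReadingFrame(
        locus=GenomicInterval("region", 100, 100 + len(orf_nt), "+"),
        strand="+",
        frame=0,
        nt_length=len(orf_nt),
        start_codon=orf_nt[:3],
        protein=SequenceRecord("toy", protein, "protein"),
    )
    return region, orf, orf_nt, 100


class TestAlignTranscript:
    def test_exact_substring_is_intronless_identity_100(self):
        region, orf, orf_nt, offset = _toy_reference()
        tx = SequenceRecord("tx", region.sequence[offset - 20 : offset + len(orf_nt) + 20])
        aln = align_transcript(tx, region)
        assert aln.intronless
        assert aln.identity_pct == 100.0
        assert aln.gaps_in_genome == []

    def test_constructed_splice_yields_one_intron(self):
        cfg = PipelineConfig(intron_min_gap=20)
        region, orf, orf_nt, offset = _toy_reference()
        # two exons of ~60 and ~90 nt around a 30-nt genomic gap
        tx = SequenceRecord(
            "tx", region.sequence[offset : offset + 60] + region.sequence[offset + 90 : offset + len(orf_nt)]
        )
        aln = align_transcript(tx, region, cfg)
        assert len(aln.gaps_in_genome) == 1
        gap = aln.gaps_in_genome[0]
        assert len(gap) == 30
        assert not aln.intronless

    def test_low_identity_rejected(self):
        region, *_ = _toy_reference()
        rng = np.random.default_rng(99)
        noise = SequenceRecord("noise", "".join("ACGT"[i] for i in rng.integers(0, 4, 300)))
        with pytest.raises(AlignmentError):
            align_transcript(noise, region)

    def test_planted_intron_recovered_at_exact_coordinates(self, dataset, config):
        led = dataset.ledger
        sp = led.spliced_gene
        tx = next(t for t in dataset.transcripts if t.identifier.startswith("SPLICED"))
        lo = sp["gene_start"] - 300
        region = SequenceRecord("sp", dataset.genome[sp["chrom"]][lo : sp["gene_end"] + 300])
        aln = align_transcript(tx, region, config)
        assert [(g.start + lo, g.end + lo) for g in aln.gaps_in_genome] == [
            (led.planted_intron["start"], led.planted_intron["end"])
        ]


class TestCallMutations:
    def _mutate(self, orf_nt, codon_index, alt_codon):
        i = (codon_index - 1) * 3
        return orf_nt[:i] + alt_codon + orf_nt[i + 3 :]

    def test_missense_silent_stopgain_names(self):
        rng = np.random.default_rng(1)
        region, orf, orf_nt, offset = _toy_reference(rng)
        # force known reference codons, then mutate them
        nt = orf_nt[:9] + "TTT" + "CCA" + "GGA" + orf_nt[18:]
        protein = translate(nt)
        orf = OpenReadingFrame(
            locus=orf.locus, strand="+", frame=0, nt_length=len(nt),
            start_codon=nt[:3], protein=SequenceRecord("toy", protein, "protein"),
        )
        region = SequenceRecord("region", region.sequence[:offset] + nt + region.sequence[offset + len(nt):])
        mutated = nt
        for idx, alt in [(4, "GTT"), (5, "CCG"), (6, "TGA")]:
            mutated = self._mutate(mutated, idx, alt)
        tx = SequenceRecord("tx", mutated)
        aln = align_transcript(tx, region)
        calls = call_mutations(aln, orf, offset)
        assert [(c.name, c.mclass) for c in calls] == [
            ("F4V", "missense"),
            ("P5P (silent)", "silent"),
            ("G6Stop", "stop-gain"),
        ]

    def test_multiple_substitutions_in_one_codon_single_call(self):
        region, orf, orf_nt, offset = _toy_reference()
        codon = orf_nt[9:12]
        alt = "".join({"A": "C", "C": "A", "G": "T", "T": "G"}[b] for b in codon)
        tx = SequenceRecord("tx", self._mutate(orf_nt, 4, alt))
        calls = call_mutations(align_transcript(tx, region), orf, offset)
        assert len(calls) == 1
        assert calls[0].codon_index == 4 and calls[0].alt_codon == alt

    def test_indel_in_orf_is_frameshift_error(self):
        region, orf, orf_nt, offset = _toy_reference()
        tx = SequenceRecord("tx", orf_nt[:30] + orf_nt[31:])  # 1-nt deletion
        aln = align_transcript(tx, region)
        with pytest.raises(FrameshiftError):
            call_mutations(aln, orf, offset)

    def test_name_regenerable_from_fields(self):
        call = MutationCall("g", 132, "GGA", "TGA", "G", "*")
        assert call.name == "G132Stop" and call.mclass == "stop-gain"
        call = MutationCall("g", 129, "CCA", "CCG", "P", "P")
        assert call.name == "P129P (silent)" and call.mclass == "silent"
        call = MutationCall("g", 42, "TTT", "GTT", "F", "V")
        assert call.name == "F42V" and call.mclass == "missense"

    def test_identical_codons_rejected(self):
        with pytest.raises(ValueError):
            MutationCall("g", 1, "ATG", "ATG", "M", "M")

    def test_planted_mutations_recovered_exactly(self, dataset, config):
        led = dataset.ledger
        gene = max(led.pericentromeric_orfs(), key=lambda o: o.nt_length)
        lo, hi = gene.start - 200, gene.end + 200
        raw = dataset.genome[gene.chrom][lo:hi]
        if gene.strand == "-":
            raw = reverse_complement(raw)
        region = SequenceRecord("ref", raw)
        offset = 200
        ref_orf = OpenReadingFrame(
            locus=gene.interval, strand=gene.strand, frame=0,
            nt_length=gene.nt_length, start_codon=gene.orf_seq[:3],
            protein=SequenceRecord(gene.gene, gene.protein, "protein"),
        )
        per_sample = {}
        for tx in dataset.transcripts:
            g, _, sample = tx.identifier.partition("|")
            if g != gene.gene:
                continue
            aln = align_transcript(tx, region, config)
            per_sample[sample] = call_mutations(aln, ref_orf, offset, gene=g)
        planted = {}
        for m in led.planted_mutations:
            planted.setdefault(m.sample, set()).add(
                (m.codon_index, m.ref_codon, m.alt_codon, m.expected_name, m.expected_class)
            )
        assert set(per_sample) == set(planted)
        for sample, calls in per_sample.items():
            got = {(c.codon_index, c.ref_codon, c.alt_codon, c.name, c.mclass) for c in calls}
            assert got == planted[sample]
        # stop-gain implies truncated product length = codon_index - 1
        for m in led.planted_mutations:
            if m.expected_class == "stop-gain":
                mutated_orf = next(
                    t for t in dataset.transcripts if t.identifier == f"{gene.gene}|{m.sample}"
                ).sequence[config.transcript_flank :]
                prot = str(__import__("Bio.Seq", fromlist=["Seq"]).Seq(mutated_orf).translate(table=1, to_stop=True))
                assert len(prot) == m.codon_index - 1


class TestTruncationConsequence:
    def _stop(self, idx):
        return MutationCall("g", idx, "GGA", "TGA", "G", "*")

    def test_downstream_motif_lost(self):
        hits = [MotifHit("g", 150, "FPFP", 1.0)]
        assert truncation_consequence([self._stop(132)], hits) == [(hits[0], True)]

    def test_upstream_motif_retained(self):
        hits = [MotifHit("g", 50, "FPFP", 1.0)]
        assert truncation_consequence([self._stop(132)], hits) == [(hits[0], False)]

    def test_no_stop_gain_all_retained(self):
        hits = [MotifHit("g", 10, "FPFP", 1.0), MotifHit("g", 300, "FPFP", 1.0)]
        missense = MutationCall("g", 5, "TTT", "GTT", "F", "V")
        assert all(not lost for _, lost in truncation_consequence([missense], hits))

    def test_planted_fpfp_lost_by_g132stop(self, dataset):
        from gps_periscan.family_homology import fpfp_scan

        led = dataset.ledger
        gene = max(led.pericentromeric_orfs(), key=lambda o: o.nt_length)
        hits = fpfp_scan(SequenceRecord(gene.gene, gene.protein, "protein"))
        stop = next(m for m in led.planted_mutations if m.expected_class == "stop-gain")
        call = MutationCall(gene.gene, stop.codon_index, stop.ref_codon, stop.alt_codon, "G", "*")
        flagged = truncation_consequence([call], hits)
        assert flagged and all(lost for _, lost in flagged)


class TestCompareSamples:
    def _call(self, idx, alt="GTT", ref="TTT", gene="g"):
        return MutationCall(gene, idx, ref, alt, "F", "V")

    def test_identical_catalogues_no_uniques(self):
        calls = [self._call(4), self._call(7)]
        cmp = compare_samples({"a": calls, "b": list(calls)})
        assert len(cmp.shared) == 2
        assert all(not u for u in cmp.unique_per_sample.values())

    def test_disjoint_catalogues_no_shared(self):
        cmp = compare_samples({"a": [self._call(4)], "b": [self._call(7)]})
        assert cmp.shared == []
        assert len(cmp.unique_per_sample["a"]) == 1
        assert len(cmp.unique_per_sample["b"]) == 1

    def test_different_genes_rejected(self):
        with pytest.raises(ValueError, match="different genes"):
            compare_samples({"a": [self._call(4, gene="g1")], "b": [self._call(4, gene="g2")]})

    def test_planted_shared_unique_partition(self, dataset):
        led = dataset.ledger
        per_sample: dict[str, list[MutationCall]] = {}
        for m in led.planted_mutations:
            ref_aa = m.expected_name[0]
            alt_aa = "*" if m.expected_class == "stop-gain" else (
                ref_aa if m.expected_class == "silent" else m.expected_name.rstrip(" (silent)")[-1]
            )
            per_sample.setdefault(m.sample, []).append(
                MutationCall(m.gene, m.codon_index, m.ref_codon, m.alt_codon, ref_aa, alt_aa)
            )
        cmp = compare_samples(per_sample)
        shared_truth = {(m.codon_index, m.alt_codon) for m in led.planted_mutations if m.shared}
        assert {c.key for c in cmp.shared} == shared_truth
        for sample, calls in cmp.unique_per_sample.items():
            truth = {
                (m.codon_index, m.alt_codon)
                for m in led.planted_mutations
                if m.sample == sample and not m.shared
            }
            assert {c.key for c in calls} == truth
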