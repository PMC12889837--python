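"""Pipeline configuration: one flat namespace of tunables with validated defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with defaults.

    Unknown keys are rejected on construction from a mapping or YAML file so
    that a typo in a config file fails loudly instead of silently using a
    default.
    """

    # --- pericentromere scan ---
    flank: int = 50_000  # bp of pericentromeric window either side of the centromere
    h3k27ac_threshold: float = 2.0  # fold-change-over-control cutoff for "strong" mark
    h3k27me3_threshold: float = 2.0
    peak_min_width: int = 200  # bp
    peak_merge_gap: int = 100  # bp
    candidate_padding: int = 1_000  # bp added around window∩repeat candidates

    # --- ORF discovery / protein annotation ---
    start_codons: tuple[str, ...] = ("ATG", "CTG", "GTG", "TTG")
    min_orf_length: int = 300  # nt, stop codon included
    enrichment_cutoff: float = 1.5  # residue fraction / background fraction

    # --- alignment ---
    nt_match: float = 2.0
    nt_mismatch: float = -3.0
    nt_gap_open: float = -5.0  # score of the first gapped position
    nt_gap_extend: float = -2.0
    protein_gap_open: float = -11.0
    protein_gap_extend: float = -1.0
    intron_min_gap: int = 20  # genome-side gap length that counts as an intron
    alignment_identity_floor: float = 70.0  # percent

    # --- family homology ---
    window_min: int = 12  # conserved-window length bounds (aa)
    window_max: int = 13
    window_identity_cutoff: float = 10 / 12  # per-window match fraction
    conservation_fraction: float = 0.8  # fraction of family members required

    # --- expression analysis ---
    n_per_group: int = 12
    log2fc_threshold: float = 2.0
    p_threshold: float = 0.05
    gps_positive_cutoff: float = 0.0  # GPS score strictly above this is "positive"

    # --- synthetic genome (toy scale) ---
    n_chromosomes: int = 3
    chromosome_length: int = 300_000
    centromere_length: int = 30_000
    repeat_flank_length: int = 50_000
    orf_lengths: tuple[int, ...] = (624, 792, 450, 366)  # nt, stop included
    decoy_orf_length: int = 501
    spliced_exon_lengths: tuple[int, int] = (240, 240)
    spliced_intron_length: int = 100
    peak_amplitude: float = 3.0
    peak_padding: int = 300  # peak extends this far past the ORF on each side
    noise_bin: int = 500  # bp per background noise record in signal tracks
    noise_free: bool = False
    transcript_flank: int = 30  # nt of genomic context around transcript ORFs
    n_cell_lines: int = 100
    n_background_genes: int = 20
    background_sd: float = 0.3  # within-group sd of log2 expression
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flank <= 0:
            raise ValueError("flank must be positive")
        if self.min_orf_length < 6 or self.min_orf_length % 3:
            raise ValueError("min_orf_length must be a positive multiple of 3")
        for codon in self.start_codons:
            if len(codon) != 3 or set(codon) - set("ACGT"):
                raise ValueError(f"invalid start codon {codon!r}")
        if self.n_cell_lines < 2 * self.n_per_group:
            raise ValueError(
                f"n_cell_lines={self.n_cell_lines} cannot host two groups of {self.n_per_group}"
            )

    @classmethod
    def from_dict(cls, mapping: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = dict(mapping)
        for key in ("start_codons", "orf_lengths", "spliced_exon_lengths"):
            if key in coerced and not isinstance(coerced[key], tuple):
                coerced[key] = tuple(coerced[key])
        return cls(**coerced)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        return cls.from_dict(data)

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
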