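"""Family-level homology: pairwise global-alignment identity matrices,
UPGMA cladograms with Newick output, conserved-window scoring, and
exact FPFP-motif scanning.

Homology is computed pairwise (Needleman-Wunsch with affine gaps) rather
than by progressive multiple alignment: the family-level readout is an
identity-from-anchor matrix and an average-linkage tree, for which pairwise
identities are sufficient and fully deterministic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .config import PipelineConfig
from .core_io import SequenceRecord

logger = logging.getLogger("gps_periscan")


# ---------------------------------------------------------------------------
# pairwise global alignment
# ---------------------------------------------------------------------------


def _make_aligner(mode: str, config: PipelineConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if mode == "nucleotide":
        aligner.match_score = config.nt_match
        aligner.mismatch_score = config.nt_mismatch
        aligner.open_gap_score = config.nt_gap_open
        aligner.extend_gap_score = config.nt_gap_extend
    elif mode == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = config.protein_gap_open
        aligner.extend_gap_score = config.protein_gap_extend
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return aligner


def alignment_identity(aligned_a: str, aligned_b: str) -> float:
    """Percent identity over aligned columns, terminal-gap columns excluded.

    Columns inside the left/right terminal-gap overhang of either sequence do
    not count; identity = matches / remaining columns * 100.
    """
    n = len(aligned_a)
    def core(s: str) -> tuple[int, int]:
        lo = n - len(s.lstrip("-"))
        hi = len(s.rstrip("-"))
        return lo, hi
    lo = max(core(aligned_a)[0], core(aligned_b)[0])
    hi = min(core(aligned_a)[1], core(aligned_b)[1])
    cols = hi - lo
    if cols <= 0:
        return 0.0
    matches = sum(1 for i in range(lo, hi) if aligned_a[i] == aligned_b[i] and aligned_a[i] != "-")
    return 100.0 * matches / cols


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    config: PipelineConfig | None = None,
) -> tuple[str, str, float, float]:
    """Needleman-Wunsch global alignment with affine gaps.

    Returns (aligned_a, aligned_b, score, identity_pct). Identity is computed
    from the alignment, independent of the scoring matrix that produced it.
    """
    if a.mode != b.mode:
        raise ValueError("sequences must share a mode")
    config = config or PipelineConfig()
    aligner = _make_aligner(a.mode, config)
    alignment = aligner.align(a.sequence, b.sequence)[0]
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    return aligned_a, aligned_b, alignment.score, alignment_identity(aligned_a, aligned_b)


# ---------------------------------------------------------------------------
# identity matrix
# ---------------------------------------------------------------------------


@dataclass
class IdentityMatrix:
    labels: list[str]
    values: np.ndarray  # square, percent identity 0-100

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape disagrees with labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 100.0):
            raise ValueError("diagonal must be 100")
        if self.values.min() < 0 or self.values.max() > 100 + 1e-9:
            raise ValueError("identities must lie in [0, 100]")

    def to_distance(self) -> np.ndarray:
        return 100.0 - self.values

    def anchored(self, anchor: str) -> list[tuple[str, float]]:
        """Identity of every member to one anchor, descending."""
        i = self.labels.index(anchor)
        pairs = [(lab, self.values[i, j]) for j, lab in enumerate(self.labels) if j != i]
        return sorted(pairs, key=lambda p: (-p[1], p[0]))


def identity_matrix(
    family: list[SequenceRecord],
    config: PipelineConfig | None = None,
) -> IdentityMatrix:
    """All-pairs percent identity over a sequence family."""
    if len(family) < 2:
        raise ValueError("need at least 2 sequences")
    labels = [rec.identifier for rec in family]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    n = len(family)
    values = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        *_, ident = global_align(family[i], family[j], config)
        values[i, j] = values[j, i] = ident
    logger.info("identity_matrix: %d sequences (%s mode)", n, family[0].mode)
    return IdentityMatrix(labels, values)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


@dataclass
class CladeNode:
    """A node of an ultrametric UPGMA tree; height is distance/2 units."""

    label: str | None = None
    height: float = 0.0
    children: list["CladeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        return [leaf for child in self.children for leaf in child.leaves()]

    def to_newick(self) -> str:
        return self._newick(parent_height=None) + ";"

    def _newick(self, parent_height: float | None) -> str:
        if self.is_leaf:
            body = self.label or ""
        else:
            body = "(" + ",".join(c._newick(self.height) for c in self.children) + ")"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - self.height:g}"


def upgma(matrix: IdentityMatrix) -> CladeNode:
    """Average-linkage (UPGMA) tree on distance = 100 - identity.

    Ties are broken by merging the lexicographically smallest label pair
    first, so the topology is deterministic. Node heights are half the merge
    distance, making root-to-leaf distances equal (ultrametric).
    """
    dist = {
        frozenset((a, b)): matrix.to_distance()[i, j]
        for i, a in enumerate(matrix.labels)
        for j, b in enumerate(matrix.labels)
        if i < j
    }
    clusters: dict[str, tuple[CladeNode, int]] = {
        lab: (CladeNode(label=lab), 1) for lab in matrix.labels
    }
    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted(kv[0]))),
        )
        (pair, d) = best
        a, b = sorted(pair)
        node_a, size_a = clusters.pop(a)
        node_b, size_b = clusters.pop(b)
        merged = CladeNode(height=d / 2, children=[node_a, node_b])
        del dist[pair]
        new_label = a  # smallest label represents the merged cluster
        for other in list(clusters):
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((new_label, other))] = (size_a * da + size_b * db) / (size_a + size_b)
        clusters[new_label] = (merged, size_a + size_b)
    (root, _), = clusters.values()
    return root


# ---------------------------------------------------------------------------
# conserved windows / FPFP motif
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int  # 1-based protein position
    window: str
    conservation: float  # fraction of other family members matching


def _member_matches_window(window: str, member: str, min_len: int, max_len: int, cutoff: float) -> bool:
    """True if the member contains a gapless segment matching the window.

    Sub-windows of every allowed length (min_len..max_len, capped by the
    window itself) are slid over the member; a match needs >= cutoff fraction
    of identical positions.
    """
    for length in range(min_len, min(max_len, len(window)) + 1):
        needed = int(np.ceil(cutoff * length - 1e-9))
        for w_off in range(len(window) - length + 1):
            sub = window[w_off : w_off + length]
            for m_off in range(len(member) - length + 1):
                same = sum(1 for x, y in zip(sub, member[m_off : m_off + length]) if x == y)
                if same >= needed:
                    return True
    return False


def conserved_windows(
    family: list[SequenceRecord],
    config: PipelineConfig | None = None,
    anchor: str | None = None,
) -> list[MotifHit]:
    """Sliding-window conservation scan against an anchor sequence.

    For each max-length window of the anchor, conservation is the fraction of
    the other members containing a matching segment at or above the identity
    cutoff; windows reaching the conservation fraction are hits, and
    overlapping hits are merged to maximal spans.
    """
    if len(family) < 2:
        raise ValueError("need at least 2 proteins")
    config = config or PipelineConfig()
    by_id = {rec.identifier: rec for rec in family}
    anchor_id = anchor or family[0].identifier
    anchor_seq = by_id[anchor_id].sequence
    others = [rec.sequence for rec in family if rec.identifier != anchor_id]
    wlen = config.window_max

    raw: list[tuple[int, float]] = []  # (0-based start, conservation)
    for off in range(max(0, len(anchor_seq) - wlen + 1)):
        window = anchor_seq[off : off + wlen]
        n_match = sum(
            _member_matches_window(window, member, config.window_min, config.window_max,
                                   config.window_identity_cutoff)
            for member in others
        )
        conservation = n_match / len(others)
        if conservation >= config.conservation_fraction:
            raw.append((off, conservation))

    hits: list[MotifHit] = []
    i = 0
    while i < len(raw):  # merge runs of overlapping windows into maximal spans
        start, best = raw[i]
        end = start + wlen
        j = i + 1
        while j < len(raw) and raw[j][0] < end:
            end = raw[j][0] + wlen
            best = max(best, raw[j][1])
            j += 1
        hits.append(MotifHit(anchor_id, start + 1, anchor_seq[start:end], best))
        i = j
    logger.info("conserved_windows: anchor=%s -> %d merged hits", anchor_id, len(hits))
    return hits


FPFP = "FPFP"


def fpfp_scan(protein: SequenceRecord) -> list[MotifHit]:
    """All exact FPFP occurrences (overlaps allowed), 1-based positions."""
    if protein.mode != "protein":
        raise ValueError("fpfp_scan requires a protein sequence")
    seq = protein.sequence
    hits = []
    pos = seq.find(FPFP)
    while pos != -1:
        hits.append(MotifHit(protein.identifier, pos + 1, FPFP, 1.0))
        pos = seq.find(FPFP, pos + 1)
    return hits
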