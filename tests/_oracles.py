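"""Independent brute-force oracles used only by the tests.

Each oracle is written as a direct, naive restatement of the operation's
definition, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

STOPS = {"TAA", "TAG", "TGA"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# --- ORF discovery: enumerate every (start, stop) codon pair ----------------


def orf_oracle(seq: str, start_codons: set[str], min_len: int) -> set[tuple[int, int, str]]:
    """All maximal ORFs as (fwd_start, fwd_end, strand), by pair enumeration.

    For each stop codon, every in-frame upstream start codon with no stop in
    between is a candidate; the most upstream one is kept ("maximum ORF
    length"). ORFs containing N or shorter than min_len are dropped.
    """
    n = len(seq)
    found: set[tuple[int, int, str]] = set()
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        # all start-codon positions, extended codon-by-codon to their first stop
        best_start_for_stop: dict[int, int] = {}
        for i in range(n - 2):
            if s[i : i + 3] not in start_codons or "N" in s[i : i + 3]:
                continue
            j = i + 3
            while j + 3 <= n:
                codon = s[j : j + 3]
                if codon in STOPS:
                    prev = best_start_for_stop.get(j)
                    if prev is None or i < prev:
                        best_start_for_stop[j] = i
                    break
                j += 3
        for stop, start in best_start_for_stop.items():
            end = stop + 3
            if end - start < min_len or "N" in s[start:end]:
                continue
            if strand == "+":
                found.add((start, end, "+"))
            else:
                found.add((n - end, n - start, "-"))
    return found


# --- interval intersection: per-base membership -----------------------------


def intersect_oracle(a: list[tuple[str, int, int]], b: list[tuple[str, int, int]]) -> set[tuple[str, int]]:
    """Set of (chrom, base) covered by both interval collections."""
    def cover(ivs):
        out = set()
        for chrom, lo, hi in ivs:
            out.update((chrom, p) for p in range(lo, hi))
        return out

    return cover(a) & cover(b)


# --- isoelectric point: grid search -----------------------------------------


def pi_grid_oracle(protein: str, pka: dict[str, float], resolution: float = 0.001) -> float:
    """pH of minimum |net charge| over a fine grid on [0, 14]."""
    counts = {aa: protein.count(aa) for aa in "CDEHKRY"}

    def charge(ph: float) -> float:
        pos = 1 / (1 + 10 ** (ph - pka["N_term"]))
        for aa in "HKR":
            pos += counts[aa] / (1 + 10 ** (ph - pka[aa]))
        neg = 1 / (1 + 10 ** (pka["C_term"] - ph))
        for aa in "CDEY":
            neg += counts[aa] / (1 + 10 ** (pka[aa] - ph))
        return pos - neg

    best_ph, best_abs = 0.0, float("inf")
    steps = int(14 / resolution)
    for k in range(steps + 1):
        ph = k * resolution
        c = abs(charge(ph))
        if c < best_abs:
            best_ph, best_abs = ph, c
    return best_ph


# --- global alignment: exhaustive enumeration -------------------------------


def align_score_oracle(
    a: str,
    b: str,
    substitution,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Optimal global alignment score by enumerating all alignments.

    ``substitution(x, y)`` scores an aligned residue pair. A gap run of
    length k scores gap_open + (k-1)*gap_extend (the first gapped position
    carries the open score). Feasible only for short sequences.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        # state: last column type M / I (gap in a) / D (gap in b) / start
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(substitution(a[i], b[j]) + best(i + 1, j + 1, "M"))
        if j < len(b):  # gap in a
            cost = gap_extend if state == "I" else gap_open
            options.append(cost + best(i, j + 1, "I"))
        if i < len(a):  # gap in b
            cost = gap_extend if state == "D" else gap_open
            options.append(cost + best(i + 1, j, "D"))
        return max(options)

    return best(0, 0, "start")


# --- UPGMA: naive repeated-minimum implementation ---------------------------


def upgma_cophenetic_oracle(labels: list[str], dist: dict[frozenset, float]) -> dict[frozenset, float]:
    """Cophenetic distances from a naive UPGMA (min-distance pair merging).

    Returns, for each leaf pair, the distance at which they first share a
    cluster. Independent of any tree data structure.
    """
    clusters: list[set[str]] = [{lab} for lab in labels]
    d = dict(dist)

    def cdist(c1: frozenset, c2: frozenset) -> float:
        return sum(d[frozenset((x, y))] for x in c1 for y in c2) / (len(c1) * len(c2))

    coph: dict[frozenset, float] = {}
    while len(clusters) > 1:
        pairs = list(itertools.combinations(range(len(clusters)), 2))
        best = min(pairs, key=lambda p: cdist(frozenset(clusters[p[0]]), frozenset(clusters[p[1]])))
        i, j = best
        merge_d = cdist(frozenset(clusters[i]), frozenset(clusters[j]))
        for x in clusters[i]:
            for y in clusters[j]:
                coph[frozenset((x, y))] = merge_d
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return coph


# --- FPFP: naive quadratic substring search ---------------------------------


def substring_positions_oracle(text: str, pattern: str) -> list[int]:
    """1-based start positions of every (possibly overlapping) occurrence."""
    return [i + 1 for i in range(len(text) - len(pattern) + 1) if text[i : i + len(pattern)] == pattern]
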