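"""Seeded local alignment: enumerate putative genomic binding sites of a probe.

The search is seed-and-extend: every probe substring of ``seed_length``
(from the probe for + strand hits and from its reverse complement for -
strand hits) is looked up in a precomputed index of genome seed positions;
seed hits sharing a diagonal neighborhood are clustered into candidate loci
and each locus window is scanned with an affine-gap Smith-Waterman
alignment (match +2, mismatch -6, gap open -5, gap extend -3 per gapped
base).  Alignments are kept when their score reaches ``1 + 4*ln(L)`` for a
probe of length L; within a window, qualifying alignments are enumerated by
recursing into the flanks of each reported site, and overlapping sites on
the same scaffold/strand collapse to the best-scoring one.

On small genomes the seed lookup also probes every 1-mismatch variant of
each seed, recovering sites whose exact seeds were destroyed by divergence.

Hits are reported best score first (ties by scaffold order then start), at
most ``max_alignments`` of them.  For - strand hits, coordinates are in the
forward-strand frame and the stored target row is the reverse complement of
the genomic slice, so the two rows of every hit are directly
hybridization-comparable (matched columns carry equal characters).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

from .genome import BedInterval, GenomeAssembly, reverse_complement

MATCH = 2
MISMATCH = -6
GAP_OPEN = -5
GAP_EXTEND = -3
SEED_MISMATCH_INDEX_LIMIT = 10_000_000  # genome positions

_NEG_INF = float("-inf")


class AlignError(ValueError):
    pass


def min_score_threshold(probe_length: int) -> float:
    """Minimum qualifying local alignment score for a probe of given length."""
    return 1.0 + 4.0 * math.log(probe_length)


@dataclass(frozen=True)
class AlignmentHit:
    """One putative binding site with its decoded alignment."""

    scaffold: str
    start: int
    end: int
    strand: str  # "+" or "-"
    score: int
    probe_row: str
    target_row: str


def pairwise(hit: AlignmentHit) -> tuple[str, str]:
    """The aligned (probe row, target row) character pair of a hit."""
    return hit.probe_row, hit.target_row


def alignment_score(probe_row: str, target_row: str) -> int:
    """Recompute the affine-gap score of a decoded alignment pair."""
    if len(probe_row) != len(target_row):
        raise AlignError("aligned rows must have equal length")
    score = 0
    in_gap = False
    for a, b in zip(probe_row, target_row):
        if a == "-" or b == "-":
            score += GAP_EXTEND + (0 if in_gap else GAP_OPEN)
            in_gap = True
        else:
            score += MATCH if a == b else MISMATCH
            in_gap = False
    return score


class SeedIndex:
    """Exact-match index of every N-free ``seed_length``-mer in the assembly."""

    def __init__(self, assembly: GenomeAssembly, seed_length: int = 15):
        if seed_length < 1:
            raise AlignError("seed_length must be >= 1")
        self.seed_length = seed_length
        self.assembly = assembly
        self.positions: dict[str, list[tuple[str, int]]] = defaultdict(list)
        self.total_positions = 0
        for name, seq in assembly.scaffolds.items():
            for i in range(len(seq) - seed_length + 1):
                seed = seq[i : i + seed_length]
                if "N" not in seed:
                    self.positions[seed].append((name, i))
                    self.total_positions += 1

    def lookup(self, seed: str) -> list[tuple[str, int]]:
        return self.positions.get(seed, [])


def _one_mismatch_variants(seed: str):
    for i, base in enumerate(seed):
        for alt in "ACGT":
            if alt != base:
                yield seed[:i] + alt + seed[i + 1 :]


def smith_waterman(query: str, target: str):
    """Best local alignment of query vs target with affine gaps.

    Returns ``(score, q_start, q_end, t_start, t_end, q_row, t_row)`` or
    ``None`` when no positive-scoring alignment exists.
    """
    n, m = len(query), len(target)
    if n == 0 or m == 0:
        return None
    # H: best alignment ending at (i, j); E: gap in target row (query char
    # over '-'); F: gap in query row.
    prev_h = [0.0] * (m + 1)
    prev_e = [_NEG_INF] * (m + 1)
    ptr = [[0] * (m + 1) for _ in range(n + 1)]  # bitmask traceback
    best, best_ij = 0.0, None
    for i in range(1, n + 1):
        cur_h = [0.0] * (m + 1)
        cur_e = [_NEG_INF] * (m + 1)
        f = _NEG_INF
        qi = query[i - 1]
        row_ptr = ptr[i]
        for j in range(1, m + 1):
            e = max(prev_h[j] + GAP_OPEN + GAP_EXTEND, prev_e[j] + GAP_EXTEND)
            f = max(cur_h[j - 1] + GAP_OPEN + GAP_EXTEND, f + GAP_EXTEND)
            sub = MATCH if qi == target[j - 1] else MISMATCH
            diag = prev_h[j - 1] + sub
            h = max(0.0, diag, e, f)
            cur_h[j] = h
            cur_e[j] = e
            if h > 0:
                if h == diag:
                    row_ptr[j] = 1
                elif h == e:
                    row_ptr[j] = 2
                else:
                    row_ptr[j] = 3
            if h > best:
                best, best_ij = h, (i, j)
        prev_h, prev_e = cur_h, cur_e
    if best_ij is None or best <= 0:
        return None
    i, j = best_ij
    q_row: list[str] = []
    t_row: list[str] = []
    q_end, t_end = i, j
    while i > 0 and j > 0 and ptr[i][j]:
        move = ptr[i][j]
        if move == 1:
            q_row.append(query[i - 1])
            t_row.append(target[j - 1])
            i -= 1
            j -= 1
        elif move == 2:
            q_row.append(query[i - 1])
            t_row.append("-")
            i -= 1
        else:
            q_row.append("-")
            t_row.append(target[j - 1])
            j -= 1
    return (
        int(best), i, q_end, j, t_end,
        "".join(reversed(q_row)), "".join(reversed(t_row)),
    )


def _window_hits(query: str, target: str, t_offset: int, threshold: float):
    """All non-overlapping qualifying local alignments in a window."""
    result = smith_waterman(query, target)
    if result is None:
        return []
    score, _, _, t_start, t_end, q_row, t_row = result
    if score < threshold:
        # no sub-window can score higher than the window optimum
        return []
    hits = [(score, t_offset + t_start, t_offset + t_end, q_row, t_row)]
    # recurse into flanks to pick up tandem neighbors within the window
    if t_start > 0:
        hits.extend(_window_hits(query, target[:t_start], t_offset, threshold))
    if t_end < len(target):
        hits.extend(
            _window_hits(query, target[t_end:], t_offset + t_end, threshold)
        )
    return hits


def align_probe(
    probe: str,
    assembly: GenomeAssembly,
    seed_length: int = 15,
    max_alignments: int = 500_000,
    index: SeedIndex | None = None,
    seed_mismatch: bool | None = None,
    pad: int = 10,
) -> list[AlignmentHit]:
    """Enumerate qualifying local-alignment sites of a probe in the genome."""
    if len(probe) < seed_length:
        raise AlignError(
            f"probe length {len(probe)} is shorter than seed length {seed_length}"
        )
    if index is None:
        index = SeedIndex(assembly, seed_length)
    elif index.seed_length != seed_length:
        raise AlignError("index seed length does not match seed_length")
    if seed_mismatch is None:
        seed_mismatch = index.total_positions < SEED_MISMATCH_INDEX_LIMIT
    threshold = min_score_threshold(len(probe))
    scaffold_order = {name: i for i, name in enumerate(assembly.scaffolds)}
    raw_hits: list[AlignmentHit] = []
    for strand, query in (("+", probe), ("-", reverse_complement(probe))):
        anchors: dict[str, set[int]] = defaultdict(set)
        for o in range(len(query) - seed_length + 1):
            seed = query[o : o + seed_length]
            if "N" in seed:
                continue
            seen_exact = index.lookup(seed)
            for scaf, pos in seen_exact:
                anchors[scaf].add(pos - o)
            if seed_mismatch:
                for variant in _one_mismatch_variants(seed):
                    for scaf, pos in index.lookup(variant):
                        anchors[scaf].add(pos - o)
        for scaf, anchor_set in anchors.items():
            seq = assembly.scaffolds[scaf]
            sorted_anchors = sorted(anchor_set)
            groups: list[list[int]] = [[sorted_anchors[0]]]
            for a in sorted_anchors[1:]:
                if a - groups[-1][-1] <= len(query):
                    groups[-1].append(a)
                else:
                    groups.append([a])
            for group in groups:
                w_start = max(0, group[0] - pad)
                w_end = min(len(seq), group[-1] + len(query) + pad)
                window = seq[w_start:w_end]
                if "N" in window:
                    window = window.replace("N", "n")  # never matches ACGT
                for score, t0, t1, q_row, t_row in _window_hits(
                    query, window, w_start, threshold
                ):
                    if strand == "-":
                        q_row = reverse_complement(q_row)
                        t_row = reverse_complement(t_row)
                    raw_hits.append(
                        AlignmentHit(
                            scaffold=scaf, start=t0, end=t1, strand=strand,
                            score=score, probe_row=q_row, target_row=t_row,
                        )
                    )
    # collapse overlapping extensions: best-scoring site per locus/strand
    raw_hits.sort(
        key=lambda h: (-h.score, scaffold_order[h.scaffold], h.start, h.strand)
    )
    kept: list[AlignmentHit] = []
    occupied: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for hit in raw_hits:
        spans = occupied[hit.scaffold, hit.strand]
        if any(hit.start < e and s < hit.end for s, e in spans):
            continue
        spans.append((hit.start, hit.end))
        kept.append(hit)
        if len(kept) >= max_alignments:
            break
    kept.sort(key=lambda h: (-h.score, scaffold_order[h.scaffold], h.start))
    return kept


def hits_to_bed(hits: list[AlignmentHit], probe_id: str) -> list[BedInterval]:
    """BED-style export of hits (name=probe id; score kept in the name field)."""
    return [
        BedInterval(h.scaffold, h.start, h.end, name=f"{probe_id};{h.score};{h.strand}")
        for h in hits
    ]
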