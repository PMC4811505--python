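"""RNA secondary structure folding and consensus motif characterization.

Candidate binding regions from several 3'UTRs are folded with the Nussinov
maximum-base-pairing dynamic program (Watson-Crick A-U/G-C plus wobble G-U,
hairpin loops of at least ``min_loop`` unpaired nucleotides), aligned by
center-star progressive alignment, and summarized as a consensus sequence
with a consensus dot-bracket structure and GC fraction. Motif positions are
related to AU-rich elements on the primary sequence by a span-gap distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .aremotif import PENTAMER, gc_content

_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")})

GAP = "-"


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


@dataclass(frozen=True)
class FoldResult:
    sequence: str
    structure: str  # dot-bracket
    pairs: tuple[tuple[int, int], ...]  # (i, j) with i < j, 0-based

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class ConsensusMotif:
    """A consensus over aligned short regions: sequence, structure, GC."""

    member_ids: tuple[str, ...]
    alignment: tuple[str, ...]  # gapped rows, equal length
    consensus: str  # gap-stripped consensus sequence
    structure: str  # dot-bracket of the folded consensus
    gc: float
    mean_region_length: float


@dataclass(frozen=True)
class MotifAreDistance:
    """Gap (nt strictly between spans) from a motif span to the nearest AUUUA."""

    utr_id: str
    motif_span: tuple[int, int]  # 0-based, half-open
    nearest_are_span: tuple[int, int] | None
    distance: int | None  # None when the UTR holds no pentamer
    within_165: bool | None


def nussinov_fold(seq: str, min_loop: int = 3) -> FoldResult:
    """Maximum base-pair nested structure by the Nussinov dynamic program.

    ``min_loop`` is the minimum number of unpaired nucleotides closed by any
    pair (steric hairpin minimum). Tie-breaking in the traceback is
    deterministic: leaving position i unpaired is preferred when it ties the
    optimum, otherwise i pairs with the smallest admissible j.
    """
    s = seq.upper().replace("T", "U")
    n = len(s)
    if n == 0:
        raise ValueError("cannot fold an empty sequence")
    M = [[0] * n for _ in range(n)]
    # interval DP over increasing span lengths
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if can_pair(s[i], s[k]):
                    inner = M[i + 1][k - 1] if k - 1 > i + 1 else 0
                    right = M[k + 1][j] if k + 1 <= j else 0
                    cand = 1 + inner + right
                    if cand > best:
                        best = cand
            M[i][j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        if M[i][j] == M[i + 1][j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + min_loop + 1, j + 1):
            if can_pair(s[i], s[k]):
                inner = M[i + 1][k - 1] if k - 1 > i + 1 else 0
                right = M[k + 1][j] if k + 1 <= j else 0
                if 1 + inner + right == M[i][j]:
                    pairs.append((i, k))
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    break

    structure = ["."] * n
    for i, j in pairs:
        structure[i] = "("
        structure[j] = ")"
    pairs.sort()
    return FoldResult(sequence=s, structure="".join(structure), pairs=tuple(pairs))


def parse_dot_bracket(structure: str) -> tuple[tuple[int, int], ...]:
    """Recover the (i, j) pair list from dot-bracket notation."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"illegal structure character {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return tuple(sorted(pairs))


def max_pairs_exhaustive(seq: str, min_loop: int = 3) -> int:
    """Brute-force maximum nested pair count by recursive enumeration.

    Exponential; intended as an independent oracle for short sequences.
    """
    s = seq.upper().replace("T", "U")

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        out = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if can_pair(s[i], s[k]):
                out = max(out, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return out

    return best(0, len(s) - 1) if s else 0


# -- pairwise and center-star alignment ------------------------------------

MATCH, MISMATCH, GAP_PENALTY = 2, -1, -2


def needleman_wunsch(a: str, b: str) -> tuple[str, str, int]:
    """Global alignment with deterministic traceback (diag > up > left)."""
    n, m = len(a), len(b)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * GAP_PENALTY
    for j in range(1, m + 1):
        score[0][j] = j * GAP_PENALTY
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1][j - 1] + (MATCH if a[i - 1] == b[j - 1] else MISMATCH)
            up = score[i - 1][j] + GAP_PENALTY
            left = score[i][j - 1] + GAP_PENALTY
            score[i][j] = max(diag, up, left)
    ra, rb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i][j] == score[i - 1][j - 1] + (
            MATCH if a[i - 1] == b[j - 1] else MISMATCH
        ):
            ra.append(a[i - 1]); rb.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and score[i][j] == score[i - 1][j] + GAP_PENALTY:
            ra.append(a[i - 1]); rb.append(GAP); i -= 1
        else:
            ra.append(GAP); rb.append(b[j - 1]); j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb)), score[n][m]


def align_regions(
    regions: list[tuple[str, str]],
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Center-star progressive multiple alignment of short regions.

    ``regions`` is a list of (id, sequence). The center is the member with
    the maximum summed pairwise alignment score against all others, ties
    broken by lexicographic id. Others are merged against the center with
    "once a gap, always a gap". Returns (ids, gapped rows) with the center
    first; row order otherwise follows the input.
    """
    if len(regions) < 2:
        raise ValueError("need at least 2 regions to align")
    for rid, seq in regions:
        if not seq:
            raise ValueError(f"empty region {rid!r}")
        if len(seq) > 100:
            raise ValueError(f"region {rid!r} exceeds 100 nt")

    ids = [r[0] for r in regions]
    seqs = [r[1].upper().replace("T", "U") for r in regions]
    k = len(seqs)
    totals = [0] * k
    for i in range(k):
        for j in range(k):
            if i != j:
                totals[i] += needleman_wunsch(seqs[i], seqs[j])[2]
    center = min(range(k), key=lambda i: (-totals[i], ids[i]))

    # progressive merge onto the center, keeping every previously placed gap
    center_row = seqs[center]
    rows: list[str] = []
    order = [center] + [i for i in range(k) if i != center]
    for idx in order[1:]:
        a, b, _ = needleman_wunsch(center_row.replace(GAP, ""), seqs[idx])
        # re-inject center's existing gaps; new gap columns widen earlier rows
        new_center: list[str] = []
        new_b: list[str] = []
        oi = 0  # index into the gapped center_row
        ci = 0  # index into a (freshly aligned ungapped center)
        while oi < len(center_row) or ci < len(a):
            if oi < len(center_row) and center_row[oi] == GAP:
                new_center.append(GAP)
                new_b.append(GAP)
                oi += 1
            elif ci < len(a) and a[ci] == GAP:
                col = len(new_center)
                new_center.append(GAP)
                new_b.append(b[ci])
                rows = [r[:col] + GAP + r[col:] for r in rows]
                ci += 1
            else:
                new_center.append(a[ci])
                new_b.append(b[ci])
                oi += 1
                ci += 1
        center_row = "".join(new_center)
        rows.append("".join(new_b))
    all_rows = [center_row] + rows
    all_ids = [ids[i] for i in order]
    return tuple(all_ids), tuple(all_rows)


def consensus_from_alignment(
    ids: tuple[str, ...], rows: tuple[str, ...], min_loop: int = 3
) -> ConsensusMotif:
    """Majority-rule consensus of an alignment, folded and GC-profiled.

    Columns where the gap is the (strict or tied) majority are dropped;
    base ties resolve alphabetically. GC is computed on the gap-stripped
    consensus, which is then folded by the Nussinov program.
    """
    if not rows:
        raise ValueError("empty alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("alignment rows differ in length")
    consensus_chars: list[str] = []
    for col in range(width):
        column = [r[col] for r in rows]
        gap_n = column.count(GAP)
        bases = [c for c in column if c != GAP]
        if not bases or gap_n >= len(bases):
            continue
        counts: dict[str, int] = {}
        for b in bases:
            counts[b] = counts.get(b, 0) + 1
        best = max(counts.values())
        consensus_chars.append(sorted(b for b, c in counts.items() if c == best)[0])
    consensus = "".join(consensus_chars)
    if not consensus:
        raise ValueError("consensus is empty (all columns gap-majority)")
    fold = nussinov_fold(consensus, min_loop=min_loop)
    lengths = [len(r.replace(GAP, "")) for r in rows]
    return ConsensusMotif(
        member_ids=ids,
        alignment=rows,
        consensus=consensus,
        structure=fold.structure,
        gc=gc_content(consensus),
        mean_region_length=float(sum(lengths) / len(lengths)),
    )


def span_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Nucleotides strictly between two 0-based half-open spans (0 if they touch)."""
    return max(0, b[0] - a[1], a[0] - b[1])


def motif_are_distance(
    utr_id: str,
    sequence: str,
    motif_span: tuple[int, int],
    threshold: int = 165,
) -> MotifAreDistance:
    """Distance from a motif span to the nearest AUUUA pentamer on the UTR.

    Distance is the gap in nt strictly between the motif span and the
    pentamer span (0 when they overlap or are adjacent). When the UTR holds
    no pentamer, distance is None and the threshold flag is None. The flag
    uses a strict ``< threshold`` comparison.
    """
    s = sequence.upper().replace("T", "U")
    start, end = motif_span
    if not (0 <= start < end <= len(s)):
        raise ValueError(f"motif span {motif_span} out of bounds for length {len(s)}")
    best: tuple[int, tuple[int, int]] | None = None
    pos = s.find(PENTAMER)
    while pos >= 0:
        are = (pos, pos + len(PENTAMER))
        d = span_gap(motif_span, are)
        if best is None or d < best[0]:
            best = (d, are)
        pos = s.find(PENTAMER, pos + 1)
    if best is None:
        return MotifAreDistance(utr_id, motif_span, None, None, None)
    return MotifAreDistance(
        utr_id, motif_span, best[1], best[0], best[0] < threshold
    )
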