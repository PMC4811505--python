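"""AU-rich element (ARE) scanning and discriminative k-mer motif discovery.

AREs are destabilizing cis-elements found in 3'UTRs. The core signal is the
AUUUA pentamer; the classical taxonomy distinguishes Class I (scattered
pentamers), Class II (overlapping pentamers, i.e. AUUUAUUUA), and Class III
(U-rich elements without a pentamer, operationalized here as a run of >= 17
consecutive uridines). This module profiles UTR sequences for those features,
compares feature prevalence between a bound group and a control group with a
two-sided two-proportion test (Yates-corrected chi-square, mirroring R's
``prop.test``), and performs a simplified discriminative k-mer search
(exact-letter words up to length 8, one-sided Fisher exact test per word,
Bonferroni-style E-value over all words tested).
"""

from __future__ import annotations

import random as _random
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

PENTAMER = "AUUUA"
CONSECUTIVE_PENTAMER = "AUUUAUUUA"
U_STRETCH_MIN = 17

_RNA_ALPHABET = frozenset("ACGU")
_RNA_ALPHABET_N = frozenset("ACGUN")


@dataclass(frozen=True)
class UtrSequence:
    """A canonicalized 3'UTR sequence over the RNA alphabet."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AREProfile:
    """Per-UTR ARE feature summary."""

    id: str
    length: int
    pentamer_count: int
    has_consecutive: bool
    max_u_run: int
    has_u_stretch: bool
    gc: float
    are_class: str  # one of "I", "II", "III", "none"


@dataclass(frozen=True)
class ProportionTestResult:
    """Two-sample proportion test (chi-square with continuity correction)."""

    k1: int
    n1: int
    k2: int
    n2: int
    statistic: float
    p: float

    @property
    def p1(self) -> float:
        return self.k1 / self.n1

    @property
    def p2(self) -> float:
        return self.k2 / self.n2


@dataclass(frozen=True)
class KmerMotifResult:
    """One discriminative k-mer: occurrence counts and Fisher significance."""

    motif: str
    pos_count: int
    pos_total: int
    neg_count: int
    neg_total: int
    p: float
    e_value: float
    rank: int = 0


def canonicalize(seq: str, id: str = "", allow_n: bool = False) -> UtrSequence:
    """Map a raw DNA/RNA string to the uppercase RNA alphabet.

    T (DNA convention) is mapped to U; case is ignored. Characters outside
    {A, C, G, U} are rejected with the offending position, unless ``allow_n``
    admits N as an ambiguous base.

    Raises
    ------
    ValueError
        If an illegal character is found (position reported, 0-based).
    """
    upper = seq.upper().replace("T", "U")
    allowed = _RNA_ALPHABET_N if allow_n else _RNA_ALPHABET
    for i, ch in enumerate(upper):
        if ch not in allowed:
            raise ValueError(
                f"illegal character {seq[i]!r} at position {i}"
                + (f" in sequence {id!r}" if id else "")
            )
    return UtrSequence(id=id, sequence=upper)


def count_pentamers(seq: str) -> int:
    """Count AUUUA occurrences, overlapping ones included.

    Overlap matters: AUUUAUUUA contains two pentamers sharing the middle A.
    """
    s = seq if isinstance(seq, str) else seq.sequence
    n, start = 0, 0
    while True:
        i = s.find(PENTAMER, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def has_consecutive_pentamers(seq: str) -> bool:
    """True iff two overlapping pentamers (AUUUAUUUA) occur."""
    s = seq if isinstance(seq, str) else seq.sequence
    return CONSECUTIVE_PENTAMER in s


def max_u_run(seq: str) -> int:
    """Length of the longest run of consecutive U's."""
    s = seq if isinstance(seq, str) else seq.sequence
    best = run = 0
    for ch in s:
        if ch == "U":
            run += 1
            if run > best:
                best = run
        else:
            run = 0
    return best


def u_stretch(seq: str, min_len: int = U_STRETCH_MIN) -> bool:
    """True iff the sequence holds a polyU run of >= ``min_len`` nt (inclusive)."""
    return max_u_run(seq) >= min_len


def gc_content(seq: str) -> float:
    """Fraction of G+C over the full sequence length.

    N bases (if admitted at canonicalization) count in the denominator.
    """
    s = seq if isinstance(seq, str) else seq.sequence
    if not s:
        raise ValueError("GC content is undefined for an empty sequence")
    return (s.count("G") + s.count("C")) / len(s)


def classify_are(pentamer_count: int, has_consecutive: bool, has_u_stretch: bool) -> str:
    """Assign the classical ARE class from scanned features.

    Precedence: Class II (overlapping pentamers) over Class I (any scattered
    pentamers; counts above 3 are still Class I) over Class III (U-stretch
    without any pentamer). Sequences with no pentamer and no U-stretch get
    "none".
    """
    if has_consecutive:
        return "II"
    if pentamer_count >= 1:
        return "I"
    if has_u_stretch:
        return "III"
    return "none"


def profile(utr: UtrSequence, u_stretch_min: int = U_STRETCH_MIN) -> AREProfile:
    """Scan one UTR for all ARE features."""
    s = utr.sequence
    count = count_pentamers(s)
    consec = has_consecutive_pentamers(s)
    run = max_u_run(s)
    stretch = run >= u_stretch_min
    return AREProfile(
        id=utr.id,
        length=len(s),
        pentamer_count=count,
        has_consecutive=consec,
        max_u_run=run,
        has_u_stretch=stretch,
        gc=gc_content(s),
        are_class=classify_are(count, consec, stretch),
    )


def shuffle_sequence(seq: str, seed: int | None = None) -> str:
    """Uniform random permutation of the letters (mononucleotide shuffle).

    Composition and length are preserved exactly; this is the composition-
    matched "random" control for motif prevalence.
    """
    s = list(seq if isinstance(seq, str) else seq.sequence)
    _random.Random(seed).shuffle(s)
    return "".join(s)


def build_unbound_control(
    expressed: Iterable[str], enriched: Iterable[str], n: int, seed: int | None = None
) -> list[str]:
    """Sample ``n`` expressed-but-not-enriched genes as a negative control set."""
    pool = sorted(set(expressed) - set(enriched))
    if len(pool) < n:
        raise ValueError(
            f"unbound pool has {len(pool)} genes; cannot sample {n}"
        )
    return sorted(_random.Random(seed).sample(pool, n))


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> ProportionTestResult:
    """Two-sided two-sample proportion test with Yates continuity correction.

    This is the textbook chi-square formulation used by R's ``prop.test``:
    with table margins N = n1 + n2, the corrected statistic is

        X^2 = N (|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d))

    clamped to 0 when the correction exceeds |ad - bc|, and p is the upper
    tail of chi-square with 1 degree of freedom.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("group size must be positive")
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
    a, b = k1, n1 - k1
    c, d = k2, n2 - k2
    n_tot = n1 + n2
    cross = abs(a * d - b * c)
    corrected = max(cross - n_tot / 2.0, 0.0)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        statistic, p = 0.0, 1.0
    else:
        statistic = n_tot * corrected**2 / denom
        p = float(stats.chi2.sf(statistic, df=1))
    return ProportionTestResult(k1=k1, n1=n1, k2=k2, n2=n2, statistic=statistic, p=p)


@dataclass
class GroupAreSummary:
    """Feature prevalence in bound vs control UTR groups, with tests."""

    n_bound: int
    n_control: int
    fractions: dict = field(default_factory=dict)  # feature -> (bound, control)
    tests: dict = field(default_factory=dict)  # feature -> ProportionTestResult
    mean_gc: dict = field(default_factory=dict)  # group -> mean GC fraction


def group_are_summary(
    bound: Sequence[UtrSequence],
    control: Sequence[UtrSequence],
    u_stretch_min: int = U_STRETCH_MIN,
) -> GroupAreSummary:
    """Compare ARE feature prevalence between two UTR groups.

    For each feature (>=1 pentamer, consecutive pentamers, U-stretch, zero
    pentamers) the per-group fraction and a two-sided proportion test are
    reported, together with the mean GC per group.
    """
    if not bound or not control:
        raise ValueError("both groups must be nonempty")
    profs = {
        "bound": [profile(u, u_stretch_min) for u in bound],
        "control": [profile(u, u_stretch_min) for u in control],
    }
    features = {
        "pentamer": lambda p: p.pentamer_count >= 1,
        "consecutive_pentamer": lambda p: p.has_consecutive,
        "u_stretch": lambda p: p.has_u_stretch,
        "no_pentamer": lambda p: p.pentamer_count == 0,
    }
    out = GroupAreSummary(n_bound=len(bound), n_control=len(control))
    for name, pred in features.items():
        k1 = sum(pred(p) for p in profs["bound"])
        k2 = sum(pred(p) for p in profs["control"])
        out.fractions[name] = (k1 / len(bound), k2 / len(control))
        out.tests[name] = proportion_test(k1, len(bound), k2, len(control))
    for grp, ps in profs.items():
        out.mean_gc[grp] = float(np.mean([p.gc for p in ps]))
    return out


def _kmers_in(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def discriminative_kmers(
    positives: Sequence[str],
    negatives: Sequence[str],
    k_min: int = 3,
    k_max: int = 8,
    e_threshold: float = 0.05,
) -> list[KmerMotifResult]:
    """Rank exact k-mers that discriminate the positive from the negative set.

    For every word of length ``k_min``..``k_max`` present in at least one
    sequence, count the number of sequences per set containing it, compute a
    one-sided Fisher exact p (enrichment in positives, hypergeometric tail)
    and a Bonferroni-style E-value = p x (number of words tested). Words with
    E below ``e_threshold`` are returned ranked by E then p then word.

    Only concrete letters are considered (no IUPAC wildcards) — a deliberate
    simplification of heuristic discriminative motif discovery.
    """
    if not positives or not negatives:
        raise ValueError("both sets must be nonempty")
    pos = [s if isinstance(s, str) else s.sequence for s in positives]
    neg = [s if isinstance(s, str) else s.sequence for s in negatives]
    n1, n2 = len(pos), len(neg)

    results: list[KmerMotifResult] = []
    n_tested = 0
    for k in range(k_min, k_max + 1):
        pos_counts: Counter[str] = Counter()
        neg_counts: Counter[str] = Counter()
        for s in pos:
            pos_counts.update(_kmers_in(s, k))
        for s in neg:
            neg_counts.update(_kmers_in(s, k))
        words = set(pos_counts) | set(neg_counts)
        n_tested += len(words)
        for w in words:
            k1, k2 = pos_counts.get(w, 0), neg_counts.get(w, 0)
            # P(X >= k1) with X ~ Hypergeom(N=n1+n2, K=k1+k2, n=n1)
            p = float(stats.hypergeom.sf(k1 - 1, n1 + n2, k1 + k2, n1))
            results.append(
                KmerMotifResult(
                    motif=w, pos_count=k1, pos_total=n1,
                    neg_count=k2, neg_total=n2, p=p, e_value=p,
                )
            )
    scored = [
        KmerMotifResult(
            motif=r.motif, pos_count=r.pos_count, pos_total=r.pos_total,
            neg_count=r.neg_count, neg_total=r.neg_total, p=r.p,
            e_value=min(r.p * n_tested, float("inf")),
        )
        for r in results
    ]
    kept = [r for r in scored if r.e_value < e_threshold]
    kept.sort(key=lambda r: (r.e_value, r.p, r.motif))
    return [
        KmerMotifResult(
            motif=r.motif, pos_count=r.pos_count, pos_total=r.pos_total,
            neg_count=r.neg_count, neg_total=r.neg_total, p=r.p,
            e_value=r.e_value, rank=i + 1,
        )
        for i, r in enumerate(kept)
    ]
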