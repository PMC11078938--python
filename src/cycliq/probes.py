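"""Oligonucleotide probe design for sequential smFISH.

Primary probes are 28-mer substrings of each gene's representative
transcript (the longest isoform) that occur exactly once across the whole
representative transcript set, have 45-65 % GC content, and do not form
highly complementary pairs (an exact match of >= 10 nt to the reverse
complement of another probe).  Genes retaining fewer than 24 candidates
are dropped.  Readout probes are random 15-mers with 40-60 % GC and A/T at
the 5' end, screened against mutual complementarity with the same 10-nt
word rule.  Secondary probes concatenate the complement of a primary probe
with two identical readout-binding units.

An independent validator (`validate_primary_set`, `validate_readout_set`)
re-checks every emitted probe against the stated filters through a
separate, brute-force code path.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import pandas as pd
import numpy as np

__all__ = [
    "TranscriptSet",
    "PrimaryProbe",
    "PrimaryProbeSet",
    "select_longest_isoform",
    "enumerate_primary_candidates",
    "filter_cross_hybridizing",
    "generate_readout_candidates",
    "assemble_secondary",
    "fab_oligo",
    "design_primary_probes",
    "validate_primary_set",
    "validate_readout_set",
    "reverse_complement",
]

log = logging.getLogger(__name__)

PROBE_LENGTH = 28
READOUT_LENGTH = 15
GC_PRIMARY = (0.45, 0.65)
GC_READOUT = (0.40, 0.60)
MIN_PROBES_PER_GENE = 24
WORD_SIZE = 10

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _gc_count(seq: str) -> int:
    return seq.count("G") + seq.count("C")


def _gc_in_range(seq: str, bounds: tuple[float, float]) -> bool:
    """Inclusive GC bounds on the integer G+C count.

    The epsilon keeps boundary counts (e.g. 6/15 at a 40 % bound) inclusive
    despite binary rounding of the percentage limits.
    """
    lo, hi = bounds
    n = len(seq)
    gc = _gc_count(seq)
    return lo * n - 1e-9 <= gc <= hi * n + 1e-9


@dataclass
class TranscriptSet:
    """gene -> representative transcript sequence (uppercase ACGT)."""

    sequences: dict[str, str]
    representative_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"gene {gene}: empty sequence")
            bad = set(seq) - set("ACGT")
            if bad:
                raise ValueError(f"gene {gene}: non-ACGT characters {bad}")

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass(frozen=True)
class PrimaryProbe:
    gene: str
    position: int  # 0-based start on the representative transcript
    sequence: str

    @property
    def gc_fraction(self) -> float:
        return _gc_count(self.sequence) / len(self.sequence)


@dataclass
class PrimaryProbeSet:
    """Per-gene lists of accepted primary probe targets."""

    probes: dict[str, list[PrimaryProbe]]

    def all_probes(self) -> list[PrimaryProbe]:
        return [p for plist in self.probes.values() for p in plist]

    def counts(self) -> dict[str, int]:
        return {g: len(p) for g, p in self.probes.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": p.gene,
                    "position": p.position,
                    "sequence": p.sequence,
                    "gc": p.gc_fraction,
                }
                for p in self.all_probes()
            ],
            columns=["gene", "position", "sequence", "gc"],
        )


def select_longest_isoform(records: dict[str, dict[str, str]]) -> TranscriptSet:
    """Pick one representative transcript per gene: the longest isoform.

    ``records`` maps gene -> {transcript_id: sequence}.  Length ties break
    lexicographically by transcript id (logged); genes without transcripts
    are skipped with a warning.
    """
    sequences: dict[str, str] = {}
    reps: dict[str, str] = {}
    for gene, isoforms in records.items():
        if not isoforms:
            log.warning("gene %s has no transcripts; skipped", gene)
            continue
        best = sorted(isoforms.items(), key=lambda kv: (-len(kv[1]), kv[0]))
        if len(best) > 1 and len(best[0][1]) == len(best[1][1]):
            log.info("gene %s: length tie, picked %s by id order", gene, best[0][0])
        reps[gene] = best[0][0]
        sequences[gene] = best[0][1].upper()
    return TranscriptSet(sequences=sequences, representative_ids=reps)


def _window_occurrences(ts: TranscriptSet, k: int) -> dict[str, int]:
    """Count every k-mer occurrence (overlapping, sense strand) in the set."""
    counts: dict[str, int] = {}
    for seq in ts.sequences.values():
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            counts[w] = counts.get(w, 0) + 1
    return counts


def _apply_min_per_gene(probes: dict[str, list[PrimaryProbe]]) -> dict[str, list[PrimaryProbe]]:
    kept = {}
    for gene, plist in probes.items():
        if len(plist) >= MIN_PROBES_PER_GENE:
            kept[gene] = plist
        else:
            log.info("gene %s dropped: only %d candidates", gene, len(plist))
    return kept


def enumerate_primary_candidates(ts: TranscriptSet) -> PrimaryProbeSet:
    """All unique, GC-passing 28-mer windows; genes with < 24 survivors drop.

    Uniqueness means the 28-mer occurs exactly once (exact match, sense
    strand) across the entire representative transcript set.  Transcripts
    shorter than 28 nt yield no candidates.
    """
    occurrences = _window_occurrences(ts, PROBE_LENGTH)
    per_gene: dict[str, list[PrimaryProbe]] = {}
    for gene, seq in ts.sequences.items():
        if len(seq) < PROBE_LENGTH:
            log.warning("gene %s: transcript shorter than %d nt, no candidates",
                        gene, PROBE_LENGTH)
            per_gene[gene] = []
            continue
        plist = []
        for i in range(len(seq) - PROBE_LENGTH + 1):
            w = seq[i : i + PROBE_LENGTH]
            if occurrences[w] != 1:
                continue
            if not _gc_in_range(w, GC_PRIMARY):
                continue
            plist.append(PrimaryProbe(gene, i, w))
        per_gene[gene] = plist
    return PrimaryProbeSet(probes=_apply_min_per_gene(per_gene))


def _words(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _conflict_graph(seqs: list[str], word_size: int) -> list[set[int]]:
    """Adjacency sets: i ~ j when one contains a >= word_size complement of the other.

    Probe i conflicts with probe j iff some word of i equals a word of
    reverse_complement(j); the relation is symmetric.  Indexed via a word
    table so large candidate sets stay fast.
    """
    word_of: dict[str, set[int]] = {}
    for idx, s in enumerate(seqs):
        for w in _words(s, word_size):
            word_of.setdefault(w, set()).add(idx)
    adj: list[set[int]] = [set() for _ in seqs]
    for idx, s in enumerate(seqs):
        partners: set[int] = set()
        for w in _words(reverse_complement(s), word_size):
            partners |= word_of.get(w, set())
        partners.discard(idx)
        for j in partners:
            adj[idx].add(j)
            adj[j].add(idx)
    return adj


def filter_cross_hybridizing(ps: PrimaryProbeSet, word_size: int = WORD_SIZE) -> PrimaryProbeSet:
    """Remove probes forming complementary pairs at the given word size.

    Conflicted probes are removed greedily, most-conflicted first (ties by
    gene then position, for determinism), until the set is conflict-free;
    the >= 24-per-gene rule is then re-applied.
    """
    probes = ps.all_probes()
    seqs = [p.sequence for p in probes]
    adj = _conflict_graph(seqs, word_size)
    alive = [True] * len(probes)
    degree = [len(a) for a in adj]
    # lazy max-heap on (degree, gene, position); stale entries are skipped
    heap = [
        (-degree[i], probes[i].gene, probes[i].position, i)
        for i in range(len(probes))
        if degree[i] > 0
    ]
    heapq.heapify(heap)
    while heap:
        negd, _, _, i = heapq.heappop(heap)
        if not alive[i] or degree[i] != -negd or degree[i] == 0:
            continue
        alive[i] = False
        for j in adj[i]:
            if alive[j]:
                degree[j] -= 1
                if degree[j] > 0:
                    heapq.heappush(
                        heap, (-degree[j], probes[j].gene, probes[j].position, j)
                    )
    out: dict[str, list[PrimaryProbe]] = {g: [] for g in ps.probes}
    for keep, p in zip(alive, probes):
        if keep:
            out[p.gene].append(p)
    return PrimaryProbeSet(probes=_apply_min_per_gene(out))


def design_primary_probes(records: dict[str, dict[str, str]],
                          word_size: int = WORD_SIZE) -> PrimaryProbeSet:
    """Longest-isoform selection -> candidate enumeration -> cross-hyb filter."""
    ts = select_longest_isoform(records)
    return filter_cross_hybridizing(enumerate_primary_candidates(ts), word_size)


def generate_readout_candidates(
    n_wanted: int,
    seed: int,
    word_size: int = WORD_SIZE,
    max_attempts: int = 200_000,
    screen_against: list[str] | None = None,
) -> list[str]:
    """Seeded random 15-mers passing the readout filters.

    Filters: GC in 40-60 % (inclusive), A or T at the 5' end, and no
    complementary stretch of >= word_size nt against any already-accepted
    probe (or any sequence in ``screen_against``, e.g. a user-supplied
    transcript FASTA).  Generation stops at ``n_wanted`` survivors or after
    ``max_attempts`` draws, in which case the partial set is returned with a
    warning.
    """
    if n_wanted < 1:
        raise ValueError("n_wanted must be >= 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    accepted: list[str] = []
    accepted_words: set[str] = set()
    extra_words: set[str] = set()
    for s in screen_against or []:
        extra_words |= _words(s.upper(), word_size)
    for _ in range(max_attempts):
        if len(accepted) >= n_wanted:
            break
        seq = "".join(bases[rng.integers(0, 4, size=READOUT_LENGTH)])
        if seq[0] not in "AT":
            continue
        if not _gc_in_range(seq, GC_READOUT):
            continue
        rc_words = _words(reverse_complement(seq), word_size)
        # conflict with accepted set in either orientation
        if rc_words & accepted_words:
            continue
        own_words = _words(seq, word_size)
        if any(reverse_complement(w) in accepted_words for w in own_words):
            continue
        if rc_words & extra_words or own_words & {reverse_complement(w) for w in extra_words}:
            continue
        # self-complementarity (hairpin at the word size)
        if rc_words & own_words:
            continue
        accepted.append(seq)
        accepted_words |= own_words
    if len(accepted) < n_wanted:
        log.warning("readout generation: only %d of %d after %d attempts",
                    len(accepted), n_wanted, max_attempts)
    return accepted


def assemble_secondary(primary: str, readout: str, spacer: str = "AAA") -> str:
    """Secondary probe: complement-to-primary region + 2 readout-binding units.

    The 5' region reverse-complements back to the primary target so the
    secondary hybridises to it; the two identical readout-binding units are
    the reverse complement of the readout probe, separated by a short
    spacer.
    """
    unit = reverse_complement(readout)
    return reverse_complement(primary) + spacer + unit + spacer + unit


def fab_oligo(readout: str, leader: str = "A", spacer: str = "AAA",
              trailer: str = "A") -> str:
    """Antibody-conjugated oligo carrying 2x readout-binding units.

    Layout: leader + unit + spacer + unit + trailer with
    unit = revcomp(readout); with the defaults and a 15-nt readout this is
    1 + 15 + 3 + 15 + 1 = 35 nt, the two binding units separated by the
    AAA spacer.
    """
    unit = reverse_complement(readout)
    return leader + unit + spacer + unit + trailer


# ---------------------------------------------------------------------------
# independent validators (deliberately brute force, no shared helpers)


def _count_overlapping(haystack: str, needle: str) -> int:
    n, i = 0, haystack.find(needle)
    while i != -1:
        n += 1
        i = haystack.find(needle, i + 1)
    return n


def validate_primary_set(ps: PrimaryProbeSet, ts: TranscriptSet,
                         word_size: int = WORD_SIZE) -> list[str]:
    """Re-check every stated primary-probe filter by direct scanning.

    Returns a list of human-readable violations (empty = all filters hold):
    length 28, GC in [45 %, 65 %], exactly one occurrence across all
    representative transcripts, >= 24 probes per retained gene, and no
    complementary stretch of >= word_size nt between any pair.
    """
    problems: list[str] = []
    probes = ps.all_probes()
    for p in probes:
        if len(p.sequence) != 28:
            problems.append(f"{p.gene}@{p.position}: length {len(p.sequence)}")
        gc = sum(1 for b in p.sequence if b in "GC")
        if not (0.45 * 28 - 1e-9 <= gc <= 0.65 * 28 + 1e-9):
            problems.append(f"{p.gene}@{p.position}: GC {gc}/28 out of range")
        hits = sum(_count_overlapping(seq, p.sequence) for seq in ts.sequences.values())
        if hits != 1:
            problems.append(f"{p.gene}@{p.position}: {hits} occurrences")
    for gene, plist in ps.probes.items():
        if len(plist) < 24:
            problems.append(f"{gene}: only {len(plist)} probes retained")
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i, a in enumerate(probes):
        for b in probes[i + 1 :]:
            rc_b = "".join(comp[x] for x in reversed(b.sequence))
            for s in range(len(a.sequence) - word_size + 1):
                if a.sequence[s : s + word_size] in rc_b:
                    problems.append(
                        f"{a.gene}@{a.position} ~ {b.gene}@{b.position}: "
                        f"complementary {word_size}-mer"
                    )
                    break
    return problems


def validate_readout_set(readouts: list[str], word_size: int = WORD_SIZE) -> list[str]:
    """Re-check the readout filters: 15 nt, GC 40-60 %, 5' A/T, no pairwise
    (or self) complementary stretch of >= word_size nt."""
    problems: list[str] = []
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i, s in enumerate(readouts):
        if len(s) != 15:
            problems.append(f"readout {i}: length {len(s)}")
        gc = sum(1 for b in s if b in "GC")
        if not (0.40 * 15 - 1e-9 <= gc <= 0.60 * 15 + 1e-9):
            problems.append(f"readout {i}: GC {gc}/15 out of range")
        if s[0] not in "AT":
            problems.append(f"readout {i}: 5' base {s[0]}")
    for i, a in enumerate(readouts):
        for j in range(i, len(readouts)):
            b = readouts[j]
            rc_b = "".join(comp[x] for x in reversed(b))
            for s in range(len(a) - word_size + 1):
                if a[s : s + word_size] in rc_b:
                    problems.append(f"readouts {i} ~ {j}: complementary {word_size}-mer")
                    break
    return problems
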