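"""Detection of perfect tandem repeats (microsatellites) in nucleotide sequences.

The scanner reports *maximal perfect* repeats of a fixed unit length
(trinucleotides by default, ten or more repeat units), deduplicates marker
candidates by their flanking sequences, and checks whether a PCR amplicon in a
configured size window (100-300 bp by default) is feasible around each locus.

Coordinates are 0-based half-open throughout. Compound or interrupted repeats
are never merged: a single mismatch or an ``N`` terminates a run.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGTN")


class InvalidSequenceError(ValueError):
    """The input contains characters other than A, C, G, T or N."""


@dataclass(frozen=True)
class SSRLocus:
    """A maximal perfect tandem repeat on one input sequence.

    ``start``/``end`` delimit the repeat tract (0-based half-open), so
    ``end - start == len(motif) * n_repeats``.
    """

    seq_id: str
    motif: str
    n_repeats: int
    start: int
    end: int

    @property
    def canonical_motif(self) -> str:
        return canonical_motif(self.motif)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class MarkerCandidate:
    """An SSR locus with its flanking sequence and amplicon feasibility.

    ``duplicate_of`` points at the index (in mining order) of an earlier
    candidate with identical flanks, or is ``None`` for unique candidates.
    """

    locus: SSRLocus
    left_flank: str = ""
    right_flank: str = ""
    amplicon_feasible: bool = True
    duplicate_of: Optional[int] = None


@dataclass(frozen=True)
class MiningConfig:
    motif_length: int = 3
    min_repeats: int = 10
    flank_len: int = 50
    amplicon_min: int = 100
    amplicon_max: int = 300


def _is_primitive(unit: str) -> bool:
    """True when ``unit`` is not a whole-number repetition of a shorter word."""
    m = len(unit)
    for d in range(1, m):
        if m % d == 0 and unit == unit[:d] * (m // d):
            return False
    return True


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_motif(motif: str) -> str:
    """Standardized motif class: the lexicographic minimum over all cyclic
    rotations of the motif and of its reverse complement.

    Two loci whose units are rotations or strand-flips of one another (e.g.
    ``TGA`` and ``TCA``) therefore share one canonical class (``ATC``).
    """
    if len(motif) != 3:
        raise ValueError(f"canonical_motif expects a trinucleotide, got {motif!r}")
    if not set(motif) <= frozenset("ACGT"):
        raise InvalidSequenceError(f"invalid motif {motif!r}")
    variants = []
    for word in (motif, reverse_complement(motif)):
        variants.extend(word[i:] + word[:i] for i in range(len(word)))
    return min(variants)


def _segment_candidates(
    seq: str, offset: int, motif_length: int, min_repeats: int
) -> Iterable[tuple[int, int]]:
    """Yield (start, n_repeats) for every maximal repeat phase in an N-free
    segment. Several phases of one repeat tract overlap; greedy selection in
    :func:`find_ssrs` keeps the leftmost-longest representative.
    """
    m = motif_length
    n = len(seq)
    if n < m * min_repeats:
        return
    match = [seq[j] == seq[j + m] for j in range(n - m)]
    j = 0
    while j < len(match):
        if not match[j]:
            j += 1
            continue
        run_start = j
        while j < len(match) and match[j]:
            j += 1
        region_len = (j - run_start) + m  # repeat tract including last unit
        for phase in range(m):
            n_rep = (region_len - phase) // m
            if n_rep < min_repeats:
                continue
            start = run_start + phase
            unit = seq[start : start + m]
            if not _is_primitive(unit):
                continue
            end = start + m * n_rep
            # maximality guard: a full extra unit on either side disqualifies
            if start - m >= 0 and seq[start - m : start] == unit:
                continue
            if end + m <= n and seq[end : end + m] == unit:
                continue
            yield offset + start, n_rep


def find_ssrs(
    sequence: str,
    motif_length: int = 3,
    min_repeats: int = 10,
    seq_id: str = "",
) -> list[SSRLocus]:
    """Scan one sequence for maximal perfect repeats of ``motif_length``-bp units.

    Returns non-overlapping loci left to right (greedy leftmost-longest: at a
    given start the longest phase wins and absorbs shorter overlapping
    phases). Runs containing ``N`` are broken at the ``N``; units reducible to
    a shorter period (homopolymers, for trinucleotides) are excluded.
    """
    if motif_length < 1:
        raise ValueError("motif_length must be >= 1")
    if min_repeats < 2:
        raise ValueError("min_repeats must be >= 2")
    seq = sequence.upper()
    if not set(seq) <= _VALID:
        bad = sorted(set(seq) - _VALID)
        raise InvalidSequenceError(f"invalid characters in sequence: {bad}")

    candidates: list[tuple[int, int]] = []
    pos = 0
    for segment in seq.split("N"):
        if len(segment) >= motif_length * min_repeats:
            candidates.extend(
                _segment_candidates(segment, pos, motif_length, min_repeats)
            )
        pos += len(segment) + 1

    candidates.sort(key=lambda c: (c[0], -c[1]))
    loci: list[SSRLocus] = []
    cursor = 0
    for start, n_rep in candidates:
        if start < cursor:
            continue
        end = start + motif_length * n_rep
        loci.append(
            SSRLocus(
                seq_id=seq_id,
                motif=seq[start : start + motif_length],
                n_repeats=n_rep,
                start=start,
                end=end,
            )
        )
        cursor = end
    return loci


def extract_candidate(
    sequence: str, locus: SSRLocus, config: MiningConfig
) -> MarkerCandidate:
    """Attach flanks and amplicon feasibility to a detected locus.

    A candidate is amplicon-feasible when the repeat tract itself fits under
    ``amplicon_max`` and the tract plus the *available* flanking sequence (up
    to ``flank_len`` per side) reaches ``amplicon_min``.
    """
    left = sequence[max(0, locus.start - config.flank_len) : locus.start].upper()
    right = sequence[locus.end : locus.end + config.flank_len].upper()
    repeat_len = len(locus)
    feasible = repeat_len <= config.amplicon_max and (
        repeat_len + len(left) + len(right) >= config.amplicon_min
    )
    return MarkerCandidate(
        locus=locus, left_flank=left, right_flank=right, amplicon_feasible=feasible
    )


def dedupe_candidates(
    candidates: Sequence[MarkerCandidate], flank_len: int
) -> list[MarkerCandidate]:
    """Mark candidates whose flank pair exactly matches an earlier candidate.

    Flanks are compared over at most ``flank_len`` bases adjacent to the
    repeat. Order is preserved; unique candidates keep ``duplicate_of=None``.
    """
    if flank_len <= 0:
        raise ValueError("flank_len must be positive")
    seen: dict[tuple[str, str], int] = {}
    out: list[MarkerCandidate] = []
    for i, cand in enumerate(candidates):
        key = (cand.left_flank[-flank_len:], cand.right_flank[:flank_len])
        if key in seen:
            out.append(replace_duplicate(cand, seen[key]))
        else:
            seen[key] = i
            out.append(replace_duplicate(cand, None))
    return out


def replace_duplicate(cand: MarkerCandidate, dup: Optional[int]) -> MarkerCandidate:
    return MarkerCandidate(
        locus=cand.locus,
        left_flank=cand.left_flank,
        right_flank=cand.right_flank,
        amplicon_feasible=cand.amplicon_feasible,
        duplicate_of=dup,
    )


def mine_fasta(fasta_path: str | Path, config: MiningConfig = MiningConfig()) -> list[MarkerCandidate]:
    """Mine every record of a FASTA file and return deduplicated candidates.

    Record ids are taken up to the first whitespace. Deterministic: the same
    file and configuration always yield the same candidate list.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise IOError(f"FASTA file not found: {path}")
    candidates: list[MarkerCandidate] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        try:
            loci = find_ssrs(
                seq,
                motif_length=config.motif_length,
                min_repeats=config.min_repeats,
                seq_id=record.id,
            )
        except InvalidSequenceError as exc:
            raise IOError(f"record {record.id}: {exc}") from exc
        for locus in loci:
            candidates.append(extract_candidate(seq, locus, config))
    return dedupe_candidates(candidates, config.flank_len)


def write_candidates(candidates: Sequence[MarkerCandidate], path: str | Path) -> None:
    """Write a TSV marker-candidate table."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "seq_id",
                "start",
                "end",
                "motif",
                "canonical_motif",
                "n_repeats",
                "amplicon_feasible",
                "duplicate_of",
            ]
        )
        for cand in candidates:
            loc = cand.locus
            writer.writerow(
                [
                    loc.seq_id,
                    loc.start,
                    loc.end,
                    loc.motif,
                    loc.canonical_motif,
                    loc.n_repeats,
                    int(cand.amplicon_feasible),
                    "" if cand.duplicate_of is None else cand.duplicate_of,
                ]
            )
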