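"""Diversity statistics, identity analysis, error rates, transferability and marker QC.

Statistics are locus-wise and group-wise over a :class:`~ssrmarkers.genotypes.GenotypeMatrix`:

- ``k`` — number of distinct alleles observed in the group;
- ``Ho`` — observed heterozygosity, heterozygous calls / typed calls;
- ``He`` — expected heterozygosity, ``1 - sum(p_i^2)``;
- ``PIC`` — polymorphic information content (Botstein form),
  ``1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``;
- ``pID`` — probability that two random individuals share a multilocus
  genotype under Hardy-Weinberg and locus independence, with the sibling
  variant ``pID_sib`` as the conservative upper bound for related material;
- ``e_a``/``e_l`` — genotyping error rate per allele (``m_a / 2nt``) and per
  locus (``m_l / nt``) between a reference and a replicate typing of the same
  accessions.

Identity analysis compares every accession pair and counts pairs whose total
allelic mismatch over shared loci is at most ``t`` for ``t = 0..max_t``;
profiles unmatched at ``t = 0`` are the unique profiles of the panel.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ssrmarkers.genotypes import MISSING, GenotypeMatrix, PeakTable


class UndefinedLocusError(ValueError):
    """All calls for a locus are missing within the requested group."""


@dataclass
class AlleleFrequencyTable:
    locus: str
    freqs: dict[str, float]
    n_typed: int

    def __post_init__(self):
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.locus}: frequencies sum to {total}, not 1")

    @property
    def k(self) -> int:
        return len(self.freqs)


@dataclass
class LocusSummary:
    locus: str
    group: str
    k: int
    Ho: float
    He: float
    PIC: float


def _group_ids(matrix: GenotypeMatrix, accession_ids: Optional[Iterable[str]]) -> list[str]:
    if accession_ids is None:
        return matrix.accession_ids
    ids = list(accession_ids)
    unknown = set(ids) - set(matrix.accession_ids)
    if unknown:
        raise KeyError(f"unknown accession ids: {sorted(unknown)}")
    return ids


def allele_frequencies(
    matrix: GenotypeMatrix,
    locus: str,
    accession_ids: Optional[Iterable[str]] = None,
) -> AlleleFrequencyTable:
    """Allele frequencies at one locus over a group of accessions.

    Both alleles of every non-missing call are counted (a homozygote
    contributes two copies); missing calls are excluded from the denominator.
    """
    ids = _group_ids(matrix, accession_ids)
    counts: Counter[str] = Counter()
    n_typed = 0
    for aid in ids:
        call = matrix.call(aid, locus)
        if call is MISSING:
            continue
        counts.update(call)
        n_typed += 1
    if n_typed == 0:
        raise UndefinedLocusError(f"locus {locus}: no non-missing calls in group")
    total = 2 * n_typed
    freqs = {allele: counts[allele] / total for allele in sorted(counts)}
    return AlleleFrequencyTable(locus=locus, freqs=freqs, n_typed=n_typed)


def pic_from_freqs(freqs: Sequence[float]) -> float:
    """Botstein polymorphic information content of one frequency vector."""
    p = np.asarray(list(freqs), dtype=float)
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    return 1.0 - s2 - (s2**2 - s4)


def expected_heterozygosity(freqs: Sequence[float]) -> float:
    p = np.asarray(list(freqs), dtype=float)
    return 1.0 - float(np.sum(p**2))


def locus_summary(
    matrix: GenotypeMatrix,
    locus: str,
    accession_ids: Optional[Iterable[str]] = None,
    group: str = "",
) -> LocusSummary:
    """k, Ho, He and PIC for one locus over a group."""
    ids = _group_ids(matrix, accession_ids)
    table = allele_frequencies(matrix, locus, ids)
    n_het = 0
    for aid in ids:
        call = matrix.call(aid, locus)
        if call is not MISSING and call[0] != call[1]:
            n_het += 1
    p = list(table.freqs.values())
    return LocusSummary(
        locus=locus,
        group=group,
        k=table.k,
        Ho=n_het / table.n_typed,
        He=expected_heterozygosity(p),
        PIC=pic_from_freqs(p),
    )


def column_summary(values: Sequence[float]) -> dict[str, float]:
    """Summary row logic shared by :func:`group_report`: sum, mean, median, range.

    The median is the middle order statistic for odd counts and the midpoint
    of the two central values for even counts.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty column")
    return {
        "sum": float(arr.sum()),
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def group_report(
    matrix: GenotypeMatrix, groups: dict[str, Sequence[str]]
) -> pd.DataFrame:
    """Per-locus k/Ho/He/PIC for each accession group, with summary rows.

    ``groups`` maps a group name to the accession ids it contains. The output
    has one row per (group, locus) plus ``mean`` and ``median`` rows per group
    (locus column set to the statistic's name).
    """
    rows = []
    for name, ids in groups.items():
        ids = list(ids)
        if not ids:
            raise ValueError(f"group {name!r} is empty")
        summaries = [
            locus_summary(matrix, locus, ids, group=name) for locus in matrix.loci
        ]
        for s in summaries:
            rows.append(
                {"group": name, "locus": s.locus, "k": s.k, "Ho": s.Ho, "He": s.He, "PIC": s.PIC}
            )
        for stat in ("mean", "median"):
            rows.append(
                {
                    "group": name,
                    "locus": stat,
                    "k": column_summary([s.k for s in summaries])[stat],
                    "Ho": column_summary([s.Ho for s in summaries])[stat],
                    "He": column_summary([s.He for s in summaries])[stat],
                    "PIC": column_summary([s.PIC for s in summaries])[stat],
                }
            )
    return pd.DataFrame(rows, columns=["group", "locus", "k", "Ho", "He", "PIC"])


def allele_mismatch(call1: tuple[str, str], call2: tuple[str, str]) -> int:
    """Number of allelic mismatches between two unordered diploid calls (0-2).

    Computed as 2 minus the multiset intersection of the two allele pairs, so
    a homozygote vs. a heterozygote sharing one allele counts one mismatch.
    """
    shared = sum((Counter(call1) & Counter(call2)).values())
    return 2 - shared


@dataclass
class IdentityReport:
    """Mismatch-tolerant profile matching over all accession pairs."""

    max_t: int
    min_shared_loci: int
    matching_pairs: dict[int, list[tuple[str, str]]]
    incomparable_pairs: list[tuple[str, str]]
    n_accessions: int

    @property
    def pair_counts(self) -> dict[int, int]:
        return {t: len(pairs) for t, pairs in self.matching_pairs.items()}

    @property
    def n_unique_profiles(self) -> int:
        matched = {a for pair in self.matching_pairs[0] for a in pair}
        return self.n_accessions - len(matched)


def identity_analysis(
    matrix: GenotypeMatrix, max_t: int = 5, min_shared_loci: int = 10
) -> IdentityReport:
    """Paired comparison of every accession with 0..``max_t`` allowed mismatches.

    A pair matches at threshold ``t`` when the summed allelic mismatch over
    loci typed in both accessions is at most ``t``; pairs sharing fewer than
    ``min_shared_loci`` typed loci are reported as incomparable instead.
    Matching-pair counts are therefore non-decreasing in ``t``.
    """
    ids = matrix.accession_ids
    if len(ids) < 2:
        raise ValueError("identity analysis needs at least 2 accessions")
    matching: dict[int, list[tuple[str, str]]] = {t: [] for t in range(max_t + 1)}
    incomparable: list[tuple[str, str]] = []
    for a, b in itertools.combinations(ids, 2):
        shared = 0
        mismatches = 0
        for locus in matrix.loci:
            ca, cb = matrix.call(a, locus), matrix.call(b, locus)
            if ca is MISSING or cb is MISSING:
                continue
            shared += 1
            mismatches += allele_mismatch(ca, cb)
        if shared < min_shared_loci:
            incomparable.append((a, b))
            continue
        for t in range(max_t + 1):
            if mismatches <= t:
                matching[t].append((a, b))
    return IdentityReport(
        max_t=max_t,
        min_shared_loci=min_shared_loci,
        matching_pairs=matching,
        incomparable_pairs=incomparable,
        n_accessions=len(ids),
    )


@dataclass
class PIdentityReport:
    per_locus: dict[str, float]
    per_locus_sib: dict[str, float]
    overall: float
    overall_sib: float


def p_identity(freq_tables: Sequence[AlleleFrequencyTable]) -> PIdentityReport:
    """Probability of identity across loci under HWE and independence.

    Per locus ``pID = sum p_i^4 + sum_{i<j} (2 p_i p_j)^2``; the sibling
    variant follows Evanno/Waits,
    ``pID_sib = 0.25 + 0.5 s2 + 0.5 s2^2 - 0.25 s4`` with ``s2 = sum p_i^2``
    and ``s4 = sum p_i^4``. Overall values are products across loci.
    """
    if not freq_tables:
        raise ValueError("p_identity needs at least one locus")
    per_locus: dict[str, float] = {}
    per_locus_sib: dict[str, float] = {}
    for table in freq_tables:
        p = np.asarray(list(table.freqs.values()), dtype=float)
        s2 = float(np.sum(p**2))
        s4 = float(np.sum(p**4))
        per_locus[table.locus] = 2 * s2**2 - s4
        per_locus_sib[table.locus] = 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4
    return PIdentityReport(
        per_locus=per_locus,
        per_locus_sib=per_locus_sib,
        overall=float(np.prod(list(per_locus.values()))),
        overall_sib=float(np.prod(list(per_locus_sib.values()))),
    )


@dataclass
class ErrorReport:
    """Per-locus and mean genotyping error rates between reference and replicate."""

    per_locus: pd.DataFrame  # columns locus, n, m_a, m_l, e_a, e_l
    t: int

    @property
    def mean_e_a(self) -> float:
        usable = self.per_locus[self.per_locus["n"] > 0]
        return float(usable["e_a"].mean())

    @property
    def mean_e_l(self) -> float:
        usable = self.per_locus[self.per_locus["n"] > 0]
        return float(usable["e_l"].mean())


def error_rates(
    reference: GenotypeMatrix, replicate: GenotypeMatrix, t: int = 1
) -> ErrorReport:
    """Error rate per allele (``e_a = m_a/2nt``) and per locus (``e_l = m_l/nt``).

    Per locus, over accessions typed in at least one dataset: if both calls
    are present, ``m_a`` grows by their allelic mismatch and ``m_l`` by one
    when any mismatch occurred; a call missing in exactly one dataset is an
    amplification-failure error and counts as a full locus error
    (``m_l += 1``, ``m_a += 2``). Accessions missing in both datasets are
    excluded from ``n``. Means are unweighted over loci with ``n > 0``.
    """
    shared_ids = [a for a in reference.accession_ids if a in set(replicate.accession_ids)]
    if not shared_ids:
        raise ValueError("reference and replicate share no accessions")
    shared_loci = [l for l in reference.loci if l in set(replicate.loci)]
    if not shared_loci:
        raise ValueError("reference and replicate share no loci")
    rows = []
    for locus in shared_loci:
        n = m_a = m_l = 0
        for aid in shared_ids:
            ref_call = reference.call(aid, locus)
            rep_call = replicate.call(aid, locus)
            if ref_call is MISSING and rep_call is MISSING:
                continue
            n += 1
            if ref_call is MISSING or rep_call is MISSING:
                m_a += 2
                m_l += 1
                continue
            mm = allele_mismatch(ref_call, rep_call)
            m_a += mm
            m_l += int(mm > 0)
        e_a = m_a / (2 * n * t) if n else float("nan")
        e_l = m_l / (n * t) if n else float("nan")
        rows.append({"locus": locus, "n": n, "m_a": m_a, "m_l": m_l, "e_a": e_a, "e_l": e_l})
    return ErrorReport(per_locus=pd.DataFrame(rows), t=t)


@dataclass
class TransferabilityMatrix:
    """Marker x species x lab amplification calls with an AND consensus.

    A marker counts as transferable to a species only when it amplified in
    every lab (conservative both-labs rule).
    """

    data: pd.DataFrame  # columns marker, species, lab, amplified (bool)

    def __post_init__(self):
        required = {"marker", "species", "lab", "amplified"}
        if not required <= set(self.data.columns):
            raise ValueError(f"transferability table needs columns {sorted(required)}")

    @property
    def markers(self) -> list[str]:
        return sorted(self.data["marker"].unique())

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    def consensus(self) -> pd.DataFrame:
        """Marker x species boolean table: amplified in every lab."""
        pivot = self.data.pivot_table(
            index="marker", columns="species", values="amplified", aggfunc="all"
        )
        return pivot.fillna(False).astype(bool)


def read_transferability(path) -> TransferabilityMatrix:
    df = pd.read_csv(path)
    df["amplified"] = df["amplified"].astype(bool)
    return TransferabilityMatrix(data=df)


def _genus(species: str) -> str:
    return species.split()[0].rstrip(".")


def transferability_summary(
    tm: TransferabilityMatrix, focal_species: Sequence[str]
) -> dict:
    """Cross-species transferability percentages over a focal congener set.

    Reports, over all markers and the focal species (usually the congeners of
    the source species): the percentage amplifying in every focal species, in
    all but one, in at least one, and the percentage amplifying in at least
    one species of *every* genus in the panel (cross-genus transfer). The
    per-species counts use the both-labs consensus. Percentages are rounded
    to 2 decimals.
    """
    consensus = tm.consensus()
    n_markers = len(consensus.index)
    focal = [s for s in focal_species if s in consensus.columns]
    if not focal:
        raise ValueError("no focal species present in the transferability table")
    focal_counts = consensus[focal].sum(axis=1)
    n_focal = len(focal)

    genera: dict[str, list[str]] = {}
    for sp in consensus.columns:
        genera.setdefault(_genus(sp), []).append(sp)
    across_genera = sum(
        all(consensus.loc[m, members].any() for members in genera.values())
        for m in consensus.index
    )

    def pct(count: int) -> float:
        return round(100.0 * count / n_markers, 2)

    return {
        "n_markers": n_markers,
        "per_species_counts": consensus.sum(axis=0).to_dict(),
        "pct_all_focal": pct(int((focal_counts == n_focal).sum())),
        "pct_all_but_one_focal": pct(int((focal_counts >= n_focal - 1).sum())),
        "pct_at_least_one_focal": pct(int((focal_counts >= 1).sum())),
        "pct_across_genera": pct(int(across_genera)),
    }


def marker_qc(
    matrix: GenotypeMatrix,
    peak_table: Optional[PeakTable] = None,
    focal_accessions: Optional[Sequence[str]] = None,
    min_alleles: int = 3,
    max_het_fraction: float = 0.5,
) -> pd.DataFrame:
    """Quality screen of markers against single-locus plausibility rules.

    Fail reasons per marker: ``MULTIPEAK`` (any sample with three or more
    peaks, indicating multi-locus amplification), ``LOW_POLYMORPHISM``
    (fewer than ``min_alleles`` alleles in the focal group) and
    ``IMPLAUSIBLE_HET`` (heterozygote fraction above ``max_het_fraction`` in
    material expected to be highly inbred). Markers failing no rule pass.
    """
    ids = _group_ids(matrix, focal_accessions)
    if not ids:
        raise ValueError("focal group is empty")
    multipeak_loci: set[str] = set()
    if peak_table is not None and len(peak_table.rows):
        for _, row in peak_table.rows.iterrows():
            if len(row["sizes"]) >= 3:
                multipeak_loci.add(row["locus"])
    rows = []
    for locus in matrix.loci:
        reasons = []
        if locus in multipeak_loci:
            reasons.append("MULTIPEAK")
        try:
            summary = locus_summary(matrix, locus, ids)
        except UndefinedLocusError:
            reasons.append("NO_DATA")
        else:
            if summary.k < min_alleles:
                reasons.append("LOW_POLYMORPHISM")
            if summary.Ho > max_het_fraction:
                reasons.append("IMPLAUSIBLE_HET")
        rows.append(
            {"marker": locus, "passed": not reasons, "reasons": ";".join(reasons)}
        )
    return pd.DataFrame(rows, columns=["marker", "passed", "reasons"])
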