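"""Codominant diploid genotype tables, peak-call collapsing and allele binning.

Genotype calls are unordered pairs of locus-scoped allele labels (strings,
conventionally the nominal fragment size in bp). A homozygote carries the same
label twice; a failed amplification is :data:`MISSING`. Fragment sizes read
off a capillary instrument are converted to allele labels by binning against
an *allelic ladder*: the ordered list of nominal allele sizes of a locus,
spaced by the repeat-unit length (3 bp for trinucleotide markers).

On-disk genotype tables are wide CSVs: one row per accession, columns
``accession,species,group`` followed by two columns per locus named
``LOCUS.1``/``LOCUS.2``; missing alleles are coded ``0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

MISSING = None


class _MultipeakType:
    """Sentinel for a sample with three or more peaks at one locus."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MULTIPEAK"


MULTIPEAK = _MultipeakType()

Call = Optional[tuple[str, str]]


class FormatError(ValueError):
    """A genotype or peak file violates the expected layout."""


class LadderConflictError(ValueError):
    """Two ladder rungs are too close to be distinguished at the binning tolerance."""


class OffLadderError(ValueError):
    """An observed fragment size does not match any ladder rung."""


@dataclass(frozen=True)
class Accession:
    id: str
    species: str = ""
    group: str = ""


class GenotypeMatrix:
    """Accessions x loci table of unordered diploid allele-pair calls.

    Calls are stored as sorted 2-tuples of allele labels or ``None`` for
    missing data. Allele labels are locus-scoped strings.
    """

    def __init__(
        self,
        accessions: Sequence[Accession],
        loci: Sequence[str],
        calls: dict[tuple[str, str], Call],
    ):
        ids = [a.id for a in accessions]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicated accession ids")
        self.accessions = list(accessions)
        self.loci = list(loci)
        self._calls: dict[tuple[str, str], Call] = {}
        for (aid, locus), call in calls.items():
            self._calls[(aid, locus)] = self._normalize(call)

    @staticmethod
    def _normalize(call: Call) -> Call:
        if call is MISSING:
            return MISSING
        if len(call) != 2:
            raise FormatError(f"a diploid call needs exactly 2 alleles, got {call!r}")
        a, b = call
        return (str(a), str(b)) if str(a) <= str(b) else (str(b), str(a))

    @property
    def accession_ids(self) -> list[str]:
        return [a.id for a in self.accessions]

    def call(self, accession_id: str, locus: str) -> Call:
        return self._calls.get((accession_id, locus), MISSING)

    def set_call(self, accession_id: str, locus: str, call: Call) -> None:
        self._calls[(accession_id, locus)] = self._normalize(call)

    def subset(self, accession_ids: Iterable[str]) -> "GenotypeMatrix":
        wanted = list(accession_ids)
        missing = set(wanted) - set(self.accession_ids)
        if missing:
            raise KeyError(f"unknown accession ids: {sorted(missing)}")
        keep = [a for a in self.accessions if a.id in set(wanted)]
        calls = {
            (a.id, l): self.call(a.id, l) for a in keep for l in self.loci
        }
        return GenotypeMatrix(keep, self.loci, calls)

    def group_members(self, group: str) -> list[str]:
        return [a.id for a in self.accessions if a.group == group]

    def species_members(self, species: str) -> list[str]:
        return [a.id for a in self.accessions if a.species == species]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.accessions, self.loci, dict(self._calls))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.accessions == other.accessions
            and self.loci == other.loci
            and all(
                self.call(a.id, l) == other.call(a.id, l)
                for a in self.accessions
                for l in self.loci
            )
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({len(self.accessions)} accessions x {len(self.loci)} loci)"


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a wide genotype CSV (two allele columns per locus, ``0`` = missing)."""
    df = pd.read_csv(path, dtype=str)
    cols = list(df.columns)
    df[cols[:3]] = df[cols[:3]].fillna("")
    df[cols[3:]] = df[cols[3:]].fillna("0")
    if cols[:3] != ["accession", "species", "group"]:
        raise FormatError(
            f"{path}: expected leading columns accession,species,group, got {cols[:3]}"
        )
    allele_cols = cols[3:]
    if len(allele_cols) % 2 != 0:
        raise FormatError(f"{path}: odd number of allele columns ({len(allele_cols)})")
    loci = []
    for i in range(0, len(allele_cols), 2):
        c1, c2 = allele_cols[i], allele_cols[i + 1]
        if not (c1.endswith(".1") and c2.endswith(".2") and c1[:-2] == c2[:-2]):
            raise FormatError(f"{path}: columns {c1!r}/{c2!r} are not a LOCUS.1/LOCUS.2 pair")
        loci.append(c1[:-2])
    if df["accession"].duplicated().any():
        dups = df.loc[df["accession"].duplicated(), "accession"].tolist()
        raise FormatError(f"{path}: duplicated accession ids {dups}")

    accessions = [
        Accession(id=row["accession"], species=row["species"], group=row["group"])
        for _, row in df.iterrows()
    ]
    calls: dict[tuple[str, str], Call] = {}
    for ridx, row in df.iterrows():
        for locus in loci:
            a1 = row[f"{locus}.1"].strip()
            a2 = row[f"{locus}.2"].strip()
            if a1 == "0" and a2 == "0":
                calls[(row["accession"], locus)] = MISSING
            elif a1 == "0" or a2 == "0":
                raise FormatError(
                    f"{path}: row {ridx + 2}, locus {locus}: half-missing call {a1}/{a2}"
                )
            else:
                calls[(row["accession"], locus)] = (a1, a2)
    return GenotypeMatrix(accessions, loci, calls)


def write_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the canonical wide CSV; ``read_genotypes`` inverts it exactly."""
    header = ["accession", "species", "group"]
    for locus in matrix.loci:
        header += [f"{locus}.1", f"{locus}.2"]
    rows = []
    for acc in matrix.accessions:
        row = [acc.id, acc.species, acc.group]
        for locus in matrix.loci:
            call = matrix.call(acc.id, locus)
            row += ["0", "0"] if call is MISSING else list(call)
        rows.append(row)
    pd.DataFrame(rows, columns=header).to_csv(path, index=False)


def call_genotype_from_peaks(sizes: Sequence[float]):
    """Collapse a per-sample per-locus peak list into a diploid call.

    No peak means amplification failure (:data:`MISSING`); one peak is taken as
    a homozygote (null alleles are undetectable with codominant scoring); two
    peaks form a heterozygote; three or more peaks flag probable multi-locus
    amplification (:data:`MULTIPEAK`) and disqualify the sample.
    """
    if len(sizes) == 0:
        return MISSING
    if len(sizes) == 1:
        return (sizes[0], sizes[0])
    if len(sizes) == 2:
        return tuple(sorted(sizes))
    return MULTIPEAK


@dataclass
class AllelicLadder:
    """Nominal allele sizes of one locus, used to bin observed fragment sizes."""

    locus: str
    nominal_sizes: list[float]
    step: float = 3.0
    tolerance: float = 1.0

    def __post_init__(self):
        if not self.nominal_sizes:
            raise ValueError(f"{self.locus}: ladder needs at least one rung")
        if any(b <= a for a, b in zip(self.nominal_sizes, self.nominal_sizes[1:])):
            raise ValueError(f"{self.locus}: nominal sizes must be strictly increasing")
        if not self.tolerance < self.step / 2:
            raise ValueError(
                f"{self.locus}: tolerance {self.tolerance} must be < step/2 = {self.step / 2}"
            )


def build_ladder(
    sizes: Sequence[float],
    locus: str = "",
    step: float = 3.0,
    min_support: int = 1,
    tolerance: float = 1.0,
) -> AllelicLadder:
    """Cluster observed fragment sizes into ladder rungs.

    Single-linkage clustering in one dimension: sorted sizes are merged while
    the gap to the next size is below ``step/2``. Each rung's nominal size is
    the median of its members rounded to 0.1 bp; rungs with fewer than
    ``min_support`` members are dropped.
    """
    if len(sizes) == 0:
        raise ValueError("build_ladder needs at least one observed size")
    ordered = sorted(float(s) for s in sizes)
    clusters: list[list[float]] = [[ordered[0]]]
    for s in ordered[1:]:
        if s - clusters[-1][-1] < step / 2:
            clusters[-1].append(s)
        else:
            clusters.append([s])
    clusters = [c for c in clusters if len(c) >= min_support]
    if not clusters:
        raise ValueError("no ladder rung reaches min_support")
    nominal = [round(_median(c), 1) for c in clusters]
    for a, b in zip(nominal, nominal[1:]):
        if b - a < tolerance:
            raise LadderConflictError(
                f"{locus}: rungs {a} and {b} are closer than the tolerance {tolerance}"
            )
    return AllelicLadder(locus=locus, nominal_sizes=nominal, step=step, tolerance=tolerance)


def _median(values: Sequence[float]) -> float:
    ordered = sorted(values)
    n = len(ordered)
    mid = n // 2
    return ordered[mid] if n % 2 else (ordered[mid - 1] + ordered[mid]) / 2


def bin_size(size: float, ladder: AllelicLadder) -> str:
    """Assign an observed size to the nearest ladder rung within tolerance.

    The allele label is the nominal size rounded to an integer. Midpoint ties
    between two rungs go to the lower rung. Sizes outside the tolerance raise
    :class:`OffLadderError` so new or artifact alleles are never silently
    assigned.
    """
    best = None
    best_diff = math.inf
    for nominal in ladder.nominal_sizes:  # ties resolve to the lower rung
        diff = abs(size - nominal)
        if diff < best_diff:
            best, best_diff = nominal, diff
    if best_diff > ladder.tolerance:
        raise OffLadderError(
            f"{ladder.locus}: size {size} is off-ladder (nearest rung {best}, "
            f"diff {best_diff:.2f} > tolerance {ladder.tolerance})"
        )
    return str(int(math.floor(best + 0.5)))


@dataclass
class PeakTable:
    """Per-sample, per-locus called fragment sizes from one or more labs."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("accession", "locus", "lab", "sizes")

    def __post_init__(self):
        if len(self.rows) and not set(self.REQUIRED) <= set(self.rows.columns):
            raise FormatError(f"peak table needs columns {self.REQUIRED}")


def read_peak_table(path: str | Path) -> PeakTable:
    """Read a peak CSV: accession,locus,lab,sizes with sizes ``;``-separated."""
    df = pd.read_csv(path, dtype=str).fillna("")
    if list(df.columns) != list(PeakTable.REQUIRED):
        raise FormatError(
            f"{path}: expected columns {PeakTable.REQUIRED}, got {list(df.columns)}"
        )
    df["sizes"] = df["sizes"].map(
        lambda s: [float(x) for x in s.split(";") if x.strip()]
    )
    return PeakTable(rows=df)


def read_ladders(path: str | Path) -> dict[str, AllelicLadder]:
    """Read per-locus ladders from a flat YAML config."""
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    ladders = {}
    for locus, spec in raw.items():
        ladders[locus] = AllelicLadder(
            locus=locus,
            nominal_sizes=[float(s) for s in spec["nominal_sizes"]],
            step=float(spec.get("step", 3.0)),
            tolerance=float(spec.get("tolerance", 1.0)),
        )
    return ladders


def genotypes_from_peaks(
    peaks: PeakTable,
    ladders: dict[str, AllelicLadder],
    lab: Optional[str] = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Bin a peak table into a genotype matrix.

    Returns the matrix plus a flag table of samples excluded as MULTIPEAK or
    carrying off-ladder sizes. When ``lab`` is given only that lab's rows are
    used; otherwise the table must contain a single lab.
    """
    df = peaks.rows
    if lab is not None:
        df = df[df["lab"] == lab]
    elif df["lab"].nunique() > 1:
        raise FormatError("peak table mixes labs; pass lab= to select one")
    loci = sorted(df["locus"].unique())
    accession_ids = list(dict.fromkeys(df["accession"]))
    calls: dict[tuple[str, str], Call] = {}
    flags = []
    for _, row in df.iterrows():
        key = (row["accession"], row["locus"])
        raw_call = call_genotype_from_peaks(row["sizes"])
        if raw_call is MULTIPEAK:
            flags.append({"accession": key[0], "locus": key[1], "flag": "MULTIPEAK"})
            calls[key] = MISSING
            continue
        if raw_call is MISSING:
            calls[key] = MISSING
            continue
        try:
            ladder = ladders[row["locus"]]
        except KeyError:
            raise FormatError(f"no ladder configured for locus {row['locus']}")
        try:
            calls[key] = tuple(bin_size(s, ladder) for s in raw_call)
        except OffLadderError:
            flags.append({"accession": key[0], "locus": key[1], "flag": "OFF_LADDER"})
            calls[key] = MISSING
    accessions = [Accession(id=a) for a in accession_ids]
    full_calls = {
        (a, l): calls.get((a, l), MISSING) for a in accession_ids for l in loci
    }
    matrix = GenotypeMatrix(accessions, loci, full_calls)
    flag_df = pd.DataFrame(flags, columns=["accession", "locus", "flag"])
    return matrix, flag_df
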