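"""Seeded simulation of inbred-variety SSR genotype panels.

The generator emulates a marker panel typed on varieties of a predominantly
self-pollinating (autogamous) crop: most accessions are homozygous at every
locus, a minority are heterozygous at only one or two loci, isoline pairs
share identical multilocus profiles, and congeneric species amplify at only a
subset of markers from a shifted allele pool. Defaults follow the observed
structure of such panels: 17 trinucleotide loci with 3-10 alleles each
(k = 10,9,5,10,7,8,3,8,9,6,7,6,6,3,6,6,9), alleles spaced 3 bp apart inside a
100-300 bp size window, and a 0.71 probability that an accession is fully
homozygous.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ssrmarkers.genotypes import MISSING, Accession, Call, GenotypeMatrix
from ssrmarkers.popgen import TransferabilityMatrix

#: default per-locus allele counts of a 17-marker panel (3-10 alleles, 118 total)
DEFAULT_ALLELE_COUNTS = (10, 9, 5, 10, 7, 8, 3, 8, 9, 6, 7, 6, 6, 3, 6, 6, 9)


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Stated world of the simulated variety panel.

    - ``allele_counts``: alleles per locus (defaults above);
    - ``dirichlet_alpha``: symmetric Dirichlet concentration for allele
      frequencies (1.0 = uniform over the simplex);
    - ``p_homozygous``: probability that an accession is homozygous at every
      locus (0.71 for highly inbred variety panels);
    - ``het_locus_probs``: distribution of the number of heterozygous loci for
      the residual heterozygotes (one or two loci, 0.6/0.4);
    - ``n_isoline_pairs``: accession pairs duplicated verbatim (isolines);
    - ``substitution_rate`` / ``failure_rate``: per-allele mis-call and
      per-genotype amplification-failure probabilities for replicate error
      injection.
    """

    n_loci: int = 17
    allele_counts: Sequence[int] = DEFAULT_ALLELE_COUNTS
    dirichlet_alpha: float = 1.0
    p_homozygous: float = 0.71
    het_locus_probs: dict[int, float] = field(default_factory=lambda: {1: 0.6, 2: 0.4})
    n_isoline_pairs: int = 0
    size_range: tuple[int, int] = (100, 300)
    motif_step: int = 3
    substitution_rate: float = 0.0
    failure_rate: float = 0.0

    def __post_init__(self):
        if len(self.allele_counts) != self.n_loci:
            raise ConfigError(
                f"allele_counts has {len(self.allele_counts)} entries for n_loci={self.n_loci}"
            )
        if any(k < 1 for k in self.allele_counts):
            raise ConfigError("allele counts must be >= 1")
        for p in (self.p_homozygous, self.substitution_rate, self.failure_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if abs(sum(self.het_locus_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("het_locus_probs must sum to 1")


@dataclass
class LocusPanel:
    """Simulated marker definition: allele labels (nominal bp) and frequencies."""

    name: str
    alleles: list[str]
    freqs: np.ndarray

    @property
    def k(self) -> int:
        return len(self.alleles)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_panel(
    config: SimulationConfig, seed=None, size_offset: int = 0
) -> list[LocusPanel]:
    """Draw marker definitions: allele sizes at 3-bp spacing, Dirichlet frequencies.

    ``size_offset`` shifts every allele size, producing the (near-)disjoint
    allele pools of a diverged congeneric species.
    """
    rng = _rng(seed)
    lo, hi = config.size_range
    panel = []
    for i, k in enumerate(config.allele_counts):
        span = config.motif_step * (k - 1)
        if lo + span > hi:
            raise ConfigError(
                f"locus {i}: {k} alleles at {config.motif_step}-bp spacing exceed the size range"
            )
        start = int(rng.integers(lo, hi - span + 1)) + size_offset
        alleles = [str(start + config.motif_step * j) for j in range(k)]
        freqs = rng.dirichlet(np.full(k, config.dirichlet_alpha))
        panel.append(LocusPanel(name=f"L{i + 1:02d}", alleles=alleles, freqs=freqs))
    return panel


def simulate_genotypes(
    panel: Sequence[LocusPanel],
    config: SimulationConfig,
    n_accessions: int,
    seed=None,
    species: str = "P. somniferum",
    group: str = "somniferum",
    id_prefix: str = "ACC",
) -> GenotypeMatrix:
    """Simulate an inbred variety panel.

    Each accession is fully homozygous with probability ``p_homozygous``
    (one allele drawn per locus from the panel frequencies, doubled);
    otherwise it is heterozygous at a small number of loci drawn from
    ``het_locus_probs`` (two distinct alleles there) and homozygous elsewhere.
    The first ``n_isoline_pairs`` accessions are duplicated verbatim at the
    end of the panel, modelling isolines of a shared source variety.
    """
    rng = _rng(seed)
    if 2 * config.n_isoline_pairs > n_accessions:
        raise ConfigError("n_isoline_pairs too large for n_accessions")
    n_base = n_accessions - config.n_isoline_pairs

    homo = rng.random(n_base) < config.p_homozygous
    het_counts = np.array(sorted(config.het_locus_probs))
    het_probs = np.array([config.het_locus_probs[c] for c in het_counts])
    n_loci = len(panel)

    # per locus, draw a homozygous base allele for everyone at once
    base = np.empty((n_base, n_loci), dtype=int)
    for li, locus in enumerate(panel):
        base[:, li] = rng.choice(locus.k, size=n_base, p=locus.freqs)

    second = base.copy()
    for i in np.where(~homo)[0]:
        n_het = int(rng.choice(het_counts, p=het_probs))
        n_het = min(n_het, n_loci)
        het_loci = rng.choice(n_loci, size=n_het, replace=False)
        for li in het_loci:
            locus = panel[li]
            if locus.k < 2:
                continue
            other = int(rng.choice(locus.k, p=locus.freqs))
            while other == base[i, li]:
                other = int(rng.choice(locus.k, p=locus.freqs))
            second[i, li] = other

    accessions: list[Accession] = []
    calls: dict[tuple[str, str], Call] = {}
    for i in range(n_base):
        aid = f"{id_prefix}{i + 1:04d}"
        accessions.append(Accession(id=aid, species=species, group=group))
        for li, locus in enumerate(panel):
            calls[(aid, locus.name)] = (
                locus.alleles[base[i, li]],
                locus.alleles[second[i, li]],
            )
    for j in range(config.n_isoline_pairs):
        src = accessions[j]
        aid = f"{src.id}_iso"
        accessions.append(Accession(id=aid, species=species, group=group))
        for locus in panel:
            calls[(aid, locus.name)] = calls[(src.id, locus.name)]
    return GenotypeMatrix(accessions, [l.name for l in panel], calls)


def inject_errors(
    matrix: GenotypeMatrix,
    config: SimulationConfig,
    seed=None,
    panel: Optional[Sequence[LocusPanel]] = None,
) -> GenotypeMatrix:
    """Produce a replicate dataset with seeded genotyping errors.

    Independently per single-locus genotype: with probability ``failure_rate``
    the call becomes missing (amplification failure); otherwise each allele is
    substituted with probability ``substitution_rate`` by a uniformly drawn
    *different* allele of the locus (panel alleles when given, else the
    alleles observed in the matrix).
    """
    rng = _rng(seed)
    pools: dict[str, list[str]] = {}
    if panel is not None:
        pools = {l.name: list(l.alleles) for l in panel}
    else:
        for locus in matrix.loci:
            seen = set()
            for aid in matrix.accession_ids:
                call = matrix.call(aid, locus)
                if call is not MISSING:
                    seen.update(call)
            pools[locus] = sorted(seen)

    replicate = matrix.copy()
    for aid in matrix.accession_ids:
        for locus in matrix.loci:
            call = matrix.call(aid, locus)
            if call is MISSING:
                continue
            if rng.random() < config.failure_rate:
                replicate.set_call(aid, locus, MISSING)
                continue
            pool = pools[locus]
            new_call = list(call)
            for ai in range(2):
                if rng.random() < config.substitution_rate and len(pool) > 1:
                    choices = [a for a in pool if a != new_call[ai]]
                    new_call[ai] = choices[int(rng.integers(len(choices)))]
            replicate.set_call(aid, locus, tuple(new_call))
    return replicate


def simulate_transferability(
    markers: Sequence[str],
    species_probs: dict[str, float],
    seed=None,
    labs: Sequence[str] = ("LAB_A", "LAB_B"),
    lab_discordance: float = 0.0,
) -> TransferabilityMatrix:
    """Draw a marker x species x lab amplification panel.

    Each marker amplifies in a species with that species' probability; with
    probability ``lab_discordance`` one randomly chosen lab's call is flipped,
    exercising the conservative both-labs consensus.
    """
    rng = _rng(seed)
    rows = []
    for marker in markers:
        for species, prob in species_probs.items():
            base = bool(rng.random() < prob)
            calls = {lab: base for lab in labs}
            if rng.random() < lab_discordance:
                flip = labs[int(rng.integers(len(labs)))]
                calls[flip] = not calls[flip]
            for lab in labs:
                rows.append(
                    {"marker": marker, "species": species, "lab": lab, "amplified": calls[lab]}
                )
    return TransferabilityMatrix(data=pd.DataFrame(rows))


def simulate_mixed_species(
    config: SimulationConfig,
    n_focal: int,
    n_other: int,
    seed=None,
    other_species: str = "P. congener",
    pool_shift: int = 60,
    other_amplification: float = 1.0,
) -> GenotypeMatrix:
    """Panel mixing the focal species with a diverged congener.

    The congener draws from an allele pool shifted by ``pool_shift`` bp
    (disjoint from the focal pool when the shift exceeds the locus size span)
    and fails to amplify at each locus with probability
    ``1 - other_amplification``.
    """
    rng = _rng(seed)
    panel = simulate_panel(config, seed=rng)
    focal = simulate_genotypes(
        panel, config, n_focal, seed=rng, species="P. somniferum", group="somniferum"
    )
    shifted = [
        LocusPanel(name=p.name, alleles=[str(int(a) + pool_shift) for a in p.alleles], freqs=p.freqs)
        for p in panel
    ]
    other = simulate_genotypes(
        shifted,
        config,
        n_other,
        seed=rng,
        species=other_species,
        group="other",
        id_prefix="OTH",
    )
    accessions = focal.accessions + other.accessions
    calls: dict[tuple[str, str], Call] = {}
    for m in (focal, other):
        for acc in m.accessions:
            for locus in m.loci:
                calls[(acc.id, locus)] = m.call(acc.id, locus)
    for acc in other.accessions:
        for locus in other.loci:
            if rng.random() >= other_amplification:
                calls[(acc.id, locus)] = MISSING
    return GenotypeMatrix(accessions, focal.loci, calls)
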