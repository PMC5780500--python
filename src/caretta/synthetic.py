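"""Synthetic data with known ground truth for every pipeline stage.

The real baseline genotypes behind the Atlantic/Mediterranean assignment
are not redistributable, so this module generates statistically comparable
stand-ins: two populations of microsatellite genotypes differentiated at a
target F_ST under the Balding–Nichols model (population allele frequencies
drawn around symmetric-Dirichlet ancestral frequencies), Mendelian
half-sib clutches from known mothers and fathers, and a full nest-dataset
bundle whose clutch sizes, father counts and origins mirror the observed
sporadic-nest summary (18 clutches, 121 samples).  A multi-allele
Weir–Cockerham θ estimator is included to validate the calibration.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assignment import ATL, MED, BaselinePanel
from .genotypes import Clutch, GenotypeTable, MultilocusGenotype, write_genotype_table

__all__ = [
    "SimulationConfig",
    "BaselineTruth",
    "simulate_baseline",
    "simulate_clutch",
    "wc_fst",
    "FstResult",
    "simulate_nest_dataset",
    "DEFAULT_LOCI",
]

#: the seven microsatellite markers genotyped in the sporadic-nest samples
DEFAULT_LOCI = ("Cm84", "Cc117", "Cm72", "Ei8", "Cc141", "Cc7", "Ccar176")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults match the reference baseline panel.

    112 Mediterranean and 56 Atlantic reference individuals at 7
    microsatellite loci differentiated at F_ST ≈ 0.029.  Eight alleles per
    locus approximates microsatellite polymorphism; allele labels are
    integer fragment sizes spaced by 2.
    """

    seed: int
    n_med: int = 112
    n_atl: int = 56
    n_loci: int = 7
    alleles_per_locus: int = 8
    target_fst: float = 0.029
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_med", "n_atl", "n_loci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.alleles_per_locus < 2:
            raise ValueError("alleles_per_locus must be >= 2 (degenerate loci rejected)")
        if not (0.0 <= self.target_fst < 1.0):
            raise ValueError("target_fst must be in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def loci(self) -> tuple[str, ...]:
        if self.n_loci == len(DEFAULT_LOCI):
            return DEFAULT_LOCI
        return tuple(f"L{i + 1}" for i in range(self.n_loci))

    def allele_labels(self) -> tuple[int, ...]:
        # microsatellite-like fragment sizes; semantics are label-only
        return tuple(100 + 2 * k for k in range(self.alleles_per_locus))


@dataclass
class BaselineTruth:
    """True frequencies behind a simulated baseline panel."""

    ancestral: dict[str, dict[int, float]]
    population: dict[str, dict[str, dict[int, float]]]  # pop -> locus -> allele -> p


def _draw_genotype_rows(
    rng: np.random.Generator,
    n: int,
    loci: Sequence[str],
    labels: Sequence[int],
    pop_freqs: dict[str, dict[int, float]],
    missing_rate: float,
) -> list[MultilocusGenotype]:
    lab = np.asarray(labels)
    out = []
    for _ in range(n):
        pairs = []
        for locus in loci:
            if missing_rate and rng.random() < missing_rate:
                pairs.append(None)
                continue
            p = np.array([pop_freqs[locus][a] for a in labels])
            a, b = rng.choice(lab, size=2, p=p)
            pairs.append((int(a), int(b)))
        out.append(MultilocusGenotype(loci=tuple(loci), alleles=tuple(pairs)))
    return out


def simulate_baseline(cfg: SimulationConfig) -> tuple[BaselinePanel, BaselineTruth]:
    """Two-population baseline under the Balding–Nichols model.

    Per locus, ancestral frequencies are symmetric-Dirichlet(1); each
    population's frequencies are Dirichlet with parameters
    ``p · (1 − F) / F`` (independent draws per population), which has mean
    ``p`` and Wright's F_ST equal to ``F`` relative to the ancestor.
    Individuals are drawn in Hardy–Weinberg proportions within population.
    """
    rng = np.random.default_rng(cfg.seed)
    loci = cfg.loci
    labels = cfg.allele_labels()
    K = cfg.alleles_per_locus
    F = cfg.target_fst

    ancestral: dict[str, dict[int, float]] = {}
    pop_freqs: dict[str, dict[str, dict[int, float]]] = {MED: {}, ATL: {}}
    for locus in loci:
        p = rng.dirichlet(np.ones(K))
        ancestral[locus] = dict(zip(labels, map(float, p)))
        for pop in (MED, ATL):
            if F == 0.0:
                q = p
            else:
                q = rng.dirichlet(p * (1.0 - F) / F)
            pop_freqs[pop][locus] = dict(zip(labels, map(float, q)))

    med = _draw_genotype_rows(rng, cfg.n_med, loci, labels, pop_freqs[MED], cfg.missing_rate)
    atl = _draw_genotype_rows(rng, cfg.n_atl, loci, labels, pop_freqs[ATL], cfg.missing_rate)
    panel = BaselinePanel(
        genotypes=med + atl,
        populations=[MED] * cfg.n_med + [ATL] * cfg.n_atl,
        sample_ids=[f"MED{i + 1}" for i in range(cfg.n_med)]
        + [f"ATL{i + 1}" for i in range(cfg.n_atl)],
    )
    return panel, BaselineTruth(ancestral=ancestral, population=pop_freqs)


def draw_parent(
    rng: np.random.Generator,
    truth: BaselineTruth,
    pop: str,
    loci: Sequence[str] | None = None,
) -> MultilocusGenotype:
    """One HWE genotype from a simulated population's true frequencies."""
    freqs = truth.population[pop]
    loci = tuple(loci) if loci is not None else tuple(freqs)
    pairs = []
    for locus in loci:
        alleles = sorted(freqs[locus])
        p = np.array([freqs[locus][a] for a in alleles])
        a, b = rng.choice(np.asarray(alleles), size=2, p=p)
        pairs.append((int(a), int(b)))
    return MultilocusGenotype(loci=loci, alleles=tuple(pairs))


def simulate_clutch(
    mother: MultilocusGenotype,
    fathers: Sequence[MultilocusGenotype],
    n_offspring: int,
    seed: int | np.random.Generator,
    father_probs: Sequence[float] | None = None,
    nest_id: str = "sim",
    mtdna_haplotype: str | None = None,
    missing_rate: float = 0.0,
    include_mother: bool = True,
) -> tuple[Clutch, list[int]]:
    """Mendelian half-sib clutch with a known per-offspring sire record.

    Each offspring inherits one uniformly chosen allele from the mother and
    one from its father; the father per offspring is drawn from
    ``father_probs`` (uniform by default).  Returns the clutch and the true
    father index per offspring.
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    if not fathers:
        raise ValueError("need at least one father")
    loci = mother.loci
    if any(f.loci != loci for f in fathers):
        raise ValueError("parents must share the locus list")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if father_probs is None:
        probs = np.full(len(fathers), 1.0 / len(fathers))
    else:
        probs = np.asarray(father_probs, dtype=float)
        probs = probs / probs.sum()

    offspring = []
    truth: list[int] = []
    for _ in range(n_offspring):
        fidx = int(rng.choice(len(fathers), p=probs))
        truth.append(fidx)
        father = fathers[fidx]
        pairs = []
        for i in range(len(loci)):
            mp, fp = mother.alleles[i], father.alleles[i]
            if mp is None or fp is None or (missing_rate and rng.random() < missing_rate):
                pairs.append(None)
                continue
            pairs.append((mp[rng.integers(2)], fp[rng.integers(2)]))
        offspring.append(MultilocusGenotype(loci=loci, alleles=tuple(pairs)))
    clutch = Clutch(
        nest_id=nest_id,
        offspring=offspring,
        maternal_genotype=mother if include_mother else None,
        mtdna_haplotype=mtdna_haplotype,
    )
    return clutch, truth


# ---------------------------------------------------------------------------
# Weir–Cockerham theta

@dataclass(frozen=True)
class FstResult:
    theta: float
    per_locus: dict[str, float]


class MonomorphicDataError(ValueError):
    """θ is undefined on a dataset with no allelic variation."""


def wc_fst(panel: BaselinePanel) -> FstResult:
    """Multi-allele Weir–Cockerham θ for the two-population panel.

    Variance components a (among populations), b (among individuals
    within populations) and c (within individuals) are computed per allele
    per locus and combined ratio-of-sums over alleles and loci:
    θ = Σa / Σ(a + b + c).
    """
    by_pop = {MED: [], ATL: []}
    for g, pop in zip(panel.genotypes, panel.populations):
        by_pop[pop].append(g)
    if min(len(v) for v in by_pop.values()) < 2:
        raise ValueError("need >= 2 individuals per population")
    loci = panel.loci
    r = 2  # populations

    sum_a = 0.0
    sum_abc = 0.0
    per_locus: dict[str, float] = {}
    for li, locus in enumerate(loci):
        # per-population typed counts, allele freqs and het freqs
        stats = []
        alleles: set[int] = set()
        for pop in (MED, ATL):
            pairs = [g.alleles[li] for g in by_pop[pop] if g.alleles[li] is not None]
            if len(pairs) < 2:
                stats = []
                break
            n_i = len(pairs)
            counts: dict[int, int] = {}
            hets: dict[int, int] = {}
            for a, b in pairs:
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
                if a != b:
                    hets[a] = hets.get(a, 0) + 1
                    hets[b] = hets.get(b, 0) + 1
            alleles.update(counts)
            stats.append((n_i, counts, hets))
        if not stats:
            continue
        if len(alleles) < 2:
            continue  # monomorphic locus: no information
        n = np.array([s[0] for s in stats], dtype=float)
        nbar = n.mean()
        nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
        la = lb = lc = 0.0
        for allele in sorted(alleles):
            p_i = np.array([s[1].get(allele, 0) / (2 * s[0]) for s in stats])
            h_i = np.array([s[2].get(allele, 0) / s[0] for s in stats])
            pbar = (n * p_i).sum() / (r * nbar)
            s2 = (n * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n * h_i).sum() / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
            )
            c = hbar / 2.0
            la += a
            lb += b
            lc += c
        if la + lb + lc != 0:
            per_locus[locus] = la / (la + lb + lc)
        sum_a += la
        sum_abc += la + lb + lc
    if sum_abc == 0:
        raise MonomorphicDataError("no polymorphic locus; theta undefined")
    return FstResult(theta=sum_a / sum_abc, per_locus=per_locus)


# ---------------------------------------------------------------------------
# end-to-end nest dataset

# (clutch sizes, minimum fathers, origin, haplotype) mirroring the observed
# 18 western-Mediterranean sporadic clutches; the N33 entry includes the
# sampled nesting female (7 offspring + mother = 8 samples, total 121).
_NEST_TEMPLATE: tuple[tuple[str, int, int, str, str], ...] = (
    ("N3", 15, 2, "ATL", "CC-A3.1"),
    ("N4", 1, 1, "MED", "CC-A10.4"),
    ("N6", 1, 1, "ATL", "CC-A2.1"),
    ("N8", 1, 1, "ATL", "CC-A2.1"),
    ("N9", 1, 1, "ATL", "CC-A2.1"),
    ("N10", 1, 1, "ATL", "CC-A2.1"),
    ("N13", 6, 2, "MIXED", "CC-A2.1"),
    ("N14", 23, 2, "ATL", "CC-A1.1"),
    ("N15", 1, 1, "ATL", "CC-A9.1"),
    ("N16", 2, 1, "ATL", "CC-A2.1"),
    ("N17", 2, 1, "ATL", "CC-A2.1"),
    ("N18", 14, 1, "MED", "CC-A2.1"),
    ("N21", 2, 1, "MED", "CC-A2.1"),
    ("N27", 14, 2, "MED", "CC-A20.1"),
    ("N28", 1, 1, "ATL", "CC-A3.1"),
    ("N29", 18, 2, "ATL", "CC-A2.1"),
    ("N32", 10, 2, "ATL", "CC-A2.1"),
    ("N33", 8, 1, "ATL", "CC-A2.1"),  # includes the sampled mother
)


def simulate_nest_dataset(
    cfg: SimulationConfig, out_dir: str | Path
) -> dict[str, object]:
    """Write a self-contained bundle exercising every pipeline stage.

    Produces ``baseline.csv`` (the two-population reference panel),
    ``clutches.csv`` (offspring genotypes, one group per nest, plus the one
    sampled mother), ``nests.tsv`` (per-nest metadata: origin, haplotype,
    incubation temperature drawn from the six-temperature grid) and
    ``truth.json`` (simulated parent genotypes and per-offspring sires).
    Clutch sizes and father counts mirror the observed 18-nest summary:
    121 samples in total.  Returns the manifest as a dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    panel, truth = simulate_baseline(
        SimulationConfig(
            seed=int(rng.integers(2**31 - 1)),
            n_med=cfg.n_med,
            n_atl=cfg.n_atl,
            n_loci=cfg.n_loci,
            alleles_per_locus=cfg.alleles_per_locus,
            target_fst=cfg.target_fst,
            missing_rate=cfg.missing_rate,
        )
    )
    write_genotype_table(
        GenotypeTable(panel.sample_ids, panel.populations, panel.genotypes),
        out / "baseline.csv",
        header_note=f"simulated Balding-Nichols baseline, target FST {cfg.target_fst}",
    )

    temps = (28.0, 29.1, 29.3, 29.5, 31.0, 33.0)
    loci = cfg.loci
    clutch_rows_ids: list[str] = []
    clutch_rows_groups: list[str] = []
    clutch_rows_geno: list[MultilocusGenotype] = []
    nests_meta = []
    manifest: dict[str, object] = {"seed": cfg.seed, "nests": {}}
    for idx, (nest_id, n_samples, n_fathers, origin, hap) in enumerate(_NEST_TEMPLATE):
        mother_pop = MED if origin == "MED" else ATL
        father_pop = mother_pop
        if origin == "MIXED":
            mother_pop, father_pop = MED, ATL
        mother = draw_parent(rng, truth, mother_pop, loci)
        fathers = [draw_parent(rng, truth, father_pop, loci) for _ in range(n_fathers)]
        mother_sampled = nest_id == "N33"
        n_off = n_samples - 1 if mother_sampled else n_samples
        clutch, sires = simulate_clutch(
            mother,
            fathers,
            n_off,
            rng,
            nest_id=nest_id,
            mtdna_haplotype=hap,
            missing_rate=cfg.missing_rate,
        )
        for oid, g in zip(clutch.offspring_ids, clutch.offspring):
            clutch_rows_ids.append(oid)
            clutch_rows_groups.append(nest_id)
            clutch_rows_geno.append(g)
        if mother_sampled:
            clutch_rows_ids.append(f"{nest_id}_mother")
            clutch_rows_groups.append(nest_id)
            clutch_rows_geno.append(mother)
        nests_meta.append(
            {
                "nest_id": nest_id,
                "n_samples": n_samples,
                "origin": origin,
                "haplotype": hap,
                "temperature_c": temps[idx % len(temps)],
                "mother_sampled": mother_sampled,
            }
        )
        manifest["nests"][nest_id] = {
            "origin": origin,
            "n_fathers": n_fathers,
            "mother": [list(p) if p else None for p in mother.alleles],
            "fathers": [
                [list(p) if p else None for p in f.alleles] for f in fathers
            ],
            "sires": sires,
            "haplotype": hap,
        }

    write_genotype_table(
        GenotypeTable(clutch_rows_ids, clutch_rows_groups, clutch_rows_geno),
        out / "clutches.csv",
        header_note="simulated sporadic-nest offspring; group = nest id",
    )
    pd.DataFrame(nests_meta).to_csv(out / "nests.tsv", sep="\t", index=False)
    with (out / "truth.json").open("w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
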