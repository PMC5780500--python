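"""Two-population origin assignment and mtDNA haplotype matching.

Loggerhead turtles nesting sporadically in the western Mediterranean may
originate from Atlantic or from (eastern) Mediterranean rookeries.  Given a
labelled two-population baseline panel of microsatellite genotypes, each
query individual receives a posterior probability of Atlantic origin from a
closed-form no-admixture model: per population, the genotype likelihood is
the product of Hardy–Weinberg genotype probabilities under that
population's allele frequencies (Laplace-smoothed, leave-one-out for panel
members), and the posterior combines the two likelihoods with a prior.
This is the deterministic analogue of supervised two-cluster STRUCTURE
assignment; it is a documented methodological simplification — no MCMC, no
admixture — and is not expected to reproduce MCMC-averaged values.

An assignment is *reliable* only when the larger posterior exceeds 0.8
(strictly), the convention used for these markers; anything else is
reported as Unknown.  Maternally inherited control-region haplotypes give
an independent origin line of evidence: queries are matched to a named
haplotype reference by exact sequence or substring identity, with
reverse-complement handling and an explicit short-fragment flag (a ~380 bp
fragment cannot distinguish long-haplotype variants).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .genotypes import Clutch, GenotypeTable, MultilocusGenotype
from .kinship import ParentageSolution

logger = logging.getLogger(__name__)

__all__ = [
    "MED",
    "ATL",
    "BaselinePanel",
    "AlleleFrequencyTable",
    "OriginAssignment",
    "ClutchAssignment",
    "HaplotypeReference",
    "HaplotypeMatch",
    "estimate_frequencies",
    "assign_individual",
    "assign_clutch",
    "match_haplotype",
    "load_haplotype_reference",
]

MED = "MED"
ATL = "ATL"
RELIABILITY_THRESHOLD = 0.8


@dataclass
class BaselinePanel:
    """Labelled reference genotypes for the two source populations."""

    genotypes: list[MultilocusGenotype]
    populations: list[str]  # MED or ATL per genotype
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.genotypes) != len(self.populations):
            raise ValueError("genotypes and populations differ in length")
        pops = set(self.populations)
        if not pops <= {MED, ATL}:
            raise ValueError(f"population labels must be {MED}/{ATL}, got {pops}")
        if MED not in pops or ATL not in pops:
            raise ValueError("both populations must be non-empty")
        loci = self.genotypes[0].loci
        if any(g.loci != loci for g in self.genotypes):
            raise ValueError("all panel genotypes must share one locus list")
        if self.sample_ids is None:
            self.sample_ids = [f"B{i}" for i in range(len(self.genotypes))]

    @property
    def loci(self) -> tuple[str, ...]:
        return self.genotypes[0].loci

    def counts(self) -> dict[str, int]:
        return {
            p: sum(q == p for q in self.populations) for p in (MED, ATL)
        }

    @classmethod
    def from_table(cls, table: GenotypeTable) -> "BaselinePanel":
        return cls(
            genotypes=list(table.genotypes),
            populations=list(table.groups),
            sample_ids=list(table.sample_ids),
        )


@dataclass
class AlleleFrequencyTable:
    """Per-locus, per-population allele frequencies with Laplace smoothing.

    ``counts[pop][locus]`` holds raw allele counts; frequencies add
    ``pseudocount`` to every allele in the locus's dataset-wide allele set,
    so every frequency is strictly positive and each locus/population
    column sums to one.
    """

    counts: dict[str, dict[str, dict[int, float]]]
    allele_sets: dict[str, tuple[int, ...]]
    pseudocount: float
    sample_sizes: dict[str, int]

    def frequencies(
        self, pop: str, exclude: MultilocusGenotype | None = None
    ) -> dict[str, dict[int, float]]:
        """Smoothed frequencies for one population, optionally removing one
        panel member's alleles first (leave-one-out)."""
        out: dict[str, dict[int, float]] = {}
        for locus, alleles in self.allele_sets.items():
            c = dict(self.counts[pop].get(locus, {}))
            if exclude is not None:
                pair = exclude.alleles[exclude.loci.index(locus)] if locus in exclude.loci else None
                if pair is not None:
                    for a in pair:
                        if c.get(a, 0) > 0:
                            c[a] -= 1
            tot = sum(c.values()) + self.pseudocount * len(alleles)
            out[locus] = {
                a: (c.get(a, 0.0) + self.pseudocount) / tot for a in alleles
            }
        return out

    def pooled(self) -> dict[str, dict[int, float]]:
        """Frequencies pooled over both populations (for relatedness use)."""
        out: dict[str, dict[int, float]] = {}
        for locus, alleles in self.allele_sets.items():
            c = {a: 0.0 for a in alleles}
            for pop in self.counts:
                for a, v in self.counts[pop].get(locus, {}).items():
                    c[a] = c.get(a, 0.0) + v
            tot = sum(c.values()) + self.pseudocount * len(alleles)
            out[locus] = {a: (c[a] + self.pseudocount) / tot for a in alleles}
        return out


def estimate_frequencies(
    panel: BaselinePanel, pseudocount: float = 1.0
) -> AlleleFrequencyTable:
    """Per-population allele counts over the panel, ready for smoothing.

    The allele set per locus is the union over both populations (plus any
    allele later queried gets the pseudocount floor via ``frequencies``).
    Loci monomorphic across both populations are retained (uninformative)
    with a log entry.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    loci = panel.loci
    counts: dict[str, dict[str, dict[int, float]]] = {MED: {}, ATL: {}}
    allele_sets: dict[str, set[int]] = {l: set() for l in loci}
    for g, pop in zip(panel.genotypes, panel.populations):
        for i, locus in enumerate(loci):
            pair = g.alleles[i]
            if pair is None:
                continue
            d = counts[pop].setdefault(locus, {})
            for a in pair:
                d[a] = d.get(a, 0.0) + 1.0
                allele_sets[locus].add(a)
    for locus in loci:
        if len(allele_sets[locus]) <= 1:
            logger.info("locus %s monomorphic across both populations", locus)
    return AlleleFrequencyTable(
        counts=counts,
        allele_sets={l: tuple(sorted(s)) for l, s in allele_sets.items()},
        pseudocount=pseudocount,
        sample_sizes=panel.counts(),
    )


@dataclass(frozen=True)
class OriginAssignment:
    """Posterior origin call for one individual.

    ``category`` is Atlantic or Mediterranean only when the larger
    posterior strictly exceeds 0.8; otherwise Unknown.
    """

    p_atlantic: float
    n_loci_used: int
    reliable: bool
    category: str  # "Atlantic" | "Mediterranean" | "Unknown"

    @property
    def p_mediterranean(self) -> float:
        return 1.0 - self.p_atlantic


def _categorise(p_atl: float, n_loci: int) -> OriginAssignment:
    if n_loci == 0:
        return OriginAssignment(0.5, 0, False, "Unknown")
    top = max(p_atl, 1.0 - p_atl)
    reliable = top > RELIABILITY_THRESHOLD
    if not reliable:
        cat = "Unknown"
    else:
        cat = "Atlantic" if p_atl > 0.5 else "Mediterranean"
    return OriginAssignment(p_atl, n_loci, reliable, cat)


def assign_individual(
    g: MultilocusGenotype,
    freqs: AlleleFrequencyTable,
    prior_atlantic: float = 0.5,
    exclude_self_from: str | None = None,
) -> OriginAssignment:
    """Posterior probability of Atlantic origin under the HWE genotype model.

    Per population, log-likelihood = Σ over typed loci of log(p²) for
    homozygotes and log(2pq) for heterozygotes, using that population's
    smoothed frequencies; missing loci are skipped.  Set
    ``exclude_self_from`` to the query's own population label to apply
    leave-one-out when the query belongs to the panel.
    """
    if not (0.0 < prior_atlantic < 1.0):
        raise ValueError("prior must be strictly inside (0, 1)")
    loglik = {}
    n_used = 0
    for pop in (MED, ATL):
        exclude = g if exclude_self_from == pop else None
        pf = freqs.frequencies(pop, exclude=exclude)
        ll = 0.0
        used = 0
        for i, locus in enumerate(g.loci):
            pair = g.alleles[i]
            if pair is None or locus not in pf:
                continue
            a, b = pair
            floor = freqs.pseudocount / (
                sum(freqs.counts[pop].get(locus, {}).values())
                + freqs.pseudocount * max(len(freqs.allele_sets.get(locus, ())), 1)
            )
            pa = pf[locus].get(a, floor)
            pb = pf[locus].get(b, floor)
            ll += math.log(pa * pa) if a == b else math.log(2.0 * pa * pb)
            used += 1
        loglik[pop] = ll
        n_used = used
    if n_used == 0:
        return _categorise(0.5, 0)
    la = math.log(prior_atlantic) + loglik[ATL]
    lm = math.log(1.0 - prior_atlantic) + loglik[MED]
    mx = max(la, lm)
    pa = math.exp(la - mx) / (math.exp(la - mx) + math.exp(lm - mx))
    return _categorise(pa, n_used)


@dataclass
class ClutchAssignment:
    """Clutch-level origin report.

    Offspring posteriors are summarised as mean ± sd of P(Atlantic);
    candidate mothers and fathers are the parental genotypes across the
    supplied parentage solutions (capped), each assigned like an
    individual.  When offspring are inconclusive, solutions are partitioned
    by the maternal origin call and the corresponding fathers re-reported
    per partition — a Mediterranean-mother partition whose fathers assign
    to the Atlantic (or vice versa) indicates parents of different origin
    (category Mixed).
    """

    nest_id: str
    offspring: list[OriginAssignment]
    mean_p_atlantic: float
    sd_p_atlantic: float
    mother_assignments: list[OriginAssignment]
    father_assignments: list[OriginAssignment]
    partitions: dict[str, dict[str, float]]
    category: str  # Atlantic | Mediterranean | Mixed | Unknown


def assign_clutch(
    clutch: Clutch,
    freqs: AlleleFrequencyTable,
    solutions: Sequence[ParentageSolution] = (),
    prior_atlantic: float = 0.5,
    max_parents: int = 100,
) -> ClutchAssignment:
    """Assign a whole clutch and its reconstructed parents to an origin."""
    offspring = [
        assign_individual(g, freqs, prior_atlantic) for g in clutch.offspring
    ]
    pvals = np.array([a.p_atlantic for a in offspring if a.n_loci_used > 0])
    mean_p = float(pvals.mean()) if pvals.size else 0.5
    sd_p = float(pvals.std(ddof=1)) if pvals.size > 1 else 0.0

    mothers: list[OriginAssignment] = []
    fathers: list[OriginAssignment] = []
    partitions: dict[str, list[float]] = {"Atlantic": [], "Mediterranean": []}
    n_parents = 0
    for sol in solutions:
        if n_parents >= max_parents:
            break
        ma = assign_individual(sol.maternal_genotype, freqs, prior_atlantic)
        mothers.append(ma)
        n_parents += 1
        fas = []
        for fg in sol.paternal_genotypes:
            if n_parents >= max_parents:
                break
            fa = assign_individual(fg, freqs, prior_atlantic)
            fathers.append(fa)
            fas.append(fa)
            n_parents += 1
        if ma.category in partitions:
            partitions[ma.category].extend(f.p_atlantic for f in fas)

    part_summary = {
        f"mother_{k.lower()}": {
            "n_fathers": float(len(v)),
            "father_mean_p_atlantic": float(np.mean(v)) if v else float("nan"),
        }
        for k, v in partitions.items()
    }

    category = _clutch_category(mean_p, pvals.size, mothers, fathers, part_summary)
    return ClutchAssignment(
        nest_id=clutch.nest_id,
        offspring=offspring,
        mean_p_atlantic=mean_p,
        sd_p_atlantic=sd_p,
        mother_assignments=mothers,
        father_assignments=fathers,
        partitions=part_summary,
        category=category,
    )


def _clutch_category(
    mean_p: float,
    n_offspring: int,
    mothers: Sequence[OriginAssignment],
    fathers: Sequence[OriginAssignment],
    partitions: Mapping[str, Mapping[str, float]],
) -> str:
    """Clutch category: a reliable mean offspring posterior names the
    origin; inconclusive offspring whose partitioned parents reliably
    oppose each other (a maternal partition whose fathers assign to the
    other basin) are Mixed; anything else Unknown."""
    if n_offspring:
        call = _categorise(mean_p, n_offspring).category
        if call != "Unknown":
            return call
    parent_cats = {a.category for a in (*mothers, *fathers) if a.reliable}
    for mcat, other in (("Atlantic", "Mediterranean"), ("Mediterranean", "Atlantic")):
        part = partitions.get(f"mother_{mcat.lower()}", {})
        fmean = part.get("father_mean_p_atlantic", float("nan"))
        if part.get("n_fathers", 0) and not math.isnan(fmean):
            father_cat = _categorise(fmean, 1).category
            if father_cat == other:
                return "Mixed"
    if {"Atlantic", "Mediterranean"} <= parent_cats:
        return "Mixed"
    if len(parent_cats) == 1:
        return next(iter(parent_cats))
    return "Unknown"


# ---------------------------------------------------------------------------
# mtDNA haplotype matching

@dataclass
class HaplotypeReference:
    """Named control-region haplotypes with origin classes and accessions."""

    sequences: dict[str, str]                 # name -> uppercase sequence
    origin_classes: dict[str, str]            # name -> origin class
    accessions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        iupac = set("ACGTRYSWKMBDHVN")
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"haplotype {name} has an empty sequence")
            seq = seq.upper()
            bad = set(seq) - iupac
            if bad:
                raise ValueError(f"haplotype {name}: non-IUPAC characters {bad}")
            self.sequences[name] = seq
        unknown = set(self.sequences) - set(self.origin_classes)
        if unknown:
            raise ValueError(f"haplotypes without origin class: {sorted(unknown)}")


@dataclass(frozen=True)
class HaplotypeMatch:
    """Result of matching a query sequence against the reference."""

    status: str                      # "match" | "ambiguous" | "no-match"
    name: str | None = None
    origin_class: str | None = None
    short_fragment: bool = False     # query was a proper substring
    reverse_complement: bool = False
    candidates: tuple[str, ...] = ()


def match_haplotype(seq: str, ref: HaplotypeReference) -> HaplotypeMatch:
    """Match a control-region sequence to a named haplotype.

    Exact equality first; otherwise the query may be a substring of exactly
    one reference (a short sequenced fragment), reported with a
    short-fragment flag.  Both strands are tried.  A query contained in
    several references is ambiguous and all candidates are listed.
    """
    if not seq:
        raise ValueError("empty query sequence")
    q = seq.upper().replace("\n", "").replace(" ", "")
    for rc in (False, True):
        query = str(Seq(q).reverse_complement()) if rc else q
        exact = [n for n, s in ref.sequences.items() if s == query]
        if len(exact) == 1:
            n = exact[0]
            return HaplotypeMatch("match", n, ref.origin_classes[n], False, rc)
        if len(exact) > 1:
            return HaplotypeMatch("ambiguous", candidates=tuple(sorted(exact)))
        subs = [n for n, s in ref.sequences.items() if query in s and s != query]
        if len(subs) == 1:
            n = subs[0]
            return HaplotypeMatch("match", n, ref.origin_classes[n], True, rc)
        if len(subs) > 1:
            return HaplotypeMatch("ambiguous", candidates=tuple(sorted(subs)))
    return HaplotypeMatch("no-match")


def load_haplotype_reference(
    fasta_path: str | Path, origins_path: str | Path
) -> HaplotypeReference:
    """Load a haplotype FASTA plus its sidecar origin-class TSV
    (columns: name, origin_class, accession)."""
    seqs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    if len(seqs) == 0:
        raise ValueError(f"no sequences in {fasta_path}")
    meta = pd.read_csv(origins_path, sep="\t", comment="#")
    origin = dict(zip(meta["name"], meta["origin_class"]))
    acc = dict(zip(meta["name"], meta.get("accession", meta["name"])))
    missing = set(seqs) - set(origin)
    if missing:
        raise ValueError(f"origin classes missing for {sorted(missing)}")
    return HaplotypeReference(sequences=seqs, origin_classes=origin, accessions=acc)
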