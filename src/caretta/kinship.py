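"""Parentage reconstruction and pairwise relatedness for progeny arrays.

Sea turtle clutches are half-sib progeny arrays: one mother (sometimes
sampled, usually not) and one or more fathers.  With unlinked codominant
microsatellites the offspring genotypes constrain the parental genotypes
tightly enough that the *minimum* number of fathers can be found by
exhaustive Mendelian search, and multiple paternity can be screened simply
by counting distinct parental alleles per locus: two parents carry at most
four alleles, so a fifth allele in the clutch proves a second father.

The module also implements the Lynch & Ritland (1999) pairwise relatedness
estimator from reference allele frequencies, locus-weighted and averaged
over the two reciprocal reference/proband orderings.  Values are reported
on the doubled scale (range −1..1) used by GenAlEx-style software, on which
unrelated pairs centre on 0 and full sibs on 0.5; the half-scale raw value
is stored alongside.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import Clutch, MultilocusGenotype

logger = logging.getLogger(__name__)

__all__ = [
    "MultiplePaternityResult",
    "ParentageSolution",
    "MinFathersResult",
    "RelatednessMatrix",
    "detect_multiple_paternity",
    "min_fathers",
    "pooled_frequencies",
    "lynch_ritland_pair",
    "lynch_ritland_matrix",
    "relatedness_heatmap_export",
]

FreqTable = Mapping[str, Mapping[int, float]]  # locus -> allele -> frequency


# ---------------------------------------------------------------------------
# multiple-paternity screen

@dataclass(frozen=True)
class MultiplePaternityResult:
    """Outcome of the parental-allele-count screen.

    ``flag`` is True when some locus requires more than two parents, False
    when no locus does, and None when every locus is untyped
    (indeterminate).
    """

    flag: bool | None
    allele_counts: dict[str, int]
    evidencing_loci: tuple[str, ...]


def detect_multiple_paternity(clutch: Clutch) -> MultiplePaternityResult:
    """Screen a clutch for multiple paternity by counting parental alleles.

    With the mother unknown, a locus showing more than four distinct
    alleles across the offspring cannot come from a single pair of parents.
    With the mother known, more than two distinct non-maternal alleles at a
    locus exceed what one father can carry.
    """
    if len(clutch.offspring) < 2:
        raise ValueError("need at least two offspring to screen for multiple paternity")
    counts: dict[str, int] = {}
    evidence: list[str] = []
    any_typed = False
    mother = clutch.maternal_genotype
    for i, locus in enumerate(clutch.loci):
        alleles: set[int] = set()
        for g in clutch.offspring:
            pair = g.alleles[i]
            if pair is not None:
                alleles.update(pair)
        if not alleles:
            continue
        any_typed = True
        counts[locus] = len(alleles)
        if mother is not None and mother.alleles[i] is not None:
            paternal = alleles - set(mother.alleles[i])
            if len(paternal) > 2:
                evidence.append(locus)
                continue
        if len(alleles) > 4:
            evidence.append(locus)
    if not any_typed:
        return MultiplePaternityResult(flag=None, allele_counts={}, evidencing_loci=())
    return MultiplePaternityResult(
        flag=bool(evidence), allele_counts=counts, evidencing_loci=tuple(evidence)
    )


# ---------------------------------------------------------------------------
# minimum-father reconstruction

@dataclass(frozen=True)
class ParentageSolution:
    """One minimal Mendelian-compatible parentage for a clutch.

    Father genotypes are representative: at each locus the lexicographically
    smallest allele pair compatible with that father's offspring is
    reported (loci where none of a father's offspring are typed are left
    missing).  ``log_likelihood`` is the summed log HWE probability of the
    parental genotypes when allele frequencies were supplied, else None.
    """

    maternal_genotype: MultilocusGenotype
    paternal_genotypes: tuple[MultilocusGenotype, ...]
    father_assignment: tuple[int, ...]  # per offspring, index into paternal_genotypes
    log_likelihood: float | None = None

    @property
    def n_fathers(self) -> int:
        return len(self.paternal_genotypes)


@dataclass(frozen=True)
class MinFathersResult:
    k: int | None                 # minimal father count, None if > max_fathers
    solutions: tuple[ParentageSolution, ...]
    exhaustive: bool              # False when the node budget was exhausted
    low_power: bool               # fewer than three offspring
    loci_used: tuple[str, ...]
    max_fathers: int

    @property
    def label(self) -> str:
        return str(self.k) if self.k is not None else f">{self.max_fathers}"


class IncompatibleMotherError(ValueError):
    """A known maternal genotype contradicts an offspring genotype."""


def _maternal_candidates_locus(
    offspring_pairs: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Unordered maternal allele pairs (from observed alleles) compatible
    with every typed offspring at one locus.

    A mother carrying an allele never seen in the offspring is
    constraint-equivalent to a homozygote for her observed allele, so pairs
    over the observed allele set (homozygotes included) cover all cases.
    """
    observed = sorted({a for pair in offspring_pairs for a in pair})
    cands = []
    for a, b in itertools.combinations_with_replacement(observed, 2):
        mset = {a, b}
        if all(mset & set(p) for p in offspring_pairs):
            cands.append((a, b))
    return cands


def _paternal_sets(
    mother_pair: tuple[int, int], offspring_pairs: list[tuple[int, int] | None]
) -> list[frozenset[int] | None] | None:
    """Per offspring, the set of alleles its father may have transmitted,
    given the maternal pair; None entries for untyped offspring.  Returns
    None if some offspring is incompatible with the mother."""
    mset = set(mother_pair)
    out: list[frozenset[int] | None] = []
    for pair in offspring_pairs:
        if pair is None:
            out.append(None)
            continue
        a, b = pair
        s = set()
        if b in mset:
            s.add(a)
        if a in mset:
            s.add(b)
        if not s:
            return None
        out.append(frozenset(s))
    return out


def _father_pair(sets: list[frozenset[int]]) -> tuple[int, int] | None:
    """Lexicographically smallest feasible allele pair for one father."""
    if not sets:
        return None
    universe = sorted(set().union(*sets))
    for p, q in itertools.combinations_with_replacement(universe, 2):
        if all(p in s or q in s for s in sets):
            return (p, q)
    raise AssertionError("called on an infeasible group")


class _Budget:
    def __init__(self, nodes: int) -> None:
        self.left = nodes
        self.exhausted = False

    def tick(self) -> bool:
        self.left -= 1
        if self.left < 0:
            self.exhausted = True
        return not self.exhausted


def _pair_hits(
    sets_l: list[frozenset[int] | None],
) -> list[frozenset[tuple[int, int]] | None]:
    """Per offspring at one locus, the set of father allele pairs (p <= q)
    that could have sired it; None for untyped offspring."""
    universe = sorted(set().union(*(s for s in sets_l if s is not None)))
    all_pairs = list(itertools.combinations_with_replacement(universe, 2))
    out: list[frozenset[tuple[int, int]] | None] = []
    for s in sets_l:
        if s is None:
            out.append(None)
        else:
            out.append(frozenset(p for p in all_pairs if p[0] in s or p[1] in s))
    return out


def _partitions(
    n: int,
    k: int,
    hits: list[list[frozenset[tuple[int, int]] | None]],  # [locus][offspring]
    budget: _Budget,
    max_solutions: int,
) -> Iterable[tuple[int, ...]]:
    """Assignments of offspring 0..n-1 to exactly k fathers, canonical
    (offspring may open group g only after g-1 exists).  A group's state is
    its per-locus set of still-feasible father allele pairs, intersected
    incrementally; infeasible branches are pruned immediately."""
    n_loci = len(hits)
    assign = [0] * n
    # state[g][l]: feasible father pairs for group g at locus l (None = unconstrained)
    state: list[list[frozenset | None]] = [[None] * n_loci for _ in range(k)]
    found = 0

    def rec(i: int, used: int):
        nonlocal found
        if found >= max_solutions or not budget.tick():
            return
        if i == n:
            if used == k:
                found += 1
                yield tuple(assign)
            return
        if used + (n - i) < k:  # cannot open enough new groups
            return
        for g in range(min(used + 1, k)):
            saved = state[g]
            new: list[frozenset | None] = [None] * n_loci
            ok = True
            for l in range(n_loci):
                h = hits[l][i]
                if h is None:
                    new[l] = saved[l]
                    continue
                new[l] = h if saved[l] is None else (saved[l] & h)
                if not new[l]:
                    ok = False
                    break
            if not ok:
                continue
            assign[i] = g
            state[g] = new
            yield from rec(i + 1, max(used, g + 1))
            state[g] = saved

    yield from rec(0, 0)


def min_fathers(
    clutch: Clutch,
    max_fathers: int = 4,
    freqs: FreqTable | None = None,
    node_budget: int = 500_000,
    min_locus_coverage: float = 0.5,
    max_solutions: int = 1000,
) -> MinFathersResult:
    """Smallest number of fathers admitting a Mendelian-compatible parentage.

    Exhaustive search in the GERUD spirit: maternal genotypes compatible
    with every offspring are enumerated (or the known mother used), the
    offspring are partitioned among ``k = 1, 2, …`` candidate fathers, and
    the first ``k`` with a fully compatible assignment is returned together
    with every optimal (mother, partition) solution in canonical order.
    The count is a lower bound on the true number of sires by construction.

    Loci typed in fewer than ``min_locus_coverage`` of the offspring are
    excluded (logged); offspring untyped at a used locus impose no
    constraint there.  The search visits at most ``node_budget`` nodes;
    beyond that the result is flagged non-exhaustive.
    """
    n = len(clutch.offspring)
    if n < 1:
        raise ValueError("empty clutch")
    low_power = n < 3

    # locus filter by offspring coverage
    loci_used: list[int] = []
    for i, locus in enumerate(clutch.loci):
        typed = sum(g.alleles[i] is not None for g in clutch.offspring)
        if typed == 0:
            continue
        if typed / n < min_locus_coverage:
            logger.info("locus %s typed in %d/%d offspring; excluded", locus, typed, n)
            continue
        loci_used.append(i)
    if not loci_used:
        raise ValueError(f"clutch {clutch.nest_id}: no usable loci")
    loci_names = tuple(clutch.loci[i] for i in loci_used)

    # maternal candidates
    known_mother = clutch.maternal_genotype
    if known_mother is not None:
        bad = clutch.maternal_incompatibilities()
        if bad:
            oid, locus = bad[0]
            raise IncompatibleMotherError(
                f"clutch {clutch.nest_id}: offspring {oid} shares no allele "
                f"with the known mother at locus {locus}"
            )
        per_locus_mothers = []
        for i in loci_used:
            pair = known_mother.alleles[i]
            if pair is None:
                typed_pairs = [g.alleles[i] for g in clutch.offspring if g.alleles[i]]
                per_locus_mothers.append(_maternal_candidates_locus(typed_pairs))
            else:
                per_locus_mothers.append([pair])
    else:
        per_locus_mothers = []
        for i in loci_used:
            typed_pairs = [g.alleles[i] for g in clutch.offspring if g.alleles[i]]
            cands = _maternal_candidates_locus(typed_pairs)
            if not cands:
                # >4 alleles with no shared one: no single mother exists at all
                raise ValueError(
                    f"clutch {clutch.nest_id}: no single maternal genotype is "
                    f"compatible at locus {clutch.loci[i]} (multiple mothers?)"
                )
            per_locus_mothers.append(cands)

    budget = _Budget(node_budget)
    offspring_pairs = [
        [clutch.offspring[o].alleles[i] for o in range(n)] for i in loci_used
    ]

    # Pre-compute, per maternal multilocus candidate, the paternal-allele
    # requirement sets; then search partitions jointly.
    solutions: list[tuple[MultilocusGenotype, tuple[int, ...]]] = []
    best_k: int | None = None

    def mother_iter():
        for combo in itertools.product(*per_locus_mothers):
            yield combo

    for k in range(1, max_fathers + 1):
        if best_k is not None:
            break
        for combo in mother_iter():
            if not budget.tick():
                break
            # paternal requirement sets per locus; skip incompatible mothers
            psets: list[list[frozenset[int] | None]] = []
            ok = True
            for pairs_l, mpair in zip(offspring_pairs, combo):
                s = _paternal_sets(mpair, pairs_l)
                if s is None:
                    ok = False
                    break
                psets.append(s)
            if not ok:
                continue
            hits = [_pair_hits(sets_l) for sets_l in psets]
            room = max_solutions - len(solutions)
            for assign in _partitions(n, k, hits, budget, room):
                mg = MultilocusGenotype(loci=loci_names, alleles=tuple(combo))
                solutions.append((mg, assign))
            if budget.exhausted or len(solutions) >= max_solutions:
                break
        if solutions:
            best_k = k
        if budget.exhausted:
            break

    built: list[ParentageSolution] = []
    seen: set[tuple] = set()
    for mg, assign in solutions:
        key = (mg.alleles, assign)
        if key in seen:
            continue
        seen.add(key)
        fathers = []
        for fidx in range(max(assign) + 1):
            members = [o for o in range(n) if assign[o] == fidx]
            pairs: list[tuple[int, int] | None] = []
            for li, sets_l in enumerate(
                _paternal_sets(mg.alleles[li2], offspring_pairs[li2])
                for li2 in range(len(loci_used))
            ):
                grp = [sets_l[o] for o in members if sets_l[o] is not None]
                pairs.append(_father_pair(grp))
            fathers.append(MultilocusGenotype(loci=loci_names, alleles=tuple(pairs)))
        ll = None
        if freqs is not None:
            ll = _parental_log_likelihood(mg, fathers, freqs)
        built.append(
            ParentageSolution(
                maternal_genotype=mg,
                paternal_genotypes=tuple(fathers),
                father_assignment=assign,
                log_likelihood=ll,
            )
        )
    if freqs is not None:
        built.sort(key=lambda s: (-(s.log_likelihood or 0.0), s.maternal_genotype.alleles))
    else:
        built.sort(key=lambda s: (s.maternal_genotype.alleles, s.father_assignment))

    return MinFathersResult(
        k=best_k,
        solutions=tuple(built),
        exhaustive=not budget.exhausted,
        low_power=low_power,
        loci_used=loci_names,
        max_fathers=max_fathers,
    )


def _hwe_log_prob(pair: tuple[int, int] | None, locus_freqs: Mapping[int, float]) -> float:
    if pair is None:
        return 0.0
    a, b = pair
    floor = 1e-6
    pa = max(locus_freqs.get(a, 0.0), floor)
    pb = max(locus_freqs.get(b, 0.0), floor)
    return math.log(pa * pa) if a == b else math.log(2 * pa * pb)


def _parental_log_likelihood(
    mother: MultilocusGenotype,
    fathers: Sequence[MultilocusGenotype],
    freqs: FreqTable,
) -> float:
    ll = 0.0
    for g in (mother, *fathers):
        for locus, pair in zip(g.loci, g.alleles):
            if locus in freqs:
                ll += _hwe_log_prob(pair, freqs[locus])
    return ll


# ---------------------------------------------------------------------------
# Lynch & Ritland relatedness

def pooled_frequencies(
    genotypes: Iterable[MultilocusGenotype], pseudocount: float = 0.0
) -> dict[str, dict[int, float]]:
    """Allele frequencies per locus pooled over a set of genotypes."""
    genotypes = list(genotypes)
    if not genotypes:
        raise ValueError("no genotypes supplied")
    loci = genotypes[0].loci
    out: dict[str, dict[int, float]] = {}
    for i, locus in enumerate(loci):
        counts: dict[int, float] = {}
        for g in genotypes:
            pair = g.alleles[i]
            if pair is None:
                continue
            for a in pair:
                counts[a] = counts.get(a, 0.0) + 1.0
        if pseudocount:
            counts = {a: c + pseudocount for a, c in counts.items()}
        tot = sum(counts.values())
        out[locus] = {a: c / tot for a, c in counts.items()} if tot else {}
    return out


def _lr_locus(
    ref: tuple[int, int], prob: tuple[int, int], pf: Mapping[int, float]
) -> tuple[float, float] | None:
    """Per-locus Lynch & Ritland numerator-weighted estimate.

    Returns (W * r, W) for reference genotype (a, b) and proband (c, d),
    or None where the weight is undefined (monomorphic reference alleles).
    """
    a, b = ref
    c, d = prob
    pa, pb = pf.get(a, 0.0), pf.get(b, 0.0)
    if pa <= 0 or pb <= 0:
        return None
    sab = 1.0 if a == b else 0.0
    sac = 1.0 if a == c else 0.0
    sad = 1.0 if a == d else 0.0
    sbc = 1.0 if b == c else 0.0
    sbd = 1.0 if b == d else 0.0
    denom = (1.0 + sab) * (pa + pb) - 4.0 * pa * pb
    if denom <= 0:
        return None  # reference homozygous for a (near-)fixed allele
    r = (pa * (sbc + sbd) + pb * (sac + sad) - 4.0 * pa * pb) / denom
    w = denom / (2.0 * pa * pb)
    return (w * r, w)


def lynch_ritland_pair(
    x: MultilocusGenotype, y: MultilocusGenotype, freqs: FreqTable
) -> float | None:
    """Doubled Lynch & Ritland relatedness for one pair.

    Locus estimates are combined with the estimator's sampling-variance
    weights and averaged over the two reciprocal reference/proband
    orderings; the result is reported on the doubled (−1..1) scale, on
    which full sibs centre at 0.5.  Returns None when no locus is usable.
    """
    vals = []
    for ref, prob in ((x, y), (y, x)):
        num = 0.0
        den = 0.0
        for i, locus in enumerate(ref.loci):
            rp, pp = ref.alleles[i], prob.alleles[i]
            if rp is None or pp is None:
                continue
            pf = freqs.get(locus)
            if not pf:
                logger.debug("locus %s absent from frequency table; skipped", locus)
                continue
            contrib = _lr_locus(rp, pp, pf)
            if contrib is None:
                continue
            num += contrib[0]
            den += contrib[1]
        if den > 0:
            vals.append(num / den)
    if not vals:
        return None
    return float(np.mean(vals))


@dataclass
class RelatednessMatrix:
    """Symmetric doubled Lynch & Ritland matrix with the raw half-scale
    values and the reference frequencies kept alongside."""

    sample_ids: list[str]
    doubled: np.ndarray
    raw: np.ndarray
    freqs: FreqTable

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.doubled, index=self.sample_ids, columns=self.sample_ids)


def lynch_ritland_matrix(
    samples: Sequence[MultilocusGenotype],
    freqs: FreqTable | None = None,
    sample_ids: Sequence[str] | None = None,
) -> RelatednessMatrix:
    """Pairwise doubled Lynch & Ritland matrix over ``samples``.

    When ``freqs`` is omitted the reference frequencies are pooled from the
    samples themselves.  Diagonal entries are the pair estimate of a sample
    with itself.  Estimates outside [−1, 1] are clamped with a log entry.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    if freqs is None:
        freqs = pooled_frequencies(samples)
    ids = list(sample_ids) if sample_ids is not None else [
        f"S{i}" for i in range(len(samples))
    ]
    m = len(samples)
    doubled = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i, m):
            r = lynch_ritland_pair(samples[i], samples[j], freqs)
            if r is None:
                continue
            if not (-1.0 <= r <= 1.0):
                logger.info("relatedness %.3f for (%s, %s) clamped to [-1, 1]", r, ids[i], ids[j])
                r = float(np.clip(r, -1.0, 1.0))
            doubled[i, j] = doubled[j, i] = r
    return RelatednessMatrix(sample_ids=ids, doubled=doubled, raw=doubled / 2.0, freqs=freqs)


def relatedness_heatmap_export(
    matrix: RelatednessMatrix, grouping: Mapping[str, str]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Long-format pair table for plotting, plus within/between-nest means.

    One row per unordered sample pair: sample_i, sample_j, nest_i, nest_j,
    r (doubled), same_nest.
    """
    missing = [s for s in matrix.sample_ids if s not in grouping]
    if missing:
        raise ValueError(f"grouping misses samples: {missing[:5]}")
    rows = []
    ids = matrix.sample_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ni, nj = grouping[ids[i]], grouping[ids[j]]
            rows.append(
                {
                    "sample_i": ids[i],
                    "sample_j": ids[j],
                    "nest_i": ni,
                    "nest_j": nj,
                    "r": matrix.doubled[i, j],
                    "same_nest": ni == nj,
                }
            )
    df = pd.DataFrame(rows)
    within = df.loc[df.same_nest, "r"].mean()
    between = df.loc[~df.same_nest, "r"].mean()
    return df, {"within_nest_mean": float(within), "between_nest_mean": float(between)}
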