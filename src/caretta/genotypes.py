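"""Multilocus microsatellite genotypes, clutches, and the genotype CSV dialect.

A genotype is an unordered allele pair per locus (alleles are positive
integer labels, typically fragment sizes); ``0`` encodes a missing locus in
files.  A clutch is a progeny array from one nest, optionally with a known
maternal genotype and an mtDNA haplotype label.

The file dialect is a GenAlEx-style CSV: ``sample_id``, ``group`` (population
or nest label), then two columns per locus named ``<locus>_1``/``<locus>_2``.
Comment lines start with ``#``; writers emit a provenance comment header and
readers skip it, so write → read round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "MultilocusGenotype",
    "Clutch",
    "GenotypeTable",
    "read_genotype_table",
    "write_genotype_table",
]

AllelePair = Optional[tuple[int, int]]


class GenotypeParseError(ValueError):
    """Malformed genotype file (message names the offending line/column)."""


@dataclass(frozen=True)
class MultilocusGenotype:
    """Unordered allele pairs over a shared, ordered locus list.

    ``alleles[i]`` is a sorted ``(a, b)`` pair of positive ints for locus
    ``loci[i]``, or ``None`` when the locus is untyped.  Homozygotes repeat
    the label.
    """

    loci: tuple[str, ...]
    alleles: tuple[AllelePair, ...]

    def __post_init__(self) -> None:
        if len(self.loci) != len(self.alleles):
            raise ValueError("loci and alleles have different lengths")
        fixed = []
        for loc, pair in zip(self.loci, self.alleles):
            if pair is None:
                fixed.append(None)
                continue
            a, b = pair
            if a <= 0 or b <= 0:
                raise ValueError(f"non-positive allele at locus {loc}: {pair}")
            fixed.append((a, b) if a <= b else (b, a))
        object.__setattr__(self, "alleles", tuple(fixed))

    def at(self, locus: str) -> AllelePair:
        return self.alleles[self.loci.index(locus)]

    @property
    def typed_loci(self) -> tuple[str, ...]:
        return tuple(l for l, p in zip(self.loci, self.alleles) if p is not None)

    def n_typed(self) -> int:
        return sum(p is not None for p in self.alleles)

    def shares_allele(self, other: "MultilocusGenotype", locus_index: int) -> bool | None:
        """True/False if both typed at the locus, None if either is missing."""
        a, b = self.alleles[locus_index], other.alleles[locus_index]
        if a is None or b is None:
            return None
        return bool(set(a) & set(b))


@dataclass
class Clutch:
    """Progeny array from a single nest."""

    nest_id: str
    offspring: list[MultilocusGenotype]
    maternal_genotype: MultilocusGenotype | None = None
    mtdna_haplotype: str | None = None
    offspring_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.offspring:
            raise ValueError(f"clutch {self.nest_id} has no offspring")
        loci = self.offspring[0].loci
        for g in self.offspring[1:]:
            if g.loci != loci:
                raise ValueError(f"clutch {self.nest_id}: offspring loci differ")
        if self.maternal_genotype is not None and self.maternal_genotype.loci != loci:
            raise ValueError(f"clutch {self.nest_id}: maternal loci differ from offspring")
        if not self.offspring_ids:
            self.offspring_ids = [
                f"{self.nest_id}_{i + 1}" for i in range(len(self.offspring))
            ]

    @property
    def loci(self) -> tuple[str, ...]:
        return self.offspring[0].loci

    def maternal_incompatibilities(self) -> list[tuple[str, str]]:
        """(offspring_id, locus) pairs where an offspring shares no allele
        with the known mother at a fully typed locus."""
        if self.maternal_genotype is None:
            return []
        bad = []
        for oid, g in zip(self.offspring_ids, self.offspring):
            for i, locus in enumerate(self.loci):
                if g.shares_allele(self.maternal_genotype, i) is False:
                    bad.append((oid, locus))
        return bad


@dataclass
class GenotypeTable:
    """A set of genotypes with per-sample group labels, in file order."""

    sample_ids: list[str]
    groups: list[str]
    genotypes: list[MultilocusGenotype]

    def __post_init__(self) -> None:
        if not (len(self.sample_ids) == len(self.groups) == len(self.genotypes)):
            raise ValueError("sample_ids, groups and genotypes differ in length")

    @property
    def loci(self) -> tuple[str, ...]:
        return self.genotypes[0].loci if self.genotypes else ()

    def by_group(self) -> dict[str, list[MultilocusGenotype]]:
        out: dict[str, list[MultilocusGenotype]] = {}
        for grp, g in zip(self.groups, self.genotypes):
            out.setdefault(grp, []).append(g)
        return out

    def __len__(self) -> int:
        return len(self.sample_ids)


def read_genotype_table(path: str | Path) -> GenotypeTable:
    """Read the genotype CSV dialect; ``0`` (either column) means missing."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str)
    cols = list(df.columns)
    if len(cols) < 4 or cols[0] != "sample_id" or cols[1] != "group":
        raise GenotypeParseError(
            f"{path}: header must start with sample_id,group and >=1 locus pair"
        )
    locus_cols = cols[2:]
    if len(locus_cols) % 2:
        raise GenotypeParseError(f"{path}: odd number of allele columns")
    loci = []
    for i in range(0, len(locus_cols), 2):
        c1, c2 = locus_cols[i], locus_cols[i + 1]
        if not (c1.endswith("_1") and c2.endswith("_2") and c1[:-2] == c2[:-2]):
            raise GenotypeParseError(
                f"{path}: locus columns must come in <name>_1,<name>_2 pairs "
                f"(got {c1!r}, {c2!r})"
            )
        loci.append(c1[:-2])
    loci_t = tuple(loci)

    seen: set[str] = set()
    sample_ids, groups, genotypes = [], [], []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        sid = str(row[0])
        if sid in seen:
            raise GenotypeParseError(f"{path}: duplicated sample id {sid!r} (row {row_no})")
        seen.add(sid)
        pairs: list[AllelePair] = []
        for j, locus in enumerate(loci_t):
            raw1, raw2 = row[2 + 2 * j], row[3 + 2 * j]
            try:
                a, b = int(raw1), int(raw2)
            except (TypeError, ValueError):
                raise GenotypeParseError(
                    f"{path}: non-integer allele at row {row_no}, locus {locus}: "
                    f"{raw1!r}/{raw2!r}"
                ) from None
            if a < 0 or b < 0:
                raise GenotypeParseError(
                    f"{path}: negative allele at row {row_no}, locus {locus}"
                )
            pairs.append(None if (a == 0 or b == 0) else (a, b))
        sample_ids.append(sid)
        groups.append(str(row[1]))
        genotypes.append(MultilocusGenotype(loci=loci_t, alleles=tuple(pairs)))
    return GenotypeTable(sample_ids=sample_ids, groups=groups, genotypes=genotypes)


def write_genotype_table(
    table: GenotypeTable, path: str | Path, *, header_note: str | None = None
) -> None:
    path = Path(path)
    loci = table.loci
    rows = []
    for sid, grp, g in zip(table.sample_ids, table.groups, table.genotypes):
        row: dict[str, object] = {"sample_id": sid, "group": grp}
        for locus, pair in zip(loci, g.alleles):
            a, b = pair if pair is not None else (0, 0)
            row[f"{locus}_1"] = a
            row[f"{locus}_2"] = b
        rows.append(row)
    with path.open("w") as fh:
        fh.write(f"# caretta genotype table; {len(table)} samples, {len(loci)} loci\n")
        if header_note:
            fh.write(f"# {header_note}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)
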