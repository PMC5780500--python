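"""Minimum-father reconstruction on a simulated half-sib clutch.

Simulates a clutch of 12 hatchlings sired by two fathers, screens it for
multiple paternity by parental-allele counting, and reconstructs the
minimal set of fathers by exhaustive Mendelian search.
"""

import numpy as np

import caretta as ct
from caretta.synthetic import draw_parent

panel, truth = ct.simulate_baseline(ct.SimulationConfig(seed=1))
rng = np.random.default_rng(7)
mother = draw_parent(rng, truth, ct.MED)
fathers = [draw_parent(rng, truth, ct.MED) for _ in range(2)]
clutch, sires = ct.simulate_clutch(mother, fathers, 12, rng, include_mother=False)

screen = ct.detect_multiple_paternity(clutch)
print(f"multiple-paternity screen: {screen.flag} (evidence at {screen.evidencing_loci})")

res = ct.min_fathers(clutch)
print(f"minimum fathers: {res.label} (simulated truth: 2)")
print(f"{len(res.solutions)} optimal parentage solutions; exhaustive={res.exhaustive}")
sol = res.solutions[0]
print("one reconstructed mother:", dict(zip(sol.maternal_genotype.loci, sol.maternal_genotype.alleles)))

print(
    "\nA locus with more than four distinct alleles proves a second father;\n"
    "the search returns the smallest father count compatible with Mendelian\n"
    "inheritance, a lower bound on the true number of sires."
)
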