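"""Temperature x propagule-pressure sweep of the colonisation model.

Runs the annual recursion at the six grid temperatures and four propagule
pressure rates, and prints the year in which each scenario first sustains
20 nesting females (the size of the smallest Mediterranean rookeries).
"""

import caretta as ct

grid = ct.default_grid()
base = ct.DemographicParams(pr=1.0, tsd=ct.params_at(grid, 31.0))
sweep = ct.scenario_sweep(grid, grid.temperatures, (0.01, 0.1, 1.0, 10.0), base, 1000)

print("Year to reach 20 nesting females (— = never within 1,000 y):")
print("temp (C) " + "".join(f"  Pr={pr:<6g}" for pr in (0.01, 0.1, 1.0, 10.0)))
for t in grid.temperatures:
    cells = []
    for pr in (0.01, 0.1, 1.0, 10.0):
        y = ct.establishment_year(sweep[(t, pr)], 20.0)
        cells.append(f"{y:>9}" if y != ct.NOT_REACHED else f"{'—':>9}")
    print(f"{t:7.1f} " + "".join(cells))

print(
    "\nNo colonisation at 28 C (all-male nests); warmer nests colonise faster\n"
    "until extreme heat (33 C) collapses emergence success, and higher\n"
    "propagule pressure shortens establishment by decades to centuries."
)
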