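"""Generate a VCU-like trial skeleton and compare it with the historical
summary counts it is built to reproduce.

The generator knows only summary parameters (34 years, 120 locations,
cohorts of 60-120 entries culled by 51%/26%, 11/13/24 locations per
series-year, a 48-variety check panel) and recreates a plausible layout:
overlapping three-year cycles, survivor slots, and checks grown in every
trial of their active years.
"""

from vcusim import StructureParams, build_structure, structure_summary

structure = build_structure(StructureParams(seed=1))
summary = structure_summary(structure)
print(summary.to_string())
print()
print(
    f"candidate observations: {summary['observations_candidates']:,} "
    "(historical series: 64,792; the generator reproduces summary counts, "
    "not the exact historical cells)"
)
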