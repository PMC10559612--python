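#!/usr/bin/env python
"""Generate one synthetic parameter workbook per region archetype.

Writes validator-clean workbooks (tasks, fertility, mortality, seasonality,
population, region metadata) under results/params/<archetype>/ and prints a
one-line profile of each: catalog size, fertility level and direction at ages
20-24, and the under-five population share.
"""

from pathlib import Path

from phcworkload import ARCHETYPES, generate_region, validate, write_region_parameters

SEED = 2020
OUT = Path(__file__).resolve().parents[1] / "results" / "params"


def main() -> None:
    for name in sorted(ARCHETYPES):
        region = generate_region(name, seed=SEED)
        violations = validate(region)
        assert violations == [], violations
        out_dir = OUT / name
        write_region_parameters(region, out_dir)
        pyr = region.baseline_pyramid
        u5 = pyr.count("both", 0, 4) / pyr.total()
        f2024 = region.fertility.bands["20-24"]
        trend = region.fertility.annual_change["20-24"]
        print(
            f"{name}: {len(region.tasks)} tasks, fertility(20-24) {f2024:.3f} "
            f"({'rising' if trend > 1 else 'declining'} at {abs(trend - 1) * 100:.1f}%/yr), "
            f"under-five share {u5:.1%} -> {out_dir}"
        )


if __name__ == "__main__":
    main()
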