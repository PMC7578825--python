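#!/usr/bin/env python
"""Generate the four synthetic input tables the downstream analyses consume.

Writes diet, isotope, consumer and gut-fullness CSVs under results/data/,
parameterized with the published group summaries (sample sizes, isotope
means/SDs, diet baselines) so every later stage runs on data with the
structure the real study assumed.
"""

from pathlib import Path

from trophicniche import simulate

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    dm = simulate.simulate_diet(simulate.DietSimConfig(seed=SEED))
    dm.data.to_csv(OUT / "diet.csv", index=False)

    it = simulate.simulate_isotopes(
        simulate.IsotopeSimConfig(seed=SEED),
        sl_model={
            "small_juvenile": (143.6, 17.5),
            "large_juvenile": (193.9, 14.6),
            "sub_adult": (241.5, 14.4),
            "adult": (287.3, 18.5),
        },
    )
    it.data.to_csv(OUT / "isotopes.csv", index=False)

    cons = simulate.simulate_consumers(simulate.MixSimConfig(seed=SEED))
    cons.data.to_csv(OUT / "consumers.csv", index=False)

    ft = simulate.simulate_fullness(simulate.FullnessSimConfig(seed=SEED))
    ft.data.to_csv(OUT / "fullness.csv", index=False)

    for name in ("diet", "isotopes", "consumers", "fullness"):
        n = sum(1 for _ in open(OUT / f"{name}.csv")) - 1
        print(f"wrote {name}.csv ({n} rows)")


if __name__ == "__main__":
    main()
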