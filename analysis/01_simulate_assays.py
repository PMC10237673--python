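#!/usr/bin/env python
"""Generate the synthetic study datasets.

Emulates the study's experiments with the package generators: mating-duration
assays for the four strains at their reported effect sizes, an exposure-time
series, fecundity arms, two-sire crosses and the CaLexA fluorescence readout.
Writes tidy CSVs under results/data/.
"""

from pathlib import Path

from mateguard.simulate import (
    AssayDesign,
    CrossDesign,
    FecundityDesign,
    FluorescenceDesign,
    exposure_time_reduction,
    generate_calexa,
    generate_fecundity,
    generate_md_assay,
    generate_paternity,
)

SEED = 20230522
OUT = Path(__file__).resolve().parents[1] / "results" / "data"

# reported per-strain shortening of mean mating duration, percent
STRAIN_EFFECTS = {"CS": 15.7, "WT-Berlin": 15.8, "Oregon-R": 15.7, "w1118": 12.4}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    for i, (strain, effect) in enumerate(STRAIN_EFFECTS.items()):
        design = AssayDesign(
            groups=((strain, "naive", 40), (strain, "experienced", 40)),
            percent_reduction=effect,
            seed=SEED + i,
        )
        table = generate_md_assay(design)
        table.to_csv(OUT / f"md_{strain.replace('-', '_')}.csv", index=False)
        print(f"{strain}: {len(table)} males, configured reduction {effect}%")

    # exposure-time series: arms at or below 6 h show no effect
    arms = []
    for hours in (2, 6, 12, 24):
        cond = "experienced" if exposure_time_reduction(hours) > 0 else "naive"
        arms.append((f"CS_{hours}h", cond, 40))
    design = AssayDesign(
        groups=(("CS_naive", "naive", 40), *arms),
        percent_reduction=15.7,
        seed=SEED + 10,
    )
    generate_md_assay(design).to_csv(OUT / "md_exposure_time.csv", index=False)
    print("exposure-time series: naive + 4 arms (2/6/12/24 h)")

    generate_fecundity(FecundityDesign(seed=SEED + 20)).to_csv(
        OUT / "fecundity.csv", index=False
    )
    generate_paternity(CrossDesign(seed=SEED + 21)).to_csv(
        OUT / "crosses_se_first.csv", index=False
    )
    generate_paternity(
        CrossDesign(
            seed=SEED + 22, first_sire_genotype="+/+", second_sire_genotype="se/se"
        )
    ).to_csv(OUT / "crosses_cs_first.csv", index=False)
    generate_calexa(FluorescenceDesign(seed=SEED + 23)).to_csv(
        OUT / "calexa.csv", index=False
    )
    print(f"fecundity, paternity (both sire orders) and CaLexA tables -> {OUT}")


if __name__ == "__main__":
    main()
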