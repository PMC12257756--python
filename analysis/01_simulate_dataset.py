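"""Simulate the working dataset for the damage-trait analysis.

Generates a six-line pig population (~5k scored animals on 13 farms) with
ordinal 0-3 ear and tail damage scores from the liability model, derives
the seven trait definitions, and writes pedigree/phenotype/truth files plus
the config echo under results/dataset/.
"""

import argparse
from pathlib import Path

from pigdamage import SimulationConfig, simulate_dataset, write_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/dataset"))
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed, phenotype_mode="ordinal")
    ds = simulate_dataset(cfg)
    write_dataset(ds, args.outdir)

    pheno = ds.phenotypes
    print(f"pedigree animals : {len(ds.pedigree)}")
    print(f"scored animals   : {len(pheno)}")
    print(f"lines            : {pheno['line'].nunique()}, "
          f"litters {pheno['litter'].nunique()}, "
          f"pens {pheno['pen'].nunique()}")
    for trait in ("ED03", "TD03"):
        counts = pheno[trait].value_counts(normalize=True).sort_index()
        pretty = ", ".join(f"{s}: {p:.1%}" for s, p in counts.items())
        print(f"{trait} score prevalence  {pretty}")
    print(f"files written to {args.outdir}/")


if __name__ == "__main__":
    main()
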