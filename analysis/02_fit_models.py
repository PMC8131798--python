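"""Fit the sex-specific animal model for each of the four behaviours.

Reads the simulated study from results/study/input/ (run
01_simulate_study.py first), fits aggression (dyadic, with contest
variance), activity and exploration (log scale) and boldness by Gibbs
sampling, and saves the posterior draw tables under results/study/<trait>/.
Profile: pass "full" as the second argument for the long chains
(130k iterations); default is the desk-scale test profile (13k).
"""

import sys
from pathlib import Path

import pandas as pd

from spiderqg.model import ChainConfig, ModelSpec, build_model, gibbs_fit
from spiderqg.pedigree import read_pedigree
from spiderqg.simulate import TRAIT_PRESETS

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
PROFILE = sys.argv[2] if len(sys.argv) > 2 else "test"
IN = Path("results/study/input")
OUT = Path("results/study")


def main() -> None:
    ped = read_pedigree(IN / "pedigree.csv")
    pheno = pd.read_csv(IN / "phenotypes.csv", keep_default_na=False)
    pheno["value"] = pheno["value"].astype(float)
    make = ChainConfig.full if PROFILE == "full" else ChainConfig.test
    for k, (trait, preset) in enumerate(TRAIT_PRESETS.items()):
        spec = ModelSpec(trait=trait, transform=preset.transform,
                         dyadic=preset.dyadic)
        state = build_model(pheno, ped, spec)
        draws = gibbs_fit(state, chain=make(seed=SEED + 7919 * (k + 1)))
        tdir = OUT / trait
        tdir.mkdir(parents=True, exist_ok=True)
        draws.save(tdir / "draws.csv")
        print(f"[{trait}] {len(draws)} retained draws -> {tdir/'draws.csv'}")
        print(draws.draws.mean().round(4).to_string())


if __name__ == "__main__":
    main()
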