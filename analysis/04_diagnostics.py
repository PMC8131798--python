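"""Convergence diagnostics for every fitted chain.

Runs Heidelberger-Welch stationarity and halfwidth tests, lag-1
autocorrelation and effective sample size on each parameter's retained
draws and writes per-trait diagnostic tables.  The cross-sex covariance
chain is the one to watch: with weak additive signal its halfwidth test
can fail while stationarity passes.
"""

from pathlib import Path

from spiderqg.diagnostics import diagnose_draws
from spiderqg.model import PosteriorDraws
from spiderqg.simulate import TRAIT_PRESETS

IN = Path("results/study")


def main() -> None:
    for trait in TRAIT_PRESETS:
        draws_path = IN / trait / "draws.csv"
        if not draws_path.exists():
            print(f"[{trait}] no draws found, skipping")
            continue
        draws = PosteriorDraws.load(draws_path)
        cols = draws.draws
        if not TRAIT_PRESETS[trait].dyadic:
            cols = cols.loc[:, cols.columns != "V_C"]
        report = diagnose_draws(cols)
        frame = report.to_frame()
        frame.to_csv(IN / trait / "diagnostics.csv", index=False)
        failing = report.failing_halfwidth()
        print(f"[{trait}] stationary: {report.all_stationary}; "
              f"halfwidth failing: {failing or 'none'}")


if __name__ == "__main__":
    main()
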