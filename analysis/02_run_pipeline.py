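"""Run the full pipeline on the simulated site (after 01_simulate_site.py).

Writes calibrated dates, the phase-model posterior, the exclusion ledger,
proxy time series and their correlations into results/run/.
"""

from pathlib import Path

from shelterchron.cli import RunConfig, run_pipeline
from shelterchron.phase_model import SamplerSettings

ROOT = Path(__file__).resolve().parent.parent / "results"
SITE = ROOT / "site"


def main() -> None:
    config = RunConfig(
        curve=SITE / "curve.txt",
        dates=SITE / "dates.csv",
        thickness=SITE / "thickness.csv",
        botanical=SITE / "botanical.csv",
        concordance=SITE / "concordance.yaml",
        model_spec=SITE / "model_spec.yaml",
        outdir=ROOT / "run",
        sampler=SamplerSettings(iterations=6_000, burn_in=3_000, thinning=5, seed=42),
    )
    outdir = run_pipeline(config)
    print(f"pipeline complete: {outdir}")
    for p in sorted(outdir.iterdir()):
        print(f"  {p.name}")


if __name__ == "__main__":
    main()
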