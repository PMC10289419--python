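"""Generate the default 16-phase synthetic site into results/site/."""

from pathlib import Path

from shelterchron import synthetic_data

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results" / "site"


def main() -> None:
    config = synthetic_data.default_site_config()
    truth, dates, thickness, botanical = synthetic_data.simulate_site(config, SEED)
    paths = synthetic_data.write_site(truth, dates, thickness, botanical, OUT)
    print(f"simulated {len(dates)} dates, {len(botanical)} botanical specimens")
    print(f"phases: {len(config.phases)}; planted shifted dates: {truth.outlier_ids}")
    for name, p in paths.items():
        print(f"  {name}: {p}")


if __name__ == "__main__":
    main()
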