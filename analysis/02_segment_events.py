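"""Segment every full day into stationary events and tabulate them.

Reads the fixture cohort written by 01_simulate_cohort.py, applies the
cleaning rules (full 00:00-24:00 days only, alarm-clock exclusions), runs
PELT with the default 3*log(n) penalty, and writes the labeled events table
(mu, sigma2, phi, T plus subgroup labels) and the per-subgroup segment-count
summary under results/.
"""

import pathlib

import pandas as pd

from elf_expochar import pipeline, segmentation

FIXTURES = pathlib.Path("results/fixtures")
OUT = pathlib.Path("results")


def main() -> None:
    config = pipeline.RunConfig(fixtures_dir=str(FIXTURES))
    days = pipeline._load_days(config)
    events = pipeline.segment_days(days, config.segmentation)
    df = segmentation.events_to_frame(events)
    df.to_csv(OUT / "events.csv", index=False, float_format="%.12g")
    summary = pipeline.summarize_events(df)
    summary.to_csv(OUT / "summary.csv", index=False)

    print(f"{len(days)} full days -> {len(df)} events "
          f"({len(df) / len(days):.1f} per day) -> results/events.csv")
    dn = df.daynight.value_counts()
    print(f"day: {dn.get('day', 0)} segments, night: {dn.get('night', 0)} segments")
    print("median event: "
          + df.groupby("daynight")[["mu_uT", "T_s"]].median().round(4).to_string())


if __name__ == "__main__":
    main()
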