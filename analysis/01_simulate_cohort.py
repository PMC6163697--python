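"""Simulate the study cohort and write it to disk as fixture files.

Generates a 20-subject synthetic cohort of 24-h personal exposure days at a
30-s sample interval (piecewise-stationary AR(1) days with day/night
contrast, clipped to the 0.01-300 µT sensor window) and writes recordings,
subject metadata, and the ground-truth segment table under
results/fixtures/.
"""

import pathlib
import sys

from elf_expochar import synthetic

OUT = pathlib.Path("results/fixtures")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    cohort = synthetic.CohortSpec(n_subjects=20, seed=SEED)
    manifest = synthetic.write_fixture_cohort(cohort, OUT)
    n_rec = len(manifest["recordings"])
    print(f"cohort seed {SEED}: {cohort.n_subjects} subjects, "
          f"{n_rec} day recordings of {86_400 // cohort.sample_interval_s} samples -> {OUT}")
    print("files: metadata.csv, ground_truth.csv, manifest.json, recordings/*.csv")


if __name__ == "__main__":
    main()
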