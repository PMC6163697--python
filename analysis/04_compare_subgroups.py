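"""Do event subgroups share a distribution? Subsampled energy tests.

For each pair of levels (day vs night, then the age groups), repeatedly
subsamples events from both pools, runs the permutation energy test on the
standardized 4-D parameter vectors, and summarizes the p-value histogram:
fraction below 0.05, sup-distance to the uniform CDF, and Storey's FDR.
Subsample size and repetitions are scaled to desk size; pass a different
seed as the first argument to re-randomize.
"""

import json
import pathlib
import sys

import numpy as np
import pandas as pd

from elf_expochar import comparison, pipeline

EVENTS = pathlib.Path("results/events.csv")
OUT = pathlib.Path("results/compare")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
M, REPS, B = 100, 300, 199


def main() -> None:
    df = pd.read_csv(EVENTS).fillna("")
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    reports = []
    for dim in ("daynight", "age"):
        pools = pipeline._pools_for_dimension(df, dim)
        levels = sorted(pools)
        for i, a in enumerate(levels):
            for b in levels[i + 1:]:
                if min(len(pools[a]), len(pools[b])) < 20:
                    print(f"{dim}: {a} vs {b} skipped (pool below 20 events)")
                    continue
                res = comparison.mc_pvalue_histogram(
                    pools[a], pools[b], m=M, reps=REPS, B=B, rng=rng)
                verdict = "different" if res.fraction_below(0.05) > 0.5 else "similar"
                print(f"{dim}: {a} (n={len(pools[a])}) vs {b} (n={len(pools[b])}): "
                      f"frac(p<0.05)={res.fraction_below(0.05):.2f}, "
                      f"FDR={res.fdr.value:.3g} -> {verdict}")
                for note in res.notes:
                    print(f"  note: {note}; with m near the pool size the "
                          f"subsamples repeat, so the histogram degenerates "
                          f"toward a single test of the finite pools")
                safe = f"{dim}_{a}_vs_{b}".replace(" ", "_").replace("/", "-")
                pd.DataFrame({"p_value": res.p_values}).to_csv(
                    OUT / f"{safe}_pvalues.csv", index=False, float_format="%.6g")
                reports.append({
                    "dimension": dim, "level_a": a, "level_b": b,
                    "m": res.m, "reps": res.reps, "B": res.B,
                    "fraction_below_0.05": res.fraction_below(0.05),
                    "uniformity_distance": res.uniformity_distance,
                    "fdr_estimate": res.fdr.value,
                })
    with open(OUT / "summary.json", "w") as fh:
        json.dump(reports, fh, indent=2)
    print(f"{len(reports)} comparisons -> results/compare/summary.json")


if __name__ == "__main__":
    main()
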