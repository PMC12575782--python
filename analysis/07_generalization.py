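#!/usr/bin/env python
"""Full generalization battery: corridor length, exhaustive cue-removal
subsets, the distractor cue, and Gaussian cue noise."""

from hcnav.generalization import summarize_by_count
from hcnav.reproduce import reproduce

OUT = "results"
SEEDS = (0, 1, 2)


def main():
    tables = reproduce("fig8_generalization", scale="desk", seeds=SEEDS,
                       out_dir=OUT, n_eval=20)
    t = tables["variants"]

    corridor = t[t["variant"].str.startswith("corridor")]
    print("Corridor-length generalization (success, mean over seeds):")
    print(corridor.groupby(["model", "variant"])["success"].mean()
          .unstack().round(2))

    removal = t[t["variant"].str.startswith("remove")]
    print("\nCue removal by count removed:")
    for model, grp in removal.groupby("model"):
        agg = summarize_by_count(grp)
        print(model)
        print(agg.pivot(index="n_removed", columns="subtask",
                        values="success").round(2))

    dist = t[t["variant"] == "distractor"]
    print("\nDistractor success (mean over seeds):")
    print(dist.groupby(["model", "subtask"])["success"].mean().unstack()
          .round(2))

    noise = t[t["variant"].str.startswith("noise")]
    print("\nGaussian cue-noise robustness:")
    print(noise.groupby(["model", "variant"])["success"].mean().unstack()
          .round(2))


if __name__ == "__main__":
    main()
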