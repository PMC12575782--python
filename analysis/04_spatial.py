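#!/usr/bin/env python
"""Place-field metrics of CA1 units: spatial information, sparsity and
coherence per unit, compared between recurrent and feedforward agents."""

from hcnav.reproduce import reproduce

OUT = "results"
SEEDS = (0, 1, 2)


def main():
    tables = reproduce("fig5_spatial", scale="scaled", seeds=SEEDS,
                       out_dir=OUT, n_eval=40)
    t = tables["place_metrics"]
    summary = t.groupby("model")[["si", "sparsity", "coherence"]].median()
    print("Median place-field metrics over CA1 units (all seeds):")
    print(summary.round(3))
    print("\nHigher spatial information with lower sparsity for the "
          "recurrent model indicates more selective spatial coding.")


if __name__ == "__main__":
    main()
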