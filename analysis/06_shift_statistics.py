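"""Image-level shift quantification and heatmap border-mass analysis.

Computes the 17 descriptors on paired synthetic image cohorts (clutter 0.8
vs a clutter-free null), runs the class-paired Wilcoxon / Cohen's d tests
with Bonferroni correction, and reports the border activation ratio of
centered vs border-shifted attention maps.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from fieldshift.shiftstats import border_mass_ratio, descriptor_table, shift_report
from fieldshift.synthetic import make_heatmap, make_image_cohort


def cohort_report(clutter: float, seed: int) -> pd.DataFrame:
    coh = make_image_cohort(4, image_size=64, clutter_level=clutter,
                            n_classes=21, seed=seed)
    dfs = descriptor_table(coh["source"][0])
    dft = descriptor_table(coh["target"][0])
    desc = pd.concat([dfs, dft], ignore_index=True)
    labels = np.r_[coh["source"][1], coh["target"][1]]
    domains = np.r_[["source"] * len(dfs), ["target"] * len(dft)]
    return shift_report(desc, labels, domains)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    rep = cohort_report(0.8, args.seed)
    rep.to_csv(args.out_dir / "shift_report_clutter08.csv", index=False)
    print("clutter 0.8 — top descriptors by effect size:")
    print(rep.head(6)[["metric", "cohens_d", "delta", "p_raw", "p_bonferroni"]]
          .to_string(index=False))

    null = cohort_report(0.0, args.seed + 1)
    null.to_csv(args.out_dir / "shift_report_null.csv", index=False)
    print(f"clutter 0 null — Bonferroni-significant descriptors: "
          f"{int(null['significant'].sum())} (expect 0)")

    centered = make_heatmap(56, center=(28, 28), sigma=6)
    drifted = make_heatmap(56, center=(4, 50), sigma=6)
    ratios = {
        "centered_attention": border_mass_ratio(centered),
        "border_drifted_attention": border_mass_ratio(drifted),
        "uniform_10x10": border_mass_ratio(np.ones((10, 10))),
    }
    (args.out_dir / "border_mass.json").write_text(json.dumps(ratios, indent=2))
    print("border activation ratio:",
          {k: round(v, 4) for k, v in ratios.items()})


if __name__ == "__main__":
    main()
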