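"""Simplex-line fits between every pair of layers.

For each unordered layer pair the 3-part subcomposition [layer i, layer j,
gmean of the rest] is fitted with the linear process x(t) = x0 ⊕ (t ⊗ v); the
direction v describes the mechanism moving relative activity between the pair
and the background, and the share of variance on the line measures how
one-dimensional the relationship is.  Pairs with small log-ratio variance
(near-proportional layers) travel together against the rest.
"""

from pathlib import Path

from soilcoda.io import read_profiles
from soilcoda.profiles import close_profiles, layer_table, pairwise_process_report

OUT = Path("results")


def main():
    records = read_profiles(OUT / "profiles.csv")
    comps, _ = close_profiles(records, layers=5)
    parts, _ = layer_table(comps)
    rep = pairwise_process_report(parts.to_numpy(), labels=list(parts.columns))
    rep.to_csv(OUT / "process_fits.csv", index=False)

    rep_sorted = rep.sort_values("vr")
    print("pairwise simplex-line fits (sorted by log-ratio variance):")
    cols = ["layer_i", "layer_j", "v_i", "v_j", "v_rest", "share_of_variance", "vr", "gm_ratio"]
    print(rep_sorted[cols].round(3).to_string(index=False))
    best = rep_sorted.iloc[0]
    print(f"\nmost proportional pair: ({best['layer_i']}, {best['layer_j']}), "
          f"v = [{best['v_i']:.2f}, {best['v_j']:.2f}, {best['v_rest']:.2f}]")


if __name__ == "__main__":
    main()
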