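"""Variation matrix and the exhaustive balance screen.

Two screens are produced.  The first reconstructs the published balance
ranking directly from the printed pairwise log-ratio variance matrix — no raw
data needed, since any balance variance is the quadratic form -(1/2) aᵀ T a —
and should range from 0.43 to 4.2 over the 90 possible balances, with the
litter pair (w1, w2) at the bottom and the surface-vs-depth split
(w1·w2·w3 | w4·w5) at the top.  The second runs the same screen on the
synthetic survey's empirical variation matrix.
"""

from pathlib import Path

import pandas as pd

from soilcoda import reference
from soilcoda.balances import balance_screen, variation_matrix
from soilcoda.io import read_profiles
from soilcoda.profiles import close_profiles, layer_table

OUT = Path("results")


def main():
    pub = balance_screen(
        reference.reference_variation(),
        labels=reference.LAYERS,
        from_variation=True,
    )
    pub.to_csv(OUT / "balance_screen_published.csv", index=False)
    lo, hi = pub.iloc[0], pub.iloc[-1]
    print(f"published reconstruction: {len(pub)} balances, "
          f"variance range {lo['variance']:.3f} .. {hi['variance']:.2f}")
    print(f"  lowest:  {lo['plus_parts']} | {lo['minus_parts']}")
    print(f"  highest: {hi['plus_parts']} | {hi['minus_parts']}")

    records = read_profiles(OUT / "profiles.csv")
    comps, _ = close_profiles(records, layers=5)
    parts, _ = layer_table(comps)
    T = variation_matrix(parts.to_numpy())
    pd.DataFrame(T, index=parts.columns, columns=parts.columns).to_csv(OUT / "vr_matrix.csv")
    syn = balance_screen(parts.to_numpy(), labels=list(parts.columns))
    syn.to_csv(OUT / "balance_screen_synthetic.csv", index=False)
    print(f"\nsynthetic survey: variance range "
          f"{syn['variance'].min():.3f} .. {syn['variance'].max():.2f}")
    print(f"  lowest balance: {syn.iloc[0]['plus_parts']} | {syn.iloc[0]['minus_parts']}")


if __name__ == "__main__":
    main()
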