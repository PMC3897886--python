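"""Quantify stripe and boundary dynamics from the integrated atlases.

Reads the stripe tables written by 04_build_atlases.py and reports the
headline comparative quantities: total anterior shift per Eve stripe (in
% EL and in nuclei), the Hb posterior-boundary shift between T3 and T8,
and the total Eve domain width (stripe 1 to 6 for the midge preset,
1 to 7 for the fly preset) per late time class, compared across presets
with a two-sided Welch t-test on unranked and ranked data.
"""

from pathlib import Path

import pandas as pd

from blastoderm_atlas import domain_width, welch_test

RESULTS = Path(__file__).resolve().parent.parent / "results"
LATE_CLASSES = ["T5", "T6", "T7", "T8"]


def main() -> None:
    shifts = {}
    widths = {}
    for species, last_stripe in (("clogmia", 6), ("drosophila", 7)):
        base = RESULTS / species
        if not base.exists():
            raise SystemExit(f"{base} missing - run 04_build_atlases.py first")
        shifts[species] = pd.read_csv(base / "stripe_shifts.tsv", sep="\t")
        stripe_table = pd.read_csv(base / "stripe_table.tsv", sep="\t")
        widths[species] = domain_width(stripe_table, 1, last_stripe)
        boundaries = pd.read_csv(base / "hb_boundaries.tsv", sep="\t")
        post = boundaries[boundaries["side"] == "posterior"].set_index("time_class")
        if {"T3", "T8"} <= set(post.index):
            drift = post.loc["T3", "position"] - post.loc["T8", "position"]
            print(f"{species}: Hb posterior boundary shift T3->T8 = {drift:.2f}% EL")
        mean_nuc = shifts[species]["shift_nuclei"].mean()
        print(f"{species}: mean Eve stripe shift = "
              f"{shifts[species]['shift'].mean():.2f}% EL ({mean_nuc:.2f} nuclei)")
        print(shifts[species].round(2).to_string(index=False))

    w_c = widths["clogmia"].reindex(LATE_CLASSES).dropna()
    w_d = widths["drosophila"].reindex(LATE_CLASSES).dropna()
    print("\nEve domain widths (% EL), T5-T8:")
    print(pd.DataFrame({"clogmia s1-s6": w_c, "drosophila s1-s7": w_d}).round(2).to_string())
    res = welch_test(w_c, w_d)
    res_r = welch_test(w_c, w_d, ranked=True)
    print(f"Welch t-test (unranked): t = {res.t:.2f}, df = {res.df:.2f}, p = {res.p:.2e}")
    print(f"Welch t-test (ranked):   t = {res_r.t:.2f}, df = {res_r.df:.2f}, p = {res_r.p:.2e}")
    summary = pd.DataFrame({
        "quantity": ["welch_t", "welch_df", "welch_p", "welch_p_ranked"],
        "value": [res.t, res.df, res.p, res_r.p],
    })
    summary.to_csv(RESULTS / "width_comparison.tsv", sep="\t", index=False)
    print(f"-> {RESULTS / 'width_comparison.tsv'}")


if __name__ == "__main__":
    main()
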