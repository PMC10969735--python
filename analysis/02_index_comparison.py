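"""Compare sensory participation indexes within each marker.

For each marker, runs the Friedman omnibus test across the four indexes
(SOM, VIS, VEST, VP) over participants, follows up with Conover pairwise
comparisons when significant, and tabulates median/IQR descriptives —
the per-marker index-comparison surface of the analysis.
"""

from pathlib import Path

import pandas as pd

from ctsib_sway import BlockMatrix, conover_posthoc, friedman_test, summarize_median_iqr

RESULTS = Path(__file__).resolve().parent.parent / "results"
INDEXES = ("som", "vis", "vest", "vp")


def main() -> None:
    idx = pd.read_csv(RESULTS / "indexes.csv")
    rows = []
    for marker, sub in idx.groupby("marker"):
        m = BlockMatrix(
            sub[list(INDEXES)].to_numpy(),
            block_labels=tuple(sub.participant_id),
            treatment_labels=INDEXES,
        )
        omnibus = friedman_test(m)
        print(
            f"{marker}: Friedman X2={omnibus.statistic:.1f}, df={omnibus.df}, "
            f"p={omnibus.p_value:.2g}"
        )
        for name in INDEXES:
            med, iqr = summarize_median_iqr(sub[name].to_numpy())
            rows.append(
                {"marker": marker, "index": name, "median": med, "iqr": iqr,
                 "comparison": "", "statistic": None, "p": None}
            )
        if omnibus.p_value < 0.05:
            for pair in conover_posthoc(m):
                rows.append(
                    {"marker": marker, "index": "", "median": None, "iqr": None,
                     "comparison": f"{pair.treatment_a}-{pair.treatment_b}",
                     "statistic": pair.statistic, "p": pair.p_unadjusted}
                )
                flag = "*" if pair.p_unadjusted < 0.05 else " "
                print(
                    f"  {pair.treatment_a:>4}-{pair.treatment_b:<4} "
                    f"t={pair.statistic:+6.2f}  p={pair.p_unadjusted:.3g} {flag}"
                )
    out = RESULTS / "table2_indexes.csv"
    pd.DataFrame(rows).to_csv(out, index=False, float_format="%.4g")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
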