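"""Functional balance (PBS) and its association with sensory indexes.

Summarizes Pediatric Balance Scale totals and correlates them (Spearman)
with every sensory index at both markers — the expectation under the
generator is a negative association with the vestibular index and null
associations elsewhere.
"""

from pathlib import Path

import pandas as pd

from ctsib_sway import spearman_correlation

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    idx = pd.read_csv(RESULTS / "indexes.csv")
    pbs = pd.read_csv(RESULTS / "pbs_totals.csv")
    print(f"PBS totals: mean={pbs.pbs_total.mean():.2f}, sd={pbs.pbs_total.std():.2f}")
    rows = []
    for marker, sub in idx.groupby("marker"):
        merged = sub.merge(pbs, on="participant_id")
        for name in ("som", "vis", "vest", "vp"):
            res = spearman_correlation(
                merged[name].to_numpy(), merged["pbs_total"].to_numpy()
            )
            rows.append({"marker": marker, "index": name, "rho": res.rho, "p": res.p_value})
            flag = "*" if res.p_value < 0.05 else " "
            print(f"  PBS vs {name.upper():>4} ({marker}): rho={res.rho:+.3f}, p={res.p_value:.3g} {flag}")
    out = RESULTS / "pbs_associations.csv"
    pd.DataFrame(rows).to_csv(out, index=False, float_format="%.4g")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
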