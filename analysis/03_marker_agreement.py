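"""Cross-marker agreement of the sensory indexes.

Correlates (Spearman) each index computed from lateral-malleolus sway
with the same index computed from mastoid-process sway — do ankle-level
and head-level recordings tell the same story about sensory reliance?
"""

from pathlib import Path

import pandas as pd

from ctsib_sway import spearman_correlation

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    idx = pd.read_csv(RESULTS / "indexes.csv")
    rows = []
    for name in ("som", "vis", "vest", "vp"):
        wide = idx.pivot(index="participant_id", columns="marker", values=name).dropna()
        res = spearman_correlation(
            wide["lateral_malleolus"].to_numpy(), wide["mastoid_process"].to_numpy()
        )
        rows.append({"index": name, "rho": res.rho, "p": res.p_value, "n": res.n})
        print(f"{name.upper():>4}: rho={res.rho:+.3f}, p={res.p_value:.3g} (n={res.n})")
    out = RESULTS / "table3_agreement.csv"
    pd.DataFrame(rows).to_csv(out, index=False, float_format="%.4g")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
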