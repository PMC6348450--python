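#!/usr/bin/env python
"""Statistics that are fully determined by published counts and geometry.

Recomputes the responder-rate chi-square statistics, the responder
percentages, the photostimulation grid size and the Bonferroni threshold
from their defining inputs, and writes them to results/.
"""

from pathlib import Path

import pandas as pd

from cortiplast.group_stats import bonferroni_alpha, chi2_yates
from cortiplast.lsps_map import make_grid

OUT = Path(__file__).resolve().parents[1] / "results"

TABLES = {
    "excitatory responders, control vs lesioned": [[220, 610], [297, 521]],
    "inhibitory responders, control vs lesioned": [[56, 109], [105, 73]],
    "excitatory responders, male vs female": [[178, 468], [42, 142]],
    "inhibitory responders, male vs female": [[45, 86], [11, 23]],
}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for label, table in TABLES.items():
        res = chi2_yates(table)
        rows.append({"comparison": label, "chi2": round(res.statistic, 3),
                     "df": res.df, "p": res.p})
        print(f"{label}: chi2(1) = {res.statistic:.3f}, p = {res.p:.4g}")
    pd.DataFrame(rows).to_csv(OUT / "contingency_tests.csv", index=False)

    fractions = [(220, 830), (297, 818), (56, 165), (105, 178)]
    frac_rows = [{"responding": r, "total": n,
                  "percent": round(100 * r / n, 1)} for r, n in fractions]
    pd.DataFrame(frac_rows).to_csv(OUT / "responder_percentages.csv", index=False)
    print("responder percentages:",
          ", ".join(f"{row['percent']}%" for row in frac_rows))

    grid = make_grid(62.5, 750.0, 1750.0)
    alpha = bonferroni_alpha(0.05, 3)
    pd.DataFrame([{"grid_sites": grid.n_sites,
                   "bonferroni_alpha_3_comparisons": alpha}]).to_csv(
        OUT / "design_constants.csv", index=False)
    print(f"grid sites: {grid.n_sites}; Bonferroni threshold (3 comparisons): "
          f"{alpha}")


if __name__ == "__main__":
    main()
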