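"""Correlate the nuclei-size factors with mitosis and Breslow thickness.

Pairwise Pearson correlation with significance stars; writes the r and
p matrices as CSV and the annotated heatmap as SVG.
"""

from pathlib import Path

import pandas as pd

from melaband import features as ft
from melaband import reporting

ROOT = Path(__file__).resolve().parents[1]
DEMO = ROOT / "results" / "demo"


def main() -> None:
    feats = pd.read_csv(DEMO / "features.csv")
    factors = [c for c in ft.FACTOR_COLUMNS if c.endswith("size") and c in feats.columns]
    factors += ["mitosis", "thickness_mm"]
    cm = reporting.correlation_matrix(feats, factors)
    cm.r.to_csv(DEMO / "correlation_r.csv")
    cm.p.to_csv(DEMO / "correlation_p.csv")
    reporting.plot_correlation_heatmap(cm, DEMO / "correlation_heatmap.svg")
    r_thick = cm.r.loc["invasive_mean_nuclei_size", "thickness_mm"]
    star = cm.stars.loc["invasive_mean_nuclei_size", "thickness_mm"]
    print(
        f"correlation matrix over {len(factors)} factors; "
        f"invasive nuclei size vs thickness: r = {r_thick:.2f} {star or '(ns)'}"
    )


if __name__ == "__main__":
    main()
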