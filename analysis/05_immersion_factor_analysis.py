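"""Reliability and exploratory factor analysis of the VRI questionnaire.

For each immersion level (engagement, engrossment, total immersion):
Cronbach's alpha, KMO sampling adequacy, Bartlett sphericity, and EFA with
Kaiser retention + varimax rotation, reporting variance explained and the
top-loading items per factor.
"""

from pathlib import Path

import pandas as pd

from vreeg.immersion import level_report
from vreeg.synth import QuestionnaireConfig, generate_questionnaires, \
    vri_item_map

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    path = OUT / "vri_responses.csv"
    if path.exists():
        vri = pd.read_csv(path)
    else:
        _, _, vri = generate_questionnaires(QuestionnaireConfig(seed=SEED),
                                            32)
    item_map = vri_item_map()

    rows = []
    for level in ("engagement", "engrossment", "total_immersion"):
        rep = level_report(vri, item_map, level)
        rows.append({
            "level": level,
            "n_items": (item_map["level"] == level).sum(),
            "KMO": round(rep.kmo, 3),
            "bartlett_chi2": round(rep.bartlett_chi2, 2),
            "bartlett_df": rep.bartlett_df,
            "bartlett_p": rep.bartlett_p,
            "n_factors": rep.n_factors,
            "variance_pct": round(rep.variance_explained_pct, 2),
            "alpha": round(rep.alpha, 3),
        })
        print(f"\n{level}: KMO={rep.kmo:.3f}, "
              f"chi2({rep.bartlett_df})={rep.bartlett_chi2:.2f} "
              f"(p={rep.bartlett_p:.1e}), {rep.n_factors} factors, "
              f"{rep.variance_explained_pct:.1f}% variance, "
              f"alpha={rep.alpha:.3f}")
        for fac, items in rep.top_items.items():
            print(f"  {fac}: top items {', '.join(items) or '(none >= .5)'}")

    pd.DataFrame(rows).to_csv(OUT / "immersion_efa_summary.csv", index=False)
    print("\n-> results/immersion_efa_summary.csv")


if __name__ == "__main__":
    main()
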