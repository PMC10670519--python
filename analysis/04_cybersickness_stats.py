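"""Cybersickness statistics on the synthetic SSQ responses.

Scores the 16-item SSQ into N/O/D subscales and the weighted total score,
summarises them per scene (mean/median/SD), and tests for scene effects
with the Friedman omnibus per scale followed by Conover pairwise post-hoc
comparisons.
"""

from pathlib import Path

import pandas as pd

from vreeg.surveys import (
    conover_posthoc,
    friedman_test,
    scene_score_matrix,
    score_ssq_table,
    summarize_ssq,
)
from vreeg.synth import QuestionnaireConfig, generate_questionnaires

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    path = OUT / "ssq_responses.csv"
    if path.exists():
        ssq = pd.read_csv(path)
    else:
        ssq, _, _ = generate_questionnaires(QuestionnaireConfig(seed=SEED),
                                            32)

    scores = score_ssq_table(ssq)
    summary = summarize_ssq(scores)
    summary.round(2).to_csv(OUT / "ssq_scale_summary.csv", index=False)
    print("per-scene SSQ scales (mean / median / sd):")
    print(summary.round(2).to_string(index=False))

    omnibus = []
    for scale in ("N", "O", "D", "TS"):
        m, scenes = scene_score_matrix(scores, scale)
        res = friedman_test(m, scale=scale)
        omnibus.append({"scale": scale, "chi2": res.statistic,
                        "df": res.df, "p": res.p_value})
        print(f"Friedman {scale}: chi2({res.df}) = {res.statistic:.2f}, "
              f"p = {res.p_value:.2e}")
    pd.DataFrame(omnibus).to_csv(OUT / "ssq_friedman.csv", index=False)

    m, scenes = scene_score_matrix(scores, "TS")
    posthoc = conover_posthoc(m, conditions=scenes)
    posthoc.p_values.round(4).to_csv(OUT / "ssq_conover_posthoc.csv")
    print("\nConover pairwise p-values (total score):")
    print(posthoc.p_values.round(4).to_string())
    tl_rc = posthoc.p_values.loc["TL", "RC"]
    print(f"\nsmallest contrast: TL vs RC p = {tl_rc:.2e} "
          "(calm scene vs roller coaster)")


if __name__ == "__main__":
    main()
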