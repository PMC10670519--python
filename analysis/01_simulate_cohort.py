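"""Generate the synthetic study cohort: EEG recordings + questionnaires.

A full-resolution recording is ~116 MB as delimited text, so the first
subject's continuous EEG goes under scratch/ (the downstream scripts
regenerate EEG on the fly from the same seed anyway); the compact marker
sidecar and the full 32-subject questionnaire tables land in results/.
"""

from pathlib import Path

import pandas as pd

from vreeg.io import write_recording
from vreeg.synth import (
    QuestionnaireConfig,
    SynthConfig,
    alpha_contrast_effects,
    generate_questionnaires,
    generate_recording,
    vri_item_map,
)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)

    cfg = SynthConfig(n_subjects=32, band_effects=alpha_contrast_effects(),
                      seed=SEED)
    rec = generate_recording(cfg, 0)
    write_recording(rec, SCRATCH / "subject00_recording")
    pd.DataFrame(
        [{"onset_s": m.onset, "duration_s": m.duration, "scene": m.scene,
          "region": m.region, "subject": m.subject} for m in rec.markers]
    ).to_csv(OUT / "subject00_markers.csv", index=False)
    print(f"subject 0 recording: {rec.n_channels} ch x "
          f"{rec.data.shape[1]} samples @ {rec.fs:g} Hz, "
          f"{len(rec.markers)} markers -> scratch/subject00_recording.*")

    qcfg = QuestionnaireConfig(seed=SEED)
    ssq, sam, vri = generate_questionnaires(qcfg, cfg.n_subjects)
    ssq.to_csv(OUT / "ssq_responses.csv", index=False)
    sam.to_csv(OUT / "sam_ratings.csv", index=False)
    vri.to_csv(OUT / "vri_responses.csv", index=False)
    vri_item_map().to_csv(OUT / "vri_item_map.csv", index=False)
    print(f"questionnaires: {len(ssq)} SSQ rows, {len(sam)} SAM rows, "
          f"{len(vri)} VRI rows for {cfg.n_subjects} subjects x 5 scenes")


if __name__ == "__main__":
    main()
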