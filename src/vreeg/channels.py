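"""Channel montage and experimental label constants.

The recording montage is the 32-electrode 10-20 layout of a saline-cap
consumer research headset (Fp1..O2 below), referenced against AFz (DRL) and
FCz (CMS).  Scalp positions are nominal 10-20 geometry expressed in an
azimuthal-equidistant ("top-down") projection: ``angle`` is the compass
bearing from the vertex toward the nasion, ``ecc`` the eccentricity with 1.0
at the head rim (90 deg inclination).  These coordinates drive topographic
interpolation only; they are not fitted to any digitised head model.
"""

from __future__ import annotations

import math

#: 32-channel 10-20 montage, frontal to occipital, left before right.
CHANNELS_32 = (
    "Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO3", "PO4", "O1", "Oz", "O2",
)

#: Hardware reference sensors (no signal is read from them).
REFERENCE_LABELS = ("AFz", "FCz")

# (bearing deg, eccentricity): bearing measured from the nasion direction,
# positive clockwise (toward the right ear).
_POLAR = {
    "Fp1": (-18, 1.00), "Fp2": (18, 1.00),
    "AF3": (-20, 0.82), "AF4": (20, 0.82),
    "F7": (-54, 1.00), "F8": (54, 1.00),
    "F3": (-39, 0.71), "F4": (39, 0.71),
    "Fz": (0, 0.50),
    "FC5": (-69, 0.80), "FC6": (69, 0.80),
    "FC1": (-45, 0.35), "FC2": (45, 0.35),
    "T7": (-90, 1.00), "T8": (90, 1.00),
    "C3": (-90, 0.50), "C4": (90, 0.50),
    "Cz": (0, 0.00),
    "CP5": (-111, 0.80), "CP6": (111, 0.80),
    "CP1": (-135, 0.35), "CP2": (135, 0.35),
    "P7": (-126, 1.00), "P8": (126, 1.00),
    "P3": (-141, 0.71), "P4": (141, 0.71),
    "Pz": (180, 0.50),
    "PO3": (-160, 0.82), "PO4": (160, 0.82),
    "O1": (-162, 1.00), "O2": (162, 1.00),
    "Oz": (180, 1.00),
}


def montage_2d(labels=CHANNELS_32) -> dict[str, tuple[float, float]]:
    """Unit-disk (x, y) scalp coordinates for *labels* (nose at +y)."""
    out = {}
    for lab in labels:
        ang, ecc = _POLAR[lab]
        rad = math.radians(ang)
        out[lab] = (ecc * math.sin(rad), ecc * math.cos(rad))
    return out


#: Homologous left-right electrode pairs used for asymmetry features.
ASYMMETRY_PAIRS = (
    ("Fp1", "Fp2"), ("AF3", "AF4"), ("F3", "F4"), ("F7", "F8"),
    ("FC1", "FC2"), ("C3", "C4"), ("P3", "P4"), ("O1", "O2"),
)

#: Frontal channels most loaded by ocular artifacts.
FRONTAL_CHANNELS = ("Fp1", "Fp2", "AF3", "AF4")

#: The five VR stimulus scenes.
SCENES = ("TWD", "PNI", "TL", "PVR", "RC")

#: Valence-arousal quadrants (high/low valence x high/low arousal).
REGIONS = ("HVHA", "LVHA", "LVLA", "HVLA")

#: Default scene -> valence-arousal quadrant assignment, from the intent of
#: each scene: zombie survival (TWD) is negative/arousing, optical illusions
#: (PNI) low-key/neutral-negative, mountain viewing (TL) calm/pleasant,
#: ski racing (PVR) and the roller coaster (RC) exciting/pleasant.
SCENE_TO_REGION = {
    "TWD": "LVHA",
    "PNI": "LVLA",
    "TL": "HVLA",
    "PVR": "HVHA",
    "RC": "HVHA",
}

#: Canonical EEG frequency bands (Hz).  The 45 Hz gamma cap matches the
#: analysis low-pass cutoff.
BAND_EDGES = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}
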