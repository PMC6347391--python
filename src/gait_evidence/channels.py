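"""Default gait waveform channel inventory.

Nine joint rotation angles (hip/knee/ankle x sagittal/frontal/transverse,
time-normalized over the full gait cycle), nine joint moments and three
ground-reaction-force components (stance phase), and two centre-of-pressure
position channels expressed relative to the foot segment.

Note: the 23-channel default includes "ML position of COP" as the 23rd
channel; the study design enumerates 22 unambiguously (9 angles, 9 moments,
3 GRF, AP COP) and the mediolateral COP channel is our assumption for the
remaining one.
"""

from __future__ import annotations

ANGLE_CHANNELS: list[str] = [
    "Hip flexion angle",
    "Hip adduction angle",
    "Hip transverse angle",
    "Knee flexion angle",
    "Knee adduction angle",
    "Knee transverse angle",
    "Ankle dorsiflexion angle",
    "Ankle adduction angle",
    "Ankle transverse angle",
]

MOMENT_CHANNELS: list[str] = [
    "Hip flexion moment",
    "Hip adduction moment",
    "Hip transverse moment",
    "Knee flexion moment",
    "Knee adduction moment",
    "Knee transverse moment",
    "Ankle dorsiflexion moment",
    "Ankle adduction moment",
    "Ankle transverse moment",
]

GRF_CHANNELS: list[str] = [
    "Anteroposterior force",
    "Mediolateral force",
    "Vertical force",
]

COP_CHANNELS: list[str] = [
    "AP position of COP",
    "ML position of COP",  # assumption: see module docstring
]

DEFAULT_CHANNELS: list[str] = (
    ANGLE_CHANNELS + MOMENT_CHANNELS + GRF_CHANNELS + COP_CHANNELS
)

#: kinematics span the full gait cycle; kinetics and GRF/COP span stance only.
CHANNEL_PHASE: dict[str, str] = {
    **{c: "cycle" for c in ANGLE_CHANNELS},
    **{c: "stance" for c in MOMENT_CHANNELS},
    **{c: "stance" for c in GRF_CHANNELS},
    **{c: "stance" for c in COP_CHANNELS},
}

#: units after normalization: angles in degrees, moments in % bodyweight*height,
#: forces as a fraction of bodyweight, COP as a fraction of foot length.
CHANNEL_UNITS: dict[str, str] = {
    **{c: "deg" for c in ANGLE_CHANNELS},
    **{c: "%BW*Ht" for c in MOMENT_CHANNELS},
    **{c: "BW" for c in GRF_CHANNELS},
    **{c: "fraction-of-foot" for c in COP_CHANNELS},
}

N_SAMPLES = 101
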