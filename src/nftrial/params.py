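"""Default trial parameters for the three-arm neurofeedback RCT generator.

The study design is a 60-participant, sex-stratified, 1:1:1 randomized
trial comparing cognitive training with NIRS neurofeedback (CT-NF),
cognitive training alone (CT) and an active control playing a puzzle game
(ACT).  Participants trained ~20 min/day for four weeks while a 2-channel
total-hemoglobin NIRS device recorded bilateral DLPFC activity.

The dictionaries below hold the published per-arm distributions the
synthetic generator emulates: baseline cognitive-test scores, four-week
change scores, preprocessed per-hemisphere NIRS activation changes
(last-3-days minus first-3-days task activation, arbitrary ΔtotalHb
units), and training adherence.  All entries are (mean, sd).
"""

from __future__ import annotations

import math

ARMS = ("CT-NF", "CT", "ACT")

#: Cognitive outcomes measured pre and post (change scores analysed).
COGNITIVE_OUTCOMES = (
    "Cd",            # digit symbol coding (processing speed), correct items
    "ST",            # Stroop task (inhibition), correct items
    "D-CAT",         # digit cancellation (attention), hits
    "DS-F",          # digit span forward (short-term memory), max length 9
    "DS-B",          # digit span backward (working memory), max length 8
    "LM-immediate",  # logical memory immediate recall, story units
    "LM-delay",      # logical memory delayed recall, story units
    "MR",            # mental rotation, correct choices (24 items x 2)
)

#: Baseline-only measures (reading/IQ screen) plus the pre-scores above.
BASELINE_MEASURES = ("JART",) + COGNITIVE_OUTCOMES

HEMISPHERES = ("left", "right")

#: Instrument bounds used when truncating generated scores.
#: Unbounded-above instruments use +inf.
SCORE_BOUNDS = {
    "JART": (0.0, 25.0),
    "Cd": (0.0, math.inf),
    "ST": (0.0, math.inf),
    "D-CAT": (0.0, math.inf),
    "DS-F": (0.0, 9.0),
    "DS-B": (0.0, 8.0),
    "LM-immediate": (0.0, 25.0),
    "LM-delay": (0.0, 25.0),
    "MR": (0.0, 48.0),
}

#: Baseline (mean, sd) per arm and measure.
BASELINE_PARAMS = {
    "CT-NF": {
        "JART": (20.30, 1.89),
        "Cd": (98.90, 12.90),
        "ST": (60.45, 9.83),
        "D-CAT": (65.20, 9.73),
        "DS-F": (7.50, 1.24),
        "DS-B": (6.00, 1.45),
        "LM-immediate": (16.35, 3.47),
        "LM-delay": (15.70, 3.06),
        "MR": (30.85, 6.29),
    },
    "CT": {
        "JART": (20.65, 1.60),
        "Cd": (98.75, 12.56),
        "ST": (61.25, 7.03),
        "D-CAT": (65.35, 10.97),
        "DS-F": (7.20, 1.01),
        "DS-B": (6.10, 1.41),
        "LM-immediate": (16.35, 4.00),
        "LM-delay": (15.90, 3.73),
        "MR": (30.60, 7.31),
    },
    "ACT": {
        "JART": (20.45, 1.76),
        "Cd": (98.45, 8.61),
        "ST": (65.45, 7.75),
        "D-CAT": (64.20, 10.23),
        "DS-F": (7.60, 1.19),
        "DS-B": (6.05, 1.61),
        "LM-immediate": (15.70, 3.06),
        "LM-delay": (15.05, 2.98),
        "MR": (30.75, 6.84),
    },
}

#: Baseline age (mean, sd) per arm, used when age_mode="normal".
AGE_PARAMS = {
    "CT-NF": (21.25, 1.12),
    "CT": (21.50, 1.15),
    "ACT": (21.55, 1.19),
}

#: Post-minus-pre change score (mean, sd) per arm and outcome.
CHANGE_PARAMS = {
    "CT-NF": {
        "Cd": (16.50, 13.34),
        "ST": (3.90, 4.45),
        "D-CAT": (12.00, 9.77),
        "DS-F": (-0.10, 1.45),
        "DS-B": (1.55, 1.61),
        "LM-immediate": (1.30, 3.34),
        "LM-delay": (2.45, 2.84),
        "MR": (3.70, 9.40),
    },
    "CT": {
        "Cd": (15.15, 10.56),
        "ST": (3.05, 9.57),
        "D-CAT": (3.15, 7.64),
        "DS-F": (0.50, 1.64),
        "DS-B": (0.40, 1.35),
        "LM-immediate": (-0.25, 3.40),
        "LM-delay": (0.30, 3.08),
        "MR": (2.85, 5.79),
    },
    "ACT": {
        "Cd": (5.95, 15.25),
        "ST": (0.75, 8.88),
        "D-CAT": (5.10, 8.41),
        "DS-F": (-0.10, 1.41),
        "DS-B": (0.45, 2.04),
        "LM-immediate": (0.60, 2.74),
        "LM-delay": (0.25, 2.77),
        "MR": (10.65, 8.06),
    },
}

#: Preprocessed NIRS activation change (mean, sd) per arm and hemisphere,
#: arbitrary ΔtotalHb units.
NIRS_CHANGE_PARAMS = {
    "CT-NF": {"left": (0.17, 0.06), "right": (0.14, 0.05)},
    "CT": {"left": (0.03, 0.07), "right": (-0.06, 0.12)},
    "ACT": {"left": (-0.05, 0.11), "right": (-0.03, 0.08)},
}

#: Training adherence in days out of 28 (mean, sd) per arm.
ADHERENCE_PARAMS = {
    "CT-NF": (25.43, 0.84),
    "CT": (25.11, 0.98),
    "ACT": (24.55, 1.06),
}

# --- session-generator neural amplitude defaults -------------------------
# The CT-NF neural amplitude ramps linearly from BASE_AMP on day 1 to a
# per-hemisphere ceiling on the final day; CT and ACT stay at BASE_AMP.
# The ceilings are calibrated once so that the full offline chain (detrend
# -> 0.1 Hz lowpass -> dual-SD regression -> rest-baseline correction ->
# last-3-minus-first-3-days) recovers mean activation changes of 0.17
# (left) and 0.14 (right) a.u. in the CT-NF arm.  The chain's amplitude
# recovery factor is ~0.60 (hemodynamic rise time plus carry-over of the
# response into the following rest block; see docs/methods.md), and with
# ~25 trained days the first/last-3-day ramp separation is ~0.91 of the
# full ramp, giving a net change-per-unit-ramp slope of ~0.55.
BASE_AMP = 0.05
CTNF_CEILING_LEFT = 0.359
CTNF_CEILING_RIGHT = 0.304
#: Participant-level multiplicative gain SD (drives between-subject spread
#: of the activation change; 0.35 * 0.17 ~ the printed SD 0.06).
GAIN_SD = 0.35
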