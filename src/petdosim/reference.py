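"""Published reference values for an F-18 SV2A radiotracer dosimetry study.

A preclinical mouse study of an F-18 labelled synaptic-vesicle-protein-2A
tracer reported human-extrapolated residence times and absorbed doses derived
two ways: classical tissue distribution by organ harvesting ("TD") and
dynamic small-animal PET with sphere volumes of interest ("dynamic single").
These printed values serve as regression references for the dose engine
(recomputing effective doses, injection limits and the method comparison from
published organ-dose vectors) — they are inputs to those computations, not
outputs of this package.

All residence times are hours; absorbed doses mGy/MBq; effective doses
mSv/MBq.  The bladder value is the theoretical voiding-model result
(excreted fraction 0.5, biological half-life 3 h, voiding interval 4 h).
"""

from __future__ import annotations

#: Human residence times (h) derived by tissue distribution (bladder fraction 0.5).
RESIDENCE_TD: dict[str, float] = {
    "brain": 1.74e-01,
    "heart": 1.79e-02,
    "kidneys": 3.57e-02,
    "liver": 4.45e-01,
    "lung": 5.96e-02,
    "spleen": 9.04e-03,
    "testes": 2.11e-03,
}

#: Printed theoretical bladder residence time (h), shared by all methods.
RESIDENCE_BLADDER: float = 3.08e-01

#: Printed remaining-body residence time (h), TD column.
RESIDENCE_REMAINDER_TD: float = 1.58e00

#: Human residence times (h) derived by dynamic imaging, sphere VOIs.
RESIDENCE_DYNAMIC_SINGLE: dict[str, float] = {
    "heart": 2.39e-02,
    "kidneys": 1.90e-02,
    "liver": 2.18e-01,
    "lung": 9.30e-02,
    "testes": 1.12e-03,
}

#: Printed remaining-body residence time (h), dynamic-single column.
RESIDENCE_REMAINDER_DYNAMIC_SINGLE: float = 1.97e00

#: Human absorbed doses (mGy/MBq), tissue-distribution method.
DOSES_TD: dict[str, float] = {
    "adrenals": 1.43e-02,
    "brain": 3.08e-02,
    "breasts": 7.71e-03,
    "gallbladder wall": 1.86e-02,
    "lli wall": 1.36e-02,
    "small intestine": 1.24e-02,
    "stomach wall": 1.11e-02,
    "uli wall": 1.25e-02,
    "heart wall": 1.76e-02,
    "kidneys": 2.96e-02,
    "liver": 5.84e-02,
    "lungs": 1.64e-02,
    "muscle": 9.82e-03,
    "ovaries": 1.38e-02,
    "pancreas": 1.40e-02,
    "red marrow": 9.71e-03,
    "osteogenic cells": 1.39e-02,
    "skin": 7.22e-03,
    "spleen": 1.52e-02,
    "testes": 1.58e-02,
    "thymus": 9.26e-03,
    "thyroid": 8.86e-03,
    "urinary bladder wall": 1.54e-01,
    "uterus": 1.90e-02,
    "total body": 1.19e-02,
}

#: Human absorbed doses (mGy/MBq), dynamic imaging with sphere VOIs.
DOSES_DYNAMIC_SINGLE: dict[str, float] = {
    "adrenals": 1.36e-02,
    "brain": 8.61e-03,
    "breasts": 8.88e-03,
    "gallbladder wall": 1.56e-02,
    "lli wall": 1.55e-02,
    "small intestine": 1.37e-02,
    "stomach wall": 1.20e-02,
    "uli wall": 1.34e-02,
    "heart wall": 2.09e-02,
    "kidneys": 1.87e-02,
    "liver": 3.14e-02,
    "lungs": 2.17e-02,
    "muscle": 1.10e-02,
    "ovaries": 1.57e-02,
    "pancreas": 1.37e-02,
    "red marrow": 1.04e-02,
    "osteogenic cells": 1.57e-02,
    "skin": 8.17e-03,
    "spleen": 1.15e-02,
    "testes": 1.25e-02,
    "thymus": 1.09e-02,
    "thyroid": 1.01e-02,
    "urinary bladder wall": 1.56e-01,
    "uterus": 2.09e-02,
    "total body": 1.18e-02,
}

#: Reported effective doses (mSv/MBq) for cross-checks.
EFFECTIVE_DOSE_REPORTED: dict[str, float] = {
    "icrp103_td": 1.88e-02,
    "icrp103_dynamic_single": 1.84e-02,
    "icrp60_td": 2.18e-02,
    "icrp60_dynamic_single": 2.15e-02,
}

#: Urinary-bladder-wall dose (mGy/MBq) at an excreted fraction of 0.3 (TD).
UBW_DOSE_TD_FRACTION_03: float = 9.67e-02
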