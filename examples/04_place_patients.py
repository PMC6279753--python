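"""Locate hypothetical patients on the latent severity axis.

Given posterior-mean item parameters, a response pattern is mapped to its
posterior-mean theta by quadrature against the standard-normal prior --
the tick marks on the difference-curve x-axis.
"""

from grmagree import ItemInfo, ItemParams, place_patient

# posterior-mean patient item parameters of published magnitude
items = [
    (ItemInfo("frequency", 5), ItemParams(5.04, (-2.58, 0.41, 3.99, 6.98))),
    (ItemInfo("severity", 5), ItemParams(5.69, (-6.46, 1.21, 5.48, 9.10))),
    (ItemInfo("interference", 5), ItemParams(4.33, (-0.92, 1.78, 4.25, 6.70))),
]

patterns = {
    "no symptoms (all 0)": {"frequency": 0, "severity": 0, "interference": 0},
    "frequency 0 only (rest skipped)": {"frequency": 0},
    "moderate (all 2)": {"frequency": 2, "severity": 2, "interference": 2},
    "severe (frequency 3, severity 3)": {"frequency": 3, "severity": 3},
    "worst (all 4)": {"frequency": 4, "severity": 4, "interference": 4},
}

for label, pattern in patterns.items():
    theta = place_patient(pattern, items)
    print(f"{label:<36} theta = {theta:+.2f}")

# Thetas are in standard-deviation units of the population severity
# distribution: a patient reporting the maximum on every attribute sits
# well above +1 SD, where the difference curves show the largest
# clinician-patient gap.
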