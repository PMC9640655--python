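"""Published benchmark values for the original two-study clinical cohort.

The clinical recordings themselves are not distributable, but the reported
cohort composition and headline classification metrics are public constants.
They serve two purposes here: consistency checks (e.g. recomputing the
majority baselines from the group sizes, verifying the balanced-accuracy
identity on the reported sensitivity/specificity pairs) and as calibration
anchors for the synthetic cohort generator.
"""

from __future__ import annotations

__all__ = [
    "GROUP_SIZES",
    "NSA_TOTAL_MEDIANS",
    "CLASSIFICATION_RESULTS",
]

#: diagnostic group sizes of the pooled cohort
GROUP_SIZES = {"SCZ": 103, "MDD": 50, "HC": 75}

#: reported NSA-Total medians (IQR omitted) per group
NSA_TOTAL_MEDIANS = {"SCZ": 41.0, "MDD": 40.5, "HC": 29.0}

#: reported diagnosis-classification results (late fusion of all modalities):
#: task -> dict(sen, spe, ppv, npv, auprc, bac, mb). The three-way task uses
#: macro one-vs-rest sensitivity/specificity and mean per-class recall as BAC,
#: so BAC = (SEN+SPE)/2 holds for the binary rows only.
CLASSIFICATION_RESULTS = {
    "SCZ vs HC": dict(sen=0.913, spe=0.733, ppv=0.825, npv=0.859,
                      auprc=0.889, bac=0.823, mb=0.579, binary=True),
    "MDD vs HC": dict(sen=0.740, spe=0.907, ppv=0.841, npv=0.840,
                      auprc=0.879, bac=0.823, mb=0.600, binary=True),
    "MDD vs SCZ": dict(sen=0.874, spe=0.820, ppv=0.909, npv=0.759,
                       auprc=0.905, bac=0.847, mb=0.673, binary=True),
    "MDD+SCZ vs HC": dict(sen=0.773, spe=0.822, ppv=0.682, npv=0.880,
                          auprc=0.861, bac=0.798, mb=0.670, binary=True),
    "MDD vs SCZ vs HC": dict(sen=0.680, spe=0.840, ppv=0.778, npv=0.761,
                             auprc=0.780, bac=0.687, mb=0.452, binary=False),
}

#: the contrasts whose majority baselines are exactly determined by the group
#: sizes (the patients-vs-controls row was reported on the modality-complete
#: subsample and differs in the third decimal, so it is excluded)
MB_CONTRASTS = {
    "SCZ vs HC": ("SCZ", "HC"),
    "MDD vs HC": ("MDD", "HC"),
    "MDD vs SCZ": ("MDD", "SCZ"),
    "MDD vs SCZ vs HC": ("SCZ", "MDD", "HC"),
}
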