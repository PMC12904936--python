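from ssnhl_ipta.audiometry import EarThresholds


def ear(thresholds, side="right", conduction="air"):
    return EarThresholds(thresholds, side=side, conduction=conduction)
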