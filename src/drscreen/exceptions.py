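class UndefinedStatisticError(ValueError):
    """A statistic's defining formula has an empty or zero denominator.

    Raised e.g. for GLCM correlation with a zero marginal variance, for
    precision when no positive predictions exist, or for AUC on a
    single-class label vector.  Callers that must stay rectangular
    substitute a documented sentinel instead of propagating.
    """
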