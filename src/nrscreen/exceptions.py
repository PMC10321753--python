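class ValidationError(ValueError):
    """An input file, table, or configuration violates a declared contract."""


class DegenerateStatisticsWarning(UserWarning):
    """A statistic was computed on degenerate input (e.g. a log-rank test
    with zero variance, where the p-value defaults to 1)."""
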