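"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A scenario or operation parameter is outside its admissible range."""


class BudgetExceededError(RuntimeError):
    """A sampling quota could not be filled within the simulation budget.

    Attributes
    ----------
    lagging_outcome : str
        The outcome category whose quota was furthest from completion.
    counts : dict
        Records collected per outcome when the budget ran out.
    """

    def __init__(self, message: str, lagging_outcome: str, counts: dict):
        super().__init__(message)
        self.lagging_outcome = lagging_outcome
        self.counts = counts


class CollinearityError(ValueError):
    """The regression design matrix is rank deficient."""
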