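"""Exception types shared across the package."""


class GasExchangeError(ValueError):
    """Base class for physiologically invalid inputs or states."""


class InvalidInputError(GasExchangeError):
    """An input lies outside its physically meaningful range."""


class ContentRangeError(GasExchangeError):
    """A requested O2 content is unattainable at the given haemoglobin."""


class InfeasibleStateError(GasExchangeError):
    """A model state cannot exist (e.g. negative mixed-venous content)."""


class PredictionError(GasExchangeError):
    """A forward PaO2 prediction is infeasible for this measure/pair."""


class ConvergenceError(RuntimeError):
    """The steady-state solver failed to converge."""
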