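"""Exception hierarchy shared across the toolkit."""


class PlorError(Exception):
    """Base class for all toolkit errors."""


class SequenceError(PlorError):
    """Invalid sequence content (bad character, empty input, wrong alphabet)."""


class PromoterError(PlorError):
    """Promoter search failed: no consensus found, or more than one site."""


class TerminatorError(PlorError):
    """No qualifying U-tract in the transcript."""


class ScheduleError(PlorError):
    """A step schedule is malformed, stalls, or leaves the transcript unfinished."""


class LabelDesignError(ScheduleError):
    """The requested label placement cannot be isolated in any step segment."""


class BandTableError(PlorError):
    """Band-intensity table fails validation."""


class FitError(PlorError):
    """Yield-model fit is underdetermined or given invalid observations."""
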