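"""Exception hierarchy shared across the pipeline."""


class RsikitError(Exception):
    """Base class for all rsikit errors."""


class ValidationError(RsikitError):
    """Input violates a structural invariant (duplicate ids, bad shapes...)."""


class ScoringError(RsikitError):
    """A signature cannot be scored (missing gene, non-finite value)."""
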