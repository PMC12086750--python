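"""Exception types shared across the design modules."""


class DesignError(ValueError):
    """Invalid design parameterization."""


class UnattainableDesignError(DesignError):
    """A sample-size search could not meet its threshold within the cap.

    The message names the limiting parameter so callers can tell a
    genuinely infeasible design (threshold unreachable for any n) from a
    cap that was simply set too low.
    """
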