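"""Exception types shared across the package."""


class AgpFretError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(AgpFretError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(AgpFretError, ValueError):
    """An input file could not be parsed."""


class MissingSiteError(AgpFretError, KeyError):
    """A labeling-scheme site cannot be resolved in a structure."""

    def __init__(self, sites):
        self.sites = list(sites)
        detail = "; ".join(
            f"chain {s.chain_id} residue {s.residue_number}" for s in self.sites
        )
        super().__init__(f"unresolvable label site(s): {detail}")
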