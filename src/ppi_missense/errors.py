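"""Exception hierarchy, tagged by pipeline stage where useful."""


class PPIMissenseError(Exception):
    """Base class for all package errors."""


class InputError(PPIMissenseError):
    """Unreadable or malformed input file."""


class EmptyStructureError(InputError):
    """No protein residues found in the selected model."""


class ChainNotFoundError(KeyError, PPIMissenseError):
    """Requested chain id absent from the structure."""


class ResidueNotFoundError(KeyError, PPIMissenseError):
    """Requested residue key absent from the structure."""


class VariantMismatchError(PPIMissenseError):
    """Wild-type residue name in the file disagrees with the variant spec.

    Raised as a hard error to guard against residue-numbering mistakes."""


class NoPartnerChainError(PPIMissenseError):
    """Interface analysis requested on a single-chain structure."""


class FixtureGenerationError(PPIMissenseError):
    """A requested engineered contact is geometrically unsatisfiable."""


class PipelineError(PPIMissenseError):
    """Wraps a module error with the pipeline stage in which it occurred."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"[{stage}] {original}")
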