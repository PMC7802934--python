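"""Exception hierarchy.

Every error raised by foldstab derives from :class:`FoldstabError` so callers
can catch the package's failures without masking programming errors.
"""


class FoldstabError(Exception):
    """Base class for all foldstab errors."""


class FormatError(FoldstabError):
    """A file does not follow the expected format (PDB, PSSM, model file...)."""


class SchemaError(FoldstabError):
    """A tabular input is missing required columns or violates key uniqueness."""


class ValidationError(FoldstabError):
    """Numerical input violates a precondition (non-finite coordinates, negative ratio...)."""


class ChainNotFoundError(FoldstabError):
    """A requested chain is absent from the structure."""


class EmptyStructureError(FoldstabError):
    """No standard amino-acid residues remain after parsing/filtering."""


class ResidueNotFoundError(FoldstabError):
    """A mutation addresses a residue that does not exist in the structure."""


class ConsistencyError(FoldstabError):
    """Declared wild-type residue disagrees with the structure/profile sequence."""


class AminoAcidError(FoldstabError):
    """Unknown amino-acid code for a lookup table."""


class MissingFeatureError(FoldstabError):
    """A feature provider has no value for the requested mutation.

    ``provider`` names the offending input (pssm, conservation, sasa...).
    """

    def __init__(self, provider: str, message: str = ""):
        self.provider = provider
        super().__init__(message or f"provider '{provider}' has no value for this mutation")


class ModelFormatError(FoldstabError):
    """A persisted model file is corrupt or from an incompatible version."""


class ConfigurationError(FoldstabError):
    """An evaluation/CLI configuration is incomplete or contradictory."""


class DegenerateInputError(FoldstabError):
    """A statistic is undefined for this input (all-zero confusion matrix, constant vector...)."""
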