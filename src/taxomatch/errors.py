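"""Exception hierarchy for taxomatch."""


class TaxomatchError(Exception):
    """Base class for all taxomatch errors."""


class BackboneFormatError(TaxomatchError):
    """The backbone file cannot be parsed (missing column, empty file, ...)."""


class BackboneValidationError(TaxomatchError):
    """The backbone parsed but violates an integrity rule (duplicate ID, ...)."""


class ConfigError(TaxomatchError):
    """A run was configured inconsistently (missing column name, bad option)."""


class GenerationError(TaxomatchError):
    """The synthetic-backbone generator could not satisfy its constraints."""
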