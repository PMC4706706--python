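"""Exception and warning types shared across the package."""


class VariantStoreError(Exception):
    """Base class for all package errors."""


class KeyCodecError(VariantStoreError):
    """Malformed key text, illegal character, or field overflow."""


class AlleleError(KeyCodecError):
    """Allele cannot be packed (non-ACGT character or length mismatch)."""


class NormalizationError(VariantStoreError):
    """Raw variant disagrees with the reference or lies out of bounds."""


class ReferenceMismatchError(NormalizationError):
    """REF allele does not match the reference sequence at its coordinates."""


class UnknownContigError(NormalizationError):
    """Contig name outside the supported set (1..22, X, Y, MT)."""


class KeyCollisionError(VariantStoreError):
    """A unique key would be overwritten by a different allele."""


class UnknownStudyError(VariantStoreError):
    """A cohort references a study id that is not registered."""


class CountsUnavailableError(VariantStoreError):
    """A cohort carries allele frequencies without allele numbers."""


class VcfParseError(VariantStoreError):
    """VCF record could not be parsed; carries file/line context."""


class NonUniqueKeyWarning(UserWarning):
    """Decoded key is flagged non-unique: the allele may be truncated."""
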